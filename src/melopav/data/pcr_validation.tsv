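gene	kind	variety	gap_size_bp	gap_coords	comment
4241	f	IQ	6225	5246795-5253019	C
4241	f	CV	-	-
4260	p	CV	498	5508275-5508772	C, SI (37 nt), E
4262	p	IQ	-	-	False PAV
4262	p	CV	-	-	False PAV
4278	p	CV	1308	5684308-5686215	C, I (partial)
4288	p	IQ	-	-	False PAV
4288	p	CV	-	-	False PAV
4289	f	IQ	86393	5790312-5876704	C, SI (3 kb)
4289	p	CV	739	5802779-5803517	C, I
4290	f	IQ	86393	5790312-5876704	C, SI (3 kb)
4291	f	IQ	86393	5790312-5876704	C, SI (3 kb)
4291	p	PI	57737	5843353-5901089	SI (744 nt)
4292	f	IQ	86393	5790312-5876704	C, SI (3 kb)
4292	p	CV	532	5857419-5857950	C, E (partial), I (partial)
4292	f	PI	57737	5843353-5901089	C, SI (744 nt)
4293	f	IQ	86393	5790312-5876704	C, SI (3 kb)
4293	f	PI	57737	5843353-5901089	C, SI (744 nt)
4294	f	CV	40204	5878047-5918250	C, SI (3 kb)
4294	f	PI	57737	5843353-5901089	C, SI (744 nt)
4295	f	CV	40204	5878047-5918250	C, SI (3 kb)
4295	f	PI	57737	5843353-5901089	C, SI (744 nt)
4299	p	IQ	525	5953236-5953760	I
4299	p	CV	525	5953236-5953760	I
4299	p	PI	524	5953237-5953760	I
4317	p	PI	-	-	False PAV
4318	f	CV	149716	6088767-6238482	C
4319	f	CV	149716	6088767-6238482	C
4319	f	PI	87210	6130422-6217631	C
4320	f	CV	149716	6088767-6238482	CC
4320	f	PI	87210	6130422-6217631	C
4321	f	CV	149716	6088767-6238482	C
4321	f	PI	87210	6130422-6217631	C
4322	f	CV	149716	6088767-6238482	C
4322	f	PI	87210	6130422-6217631	C
4322	f	IQ	-	-	Not yet confirmed
4323	f	CV	149716	6088767-6238482	C
4324	p	IQ	1637	6234788-6236424	C, E (partial)
4324	f	CV	149716	6088767-6238482	C
4324	f	PI	5714	6232627-6238340	C
4326	f	IQ	3005	6250865-6253869	C, SI (5.8 kb)
4326	f	CV	3588	6250865-6254452	C, SI (6 kb)
4331	f	PI	6370	6306115-6312484	C
5453	p	IQ	0	5239342-5239343	C, SI (225 bp)
5453	p	CV	0	5239290-5239343
14632	p	CV	7278	4628501-4635778	C, E, I, SI (39 bp)
14633	f	IQ	33861	4646955-4680815	C, SI (7.5 kb)
14633	f	PI	33861	4646955-4680815	C, SI (7.5 kb)
14634	f	IQ	33861	4646955-4680815	C, SI (7.5 kb)
14634	f	PI	33861	4646955-4680815	C, SI (7.5 kb)
14635	f	IQ	33861	4646955-4680815	C, SI (7.5 kb)
14635	f	PI	33861	4646955-4680815	C, SI (7.5 kb)
15015	f	CV	28011	1038039-1066049	C, SI (2.6 kb, transposon)
22141	p	IQ	-	-	False PAV
22141	p	PI	-	-	False PAV
22145	p	IQ	9736	1733997-1743732	C, E, I, SI (6.5 kb)
22145	p	CV	9736	1733997-1743732	C, E, I, SI (6.5 kb)
22145	p	PI	9736	1733997-1743732	C, E, I, SI (6.5 kb)
22153	p	PI	-	-	False PAV
22154	p	CV	-	-	False PAV
22154	p	PI	-	-	False PAV
23276	f	IQ	19558	755353-774910	C, SI (445 bp)
23276	f	PS	19558	755353-774910	C, SI (310 bp)
23277	f	IQ	19558	755353-774910	C, SI (445 bp)
23277	f	PS	19558	755353-774910	C, SI (310 bp)
23278	f	IQ	19558	755353-774910	C, SI (445 bp)
23278	f	PS	19558	755353-774910	C, SI (310 bp)
23577	p	CV	2191	1519298-1521488	C, E, I
24733	p	CV	193	295122-295314	C, I, SI (234 bp, transposon)
24737	f	CV	4959	344525-349483	C
24743	p	CV	726	468516-469241	C, E, I
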