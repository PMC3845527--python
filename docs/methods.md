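# Methods

## The read-depth PAV model

The analysis treats gene absence as a per-gene, per-cultivar property
inferred from mapped read counts. For cultivar *c* with library size
*L(c)* (total mapped reads at MAPQ ≥ 1) and gene *g*, the normalized
depth is

    norm(g, c) = count(g, c) × 10⁷ / L(c).

The 10⁷ scaling constant is a counts-per-10-million convention; every
decision rule downstream depends only on ratios or on a relative cutoff,
so the choice of constant is immaterial and is documented only so that
numbers in output files are interpretable.

Counting follows the semantics of a region query on a coordinate-sorted,
indexed BAM with unmapped reads excluded and MAPQ ≥ 1: any alignment
record overlapping the gene interval by ≥ 1 bp counts, secondary and
duplicate records are *not* filtered, and counting is strand-blind. An
optional "read start within interval" overlap rule is exposed for users
who want partition-additive counts; the default mirrors the region-query
behaviour.

### Screens and review

Candidate nomination uses two screens with **strict** inequalities
throughout:

- ratio screen: candidate iff some ordered cultivar pair has
  norm-ratio < 0.5. Over ordered pairs the "> 2" direction is the mirror
  image of the "< 0.5" direction, so the rule collapses to
  min/max < 0.5 whenever the maximum is positive — a zero numerator
  always yields ratio 0. The only genuinely separate case is a zero
  *denominator*, where the rule requires the positive side to reach a
  support level (default: the `min_support` threshold in normalized
  units) before the contrast counts; in practice this clause is subsumed
  by the pairwise rule and exists for contractual completeness.
- absolute screen: candidate iff min raw count < 6 and max raw count > 29.

Candidates with fewer than 10 reads in every cultivar are discarded:
a gene nobody covers supports no call. Screens are scale-invariant —
multiplying one cultivar's counts and library size by any k > 0 changes
nothing.

The historical manual step of reviewing candidate loci in a genome
browser is replaced by a deterministic rule: a cultivar is *absent* when
its normalized depth is at most `absence_rel` (default 0.05) of the
gene's cohort maximum, and — when a breadth-of-coverage matrix is
available — its breadth is ≤ 0.10; *partial* when breadth lies strictly
between 0.10 and 0.80. These three constants are artifact parameters
(the original review was visual and irreproducible); they are exposed in
`Thresholds` and in the pipeline config. Partial calling is silently
disabled (with a logged warning) when no breadth matrix is supplied.

Absences called in the reference cultivar — whose own reads were mapped
to its own assembly — are kept but flagged as mapping artifacts, and
excluded from the per-cultivar averages. When the reference line's two
parents are known, reference absences with both parents present receive
an additional `parent-inconsistent` tag: every reference segment derives
from one parent, so such calls are unambiguous false positives.

## Families and clusters

Families are connected components (single-linkage closure) of the graph
of filtered pairwise nucleotide hits: e-value ≤ 1e-20 and both query and
subject coverage strictly > 40% of the gene length. Coverage is taken
from the single best HSP per directed gene pair (highest bitscore);
a summed non-overlapping-HSP mode is available but off by default, as is
a reciprocal-passage requirement (by default an edge exists if either
direction passes) and a percent-identity floor (high identity is an
observed property of surviving nucleotide hits, not a filter). Coverage
above 1.5 is treated as an annotation/hit inconsistency and is an error.

Tandem clusters chain same-family genes along a scaffold whenever at
most `max_intervening` = 8 annotated genes (members of other families
included) separate consecutive members — the strict reading of "fewer
than nine genes between homologs". The phrase is ambiguous between ≤ 8
and ≤ 9; 8 is the default and the parameter is exposed. Chaining is
transitive along a run; clusters are built within families, so
interleaved families produce separate clusters. Curated membership
overrides (merges and additions within one family) are applied from a
directive file with full logging, replacing ad-hoc visual curation.

## Enrichment statistics

Association between PAV status and a gene attribute is tested on the
2×2 table with the df = 1 chi-square statistic, Yates-corrected by
default:

    chi2 = N (|ad − bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)].

The correction matters at the cohort's scale: the multi-copy × PAV table
[739, 6026; 476, 20186] gives 892.4 corrected versus 894.5 uncorrected,
and the corrected value is the one the analysis reports. A zero margin
leaves the statistic undefined and raises an error rather than returning
0. Reported percentages are rounded half-up to one decimal. The clustered
× PAV table [200, 2231; 1015, 23981] yields ≈ 90 (uncorrected ≈ 90.8);
the proportions 16.5% / 8.5% are the stable summary for that comparison.

## The synthetic cohort

The generator emulates the *structure* of a five-cultivar melon
resequencing cohort; it is a statistical stand-in, not a sequence
simulator. Defaults (all exposed on `SimParams`):

| parameter | default | meaning |
|---|---|---|
| `n_genes`, `n_scaffolds` | 27,427 / 50 | annotated complement size |
| `mean_gene_len`, `mean_intergenic` | 2,400 / 14,000 bp | gives a ~450 Mb genome |
| `singleton_fraction` | 0.753 | genes outside multi-copy families |
| `family_size_weights` | 64% size-2, 16% size-3, geometric tail to 20 | family-size law |
| `p_tandem` | 0.4 | multi-copy family placed as a tandem run |
| `depth_per_cultivar` | 15× (scalar or per-cultivar map) | fold-coverage, 13–16× regime |
| `read_len` | 150 bp | Illumina paired-end era read length |
| `base_del_rate` | 0.0037 | per gene × cultivar deletion probability |
| `multi_copy_multiplier`, `cluster_multiplier` | 5, 2 | deletion-odds enrichment |
| `segment_del_prob`, `segment_run_mean` | 0.3, 3 | multi-gene deletion runs (geometric) |
| `partial_del_prob` | 0.25 | partial deletions, retained ~ U(0.2, 0.8) |
| `background_mismap_rate` | 0 | mis-mapped reads per kb of deleted span |
| `overdispersion` | 0 | NB dispersion (0 = Poisson) |

The published band tallies for large families are mutually inconsistent
(the counts of 4–6-member families cannot hold the implied gene share),
so the tail is a geometric decay normalized to the residual 20% mass.
`base_del_rate` is set so that, after the 5×/2× multipliers on the ~25%
multi-copy fraction and the segment-run extension factor
(1 − p + p·mean ≈ 1.6), the realized absence rate lands near 1.5% of
genes per cultivar — the level such cohorts report. The reference
cultivar never carries planted deletions, mirroring a reference line
mapped to its own assembly; reference-artifact behaviour is tested by
injecting calls, not baked into the generator.

Expected counts are λ(g,c) = depth·(len+read_len)/read_len·retained,
plus background·len·(1−retained)/1000 for deleted spans; draws are
Poisson, or gamma-Poisson (NB with variance λ + d·λ²) when
`overdispersion` d > 0. Breadth equals the retained fraction exactly at
the endpoints — deep coverage saturates breadth at 1 and a fully deleted
gene has breadth 0 — with Beta noise (concentration 200) for partials.
Library sizes are column sums plus a Poisson intergenic read total, so
column sums never exceed them. One independent RNG stream per
sub-generator (annotation, truth, counts, hits) derives from the master
seed, so changing e.g. the decoy-hit count cannot perturb the counts;
fixed seed ⇒ byte-identical output files.

Scattered (non-tandem) family members are placed with ≥ 9 intervening
gene slots between same-family members so that planted tandem runs and
detected clusters coincide exactly; homology decoy hits are constructed
to fail the downstream filters through either a weak e-value (> 1e-20)
or ≤ 40% mutual coverage.

**What the generator does not model** — and hence what passing recovery
tests do not show about real data: mappability variation and repeats
(the dominant source of real reference-mapping artifacts), GC and
insert-size biases, paralog cross-mapping between family members,
breakpoints inside genes beyond a uniform retained fraction, and any
sequence-level effect. Recovery being exact at 13× with Poisson noise is
a statement about the decision rules, not about alignment artifacts.

## Validation and problem sizes

The test suite checks every decision rule against independent oracles:
brute-force ordered-pair enumeration for the ratio screen, union-find
for family components, exhaustive chaining for clusters, the
Σ(O−E)²/E expansion and `scipy.stats.chi2_contingency` for the
chi-square, a per-base pileup for breadth, and hand-enumerated BAM
fixtures (built programmatically at test time) for counting. Recovery
tests run 2,000–10,000-gene cohorts; the acceptance script uses
10,000-gene × 5-cultivar cohorts (one noise-free, ten with NB
overdispersion 0.2), sizes chosen to make binomial fluctuations in the
measured rates negligible while keeping runs interactive. Full
deletions are recovered with sensitivity 1.0 and zero false positives
in the noise-free regime because a deleted gene draws exactly zero
reads while the smallest present gene expects ≳ 30; partial deletions
with retained fraction above the 0.5 ratio cutoff are invisible to the
screens by construction, which is a property of the published screen
design, not a defect of the review rule.

## Known limitations

- Absence review thresholds (`absence_rel`, breadth windows) have no
  published counterpart; different settings change the partial/absent
  split on real data.
- The 2×2 machinery assumes genes are independent Bernoulli draws;
  deletion runs violate this mildly (events cluster along scaffolds),
  so real-data p-values are anti-conservative at fine scales.
- Insertion PAVs (sequence present in a cultivar but absent from the
  reference) are out of scope: the method sees only the reference
  coordinate space.
- The CLI exposes no plotting; distribution tables in the report are
  the intended interface to figures.
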