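import numpy as np
import pandas as pd
import pytest

from melopav import families as fam
from melopav.simulate import (
    DeletionTruth,
    SimParams,
    emit_homology_hits,
    generate_annotation,
    generate_pav_truth,
    simulate_cohort,
    simulate_counts,
)


def small_params(**overrides):
    defaults = dict(n_genes=2000, n_scaffolds=8, depth_per_cultivar=13.0, seed=3)
    defaults.update(overrides)
    return SimParams(**defaults)


class TestAnnotation:
    def test_all_singletons_when_singleton_fraction_is_one(self):
        genes, families = generate_annotation(small_params(singleton_fraction=1.0))
        assert families.members == {}
        assert len(genes) == 2000

    def test_family_gene_count_tracks_binomial_expectation(self):
        # mean fraction of genes in families over seeds ~ 1 - singleton_fraction
        n, frac = 2000, 0.753
        observed = []
        for seed in range(8):
            _genes, families = generate_annotation(small_params(seed=seed))
            observed.append(len(families.multi_copy_genes))
        mean = np.mean(observed)
        expect = n * (1 - frac)
        se = np.sqrt(n * frac * (1 - frac) / len(observed))
        # allow 4 SE plus the <=1-gene-per-family truncation slack
        assert abs(mean - expect) < 4 * se + 2

    def test_same_seed_gives_byte_identical_gff3(self):
        a, _ = generate_annotation(small_params())
        b, _ = generate_annotation(small_params())
        assert a.to_gff3_string() == b.to_gff3_string()

    def test_tandem_families_occupy_consecutive_ranks(self):
        genes, families = generate_annotation(small_params(p_tandem=1.0))
        assert families.members
        for fam_id, members in families.members.items():
            assert families.tandem[fam_id]
            rows = genes.df.loc[members]
            assert rows["scaffold"].nunique() == 1
            ranks = sorted(rows["rank"])
            assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))

    def test_scattered_families_never_form_tandem_runs(self):
        genes, families = generate_annotation(small_params(p_tandem=0.0))
        for members in families.members.values():
            rows = genes.df.loc[members]
            for _scaffold, grp in rows.groupby("scaffold"):
                ranks = np.sort(grp["rank"].to_numpy())
                if len(ranks) > 1:
                    assert (np.diff(ranks) - 1 > 8).all()

    def test_architecture_too_large_for_genome_raises(self):
        params = small_params(
            n_genes=12, n_scaffolds=6, singleton_fraction=0.0,
            family_size_weights={20: 1.0}, p_tandem=1.0,
        )
        with pytest.raises(ValueError, match="tandem family"):
            generate_annotation(params)


class TestDeletionTruth:
    def test_zero_rate_gives_empty_truth(self):
        params = small_params(base_del_rate=0.0)
        genes, families = generate_annotation(params)
        assert len(generate_pav_truth(genes, families, params)) == 0

    def test_reference_cultivar_never_deleted(self):
        params = small_params(base_del_rate=0.05)
        genes, families = generate_annotation(params)
        truth = generate_pav_truth(genes, families, params)
        assert all(cv != params.reference for _g, cv, _k, _f in truth.records)

    def test_multicopy_deletion_rate_ratio_matches_multipliers(self):
        # Monte-Carlo over seeds: multi-copy genes (tandem-placed ones get the
        # extra cluster multiplier) should be deleted ~5x as often as singletons
        rates_multi, rates_single = [], []
        for seed in range(10):
            params = small_params(
                seed=seed, base_del_rate=0.01, p_tandem=0.0,
                multi_copy_multiplier=5.0, segment_del_prob=0.0,
            )
            genes, families = generate_annotation(params)
            truth = generate_pav_truth(genes, families, params)
            multi = families.multi_copy_genes
            n_single = len(genes) - len(multi)
            dels = pd.DataFrame(truth.records, columns=["gene", "cv", "kind", "frac"])
            in_multi = dels["gene"].isin(multi)
            rates_multi.append(in_multi.sum() / (4 * len(multi)))
            rates_single.append((~in_multi).sum() / (4 * n_single))
        ratio = np.mean(rates_multi) / np.mean(rates_single)
        assert 4.0 < ratio < 6.0

    def test_segment_deletions_produce_long_runs(self):
        params = small_params(
            n_genes=5000, base_del_rate=0.01, segment_del_prob=1.0,
            segment_run_mean=7.0, partial_del_prob=0.0, seed=1,
        )
        genes, families = generate_annotation(params)
        truth = generate_pav_truth(genes, families, params)
        ranks = genes.df["rank"]
        scaf = genes.df["scaffold"]
        longest = 0
        for cv, deleted in truth.by_cultivar().items():
            sub = genes.df.loc[sorted(deleted)].sort_values(["scaffold", "rank"])
            run = 1
            for (s1, r1), (s2, r2) in zip(
                zip(sub["scaffold"], sub["rank"]),
                zip(sub["scaffold"][1:], sub["rank"][1:]),
            ):
                run = run + 1 if (s1 == s2 and r2 == r1 + 1) else 1
                longest = max(longest, run)
        assert longest >= 7

    def test_partial_retained_fractions_in_open_interval(self):
        params = small_params(base_del_rate=0.05, partial_del_prob=1.0,
                              segment_del_prob=0.0)
        genes, families = generate_annotation(params)
        truth = generate_pav_truth(genes, families, params)
        kinds = {k for _g, _c, k, _f in truth.records}
        assert kinds == {"partial"}
        assert all(0.2 <= f <= 0.8 for _g, _c, _k, f in truth.records)


class TestCountSimulation:
    def test_fully_deleted_gene_has_zero_count_and_breadth(self, small_cohort):
        cm, bm = small_cohort.counts, small_cohort.breadth
        full = [
            (g, c) for g, c, k, _f in small_cohort.deletions.records if k == "full"
        ]
        assert full
        for gene, cultivar in full:
            assert cm.counts.at[gene, cultivar] == 0
            assert bm.breadth.at[gene, cultivar] == 0.0

    def test_mean_count_matches_analytic_lambda(self):
        # many same-length present genes stand in for replicate draws
        params = small_params(
            n_genes=1000, singleton_fraction=1.0, base_del_rate=0.0,
            depth_per_cultivar=15.0, read_len=150, mean_gene_len=1500, seed=9,
        )
        genes, families = generate_annotation(params)
        # force identical lengths for a clean analytic mean
        df = genes.df.copy()
        df["end"] = df["start"] + 1500
        from melopav.genes import GeneTable

        genes = GeneTable(df[["gene_id", "scaffold", "start", "end", "strand"]])
        cm, _ = simulate_counts(genes, DeletionTruth(records=[]), params)
        lam = 15.0 * (1500 + 150) / 150  # = 165
        mean = cm.counts["C-836"].mean()
        se = np.sqrt(lam / len(genes))
        assert abs(mean - lam) < 3 * se

    def test_half_retained_gene_has_half_the_expected_count(self):
        params = small_params(n_genes=400, singleton_fraction=1.0, seed=2)
        genes, _fam = generate_annotation(params)
        half = DeletionTruth(
            records=[(g, "C-836", "partial", 0.5) for g in genes.gene_ids]
        )
        cm, _ = simulate_counts(genes, half, params)
        full_mean = cm.counts["C-1012"].mean()
        half_mean = cm.counts["C-836"].mean()
        assert half_mean == pytest.approx(full_mean / 2, rel=0.1)

    def test_library_sizes_bound_column_sums(self, small_cohort):
        cm = small_cohort.counts
        assert (cm.counts.sum(axis=0) <= cm.library_sizes).all()
        assert (cm.counts >= 0).all().all()
        assert ((small_cohort.breadth.breadth >= 0) & (small_cohort.breadth.breadth <= 1)).all().all()


class TestHomologyHits:
    def test_family_trio_yields_six_directed_hits(self, small_cohort):
        trios = [m for m in small_cohort.families.members.values() if len(m) == 3]
        if not trios:
            pytest.skip("no size-3 family in this cohort draw")
        trio = set(trios[0])
        hits = small_cohort.hits
        directed = hits[hits["qseqid"].isin(trio) & hits["sseqid"].isin(trio)]
        assert len(directed) >= 6

    def test_real_hits_pass_and_decoys_fail_downstream_filters(self, small_cohort):
        genes = small_cohort.genes
        edges = fam.filter_hits(small_cohort.hits, genes.lengths())
        recovered, _singles = fam.build_families(edges, genes.gene_ids)
        assert {frozenset(m) for m in recovered.values()} == small_cohort.families.family_sets()

    def test_decoys_only_yield_all_singletons(self):
        params = small_params(singleton_fraction=1.0)
        genes, families = generate_annotation(params)
        hits = emit_homology_hits(families, genes, seed=4, n_decoys=50)
        assert len(hits) == 50
        edges = fam.filter_hits(hits, genes.lengths())
        fams, singles = fam.build_families(edges, genes.gene_ids)
        assert fams == {}
        assert len(singles) == len(genes)


def test_cohort_outputs_are_deterministic_given_seed(tmp_path):
    from melopav.simulate import write_cohort

    a = simulate_cohort(small_params(seed=12))
    b = simulate_cohort(small_params(seed=12))
    pa = write_cohort(a, tmp_path / "a")
    pb = write_cohort(b, tmp_path / "b")
    for key in ("gff3", "counts", "breadth", "hits", "truth"):
        assert pa[key].read_bytes() == pb[key].read_bytes()
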