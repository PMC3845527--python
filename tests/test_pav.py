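import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melopav import pav
from melopav.coverage import CountMatrix
from melopav.pav import Thresholds


def norm_frame(rows, cultivars=None):
    rows = np.asarray(rows, dtype=float)
    cultivars = cultivars or [f"cv{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=cultivars)


def brute_force_ratio_candidates(norm, th, zero_support):
    """Oracle: enumerate every ordered cultivar pair per gene."""
    out = set()
    for gene, row in norm.iterrows():
        vals = row.to_numpy(dtype=float)
        for i in range(len(vals)):
            for j in range(len(vals)):
                if i == j:
                    continue
                a, b = vals[i], vals[j]
                if b > 0 and (a / b < th.ratio_low or a / b > th.ratio_high):
                    out.add(gene)
                elif b == 0 and a >= zero_support:
                    out.add(gene)
    return out


class TestRatioScreen:
    def test_flat_profile_is_not_a_candidate(self):
        assert pav.screen_ratio(norm_frame([[10, 10, 10, 10, 10]])) == set()

    def test_zero_vs_covered_is_a_candidate(self):
        assert pav.screen_ratio(norm_frame([[0, 20, 18, 22, 19]])) == {"g0"}

    def test_zero_numerator_pairs_always_qualify(self):
        # (0, positive) ordered pairs have ratio 0 < 0.5, however weak the
        # positive side; the low-support filter is what removes hopeless genes
        assert pav.screen_ratio(norm_frame([[0, 4, 5, 6, 7]])) == {"g0"}
        assert pav.screen_ratio(norm_frame([[0, 3, 8, 8, 8]])) == {"g0"}
        assert pav.screen_ratio(norm_frame([[0, 0, 0, 0, 0]])) == set()

    def test_single_cultivar_rejected(self):
        with pytest.raises(ValueError, match="two cultivars"):
            pav.screen_ratio(norm_frame([[5]]))

    def test_random_matrix_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        th = Thresholds()
        values = rng.choice([0, 1, 3, 8, 15, 40, 100], size=(200, 5))
        norm = norm_frame(values)
        expected = brute_force_ratio_candidates(norm, th, zero_support=10.0)
        assert pav.screen_ratio(norm, th, zero_support=10.0) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 200), min_size=3, max_size=3),
            min_size=1,
            max_size=20,
        ),
        st.integers(1, 5),
    )
    def test_scale_invariance_of_one_cultivar(self, rows, k):
        """Multiplying one cultivar's counts and library size by k leaves the
        candidate set unchanged (normalization cancels the factor)."""
        counts = pd.DataFrame(rows, columns=["A", "B", "C"],
                              index=[f"g{i}" for i in range(len(rows))])
        libs = pd.Series({"A": 10_000, "B": 10_000, "C": 10_000})
        base = CountMatrix(counts, libs).normalize()
        scaled_counts = counts.copy()
        scaled_counts["B"] *= k
        scaled_libs = libs.copy()
        scaled_libs["B"] *= k
        scaled = CountMatrix(scaled_counts, scaled_libs).normalize()
        assert pav.screen_ratio(base, zero_support=1.0) == pav.screen_ratio(
            scaled, zero_support=1.0
        )


class TestAbsoluteScreen:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((5, 30), True),  # strictly below 6 and strictly above 29
            ((6, 29), False),  # both bounds are strict
            ((5, 29), False),
            ((6, 30), False),
            ((0, 0, 0, 0, 0), False),  # max not above 29
            ((0, 100, 50, 40, 35), True),
        ],
    )
    def test_boundary_behaviour(self, profile, expected):
        raw = norm_frame([list(profile)]).astype(int)
        got = pav.screen_absolute(raw)
        assert (("g0" in got) is expected)


class TestLowSupportFilter:
    def test_all_below_ten_discarded(self):
        raw = norm_frame([[9, 9, 9, 9, 9], [9, 10, 0, 0, 0]]).astype(int)
        retained, discarded = pav.filter_low_support(raw, {"g0", "g1"})
        assert discarded == {"g0"}
        assert retained == {"g1"}

    def test_partition_of_candidates(self):
        rng = np.random.default_rng(0)
        raw = norm_frame(rng.integers(0, 30, size=(50, 5))).astype(int)
        cands = set(raw.index[::2])
        retained, discarded = pav.filter_low_support(raw, cands)
        assert retained | discarded == cands
        assert retained & discarded == set()


class TestMerge:
    def test_union_sizes_and_provenance(self):
        merged = pav.merge_candidates({"a", "b"}, {"b", "c"}, {"d"})
        assert set(merged) == {"a", "b", "c", "d"}
        assert merged["b"] == {"ratio", "absolute"}
        assert merged["d"] == {"manual"}

    def test_empty_manual_set_is_union_of_screens(self):
        merged = pav.merge_candidates({"a"}, {"b"}, set())
        assert set(merged) == {"a", "b"}


class TestAssignAbsences:
    def test_single_cultivar_absence(self):
        norm = norm_frame([[0, 100, 90, 95, 100]])
        breadth = norm_frame([[0.0, 1, 1, 1, 1]])
        calls = pav.assign_absences({"g0"}, norm, breadth)
        absent = calls[calls["status"] == "absent"]
        assert list(absent["cultivar"]) == ["cv0"]

    def test_breadth_window_gives_partial(self):
        norm = norm_frame([[40, 100, 100]])
        breadth = norm_frame([[0.5, 1.0, 1.0]])
        calls = pav.assign_absences({"g0"}, norm, breadth)
        assert calls.set_index("cultivar").at["cv0", "status"] == "partial"

    def test_gene_with_no_event_is_dropped(self):
        norm = norm_frame([[90, 100, 95]])
        calls = pav.assign_absences({"g0"}, norm, None)
        assert calls.empty

    def test_monotonicity_lowering_an_absent_cultivar_keeps_it_absent(self):
        norm = norm_frame([[4, 100, 90]])
        calls = pav.assign_absences({"g0"}, norm, None)
        assert calls.set_index("cultivar").at["cv0", "status"] == "absent"
        lower = norm_frame([[0, 100, 90]])
        calls2 = pav.assign_absences({"g0"}, lower, None)
        assert calls2.set_index("cultivar").at["cv0", "status"] == "absent"

    def test_noise_free_cohort_calls_recover_planted_truth(self, small_cohort):
        c = small_cohort
        th = Thresholds()
        norm = c.counts.normalize()
        merged = pav.merge_candidates(
            pav.screen_ratio(norm, th), pav.screen_absolute(c.counts, th)
        )
        retained, _ = pav.filter_low_support(c.counts, set(merged), th)
        calls = pav.assign_absences(
            {g: merged[g] for g in retained}, norm, c.breadth.breadth, th,
            reference_cultivar=c.params.reference,
        )
        called = {
            (r.gene_id, r.cultivar): r.status
            for r in calls.itertuples()
            if r.status != "present"
        }
        truth_full = {(g, cv) for g, cv, k, _f in c.deletions.records if k == "full"}
        # every planted full deletion is called absent, nothing spurious
        for key in truth_full:
            assert called.get(key) == "absent"
        false_pos = {k for k, v in called.items() if v == "absent"} - truth_full
        assert not false_pos
        # candidate partial deletions are recognized as partial
        truth_partial = {
            (g, cv) for g, cv, k, _f in c.deletions.records if k == "partial"
        }
        for gene, cv in truth_partial & set(called):
            assert called[(gene, cv)] == "partial"


class TestReferenceArtifacts:
    def make_calls(self):
        rows = [
            ("gX", "DHL92", "absent", "ratio", 0.0, None, False),
            ("gX", "T111", "present", "ratio", 90.0, None, False),
            ("gX", "PI", "present", "ratio", 85.0, None, False),
            ("gY", "T111", "absent", "ratio", 0.0, None, False),
            ("gY", "DHL92", "present", "ratio", 80.0, None, False),
            ("gY", "PI", "present", "ratio", 70.0, None, False),
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "cultivar", "status", "screens", "norm",
                     "breadth", "artifact_flag"],
        )

    def test_reference_absence_flagged(self):
        calls = pav.flag_reference_artifacts(self.make_calls(), "DHL92")
        flagged = calls[calls["artifact_flag"]]
        assert set(flagged["gene_id"]) == {"gX"}
        assert set(flagged["cultivar"]) == {"DHL92"}

    def test_parent_inconsistent_tag(self):
        calls = pav.flag_reference_artifacts(
            self.make_calls(), "DHL92", parents=("T111", "PI")
        )
        ref_row = calls[(calls["gene_id"] == "gX") & (calls["cultivar"] == "DHL92")]
        assert "parent-inconsistent" in ref_row["screens"].iloc[0]

    def test_no_reference_absence_no_flags(self):
        calls = self.make_calls()
        calls = calls[calls["gene_id"] == "gY"]
        out = pav.flag_reference_artifacts(calls, "DHL92")
        assert not out["artifact_flag"].any()


class TestSummarize:
    def test_single_event(self):
        calls = pd.DataFrame(
            [("g1", "A", "absent", "", 0.0, None, False),
             ("g1", "B", "present", "", 50.0, None, False)],
            columns=["gene_id", "cultivar", "status", "screens", "norm",
                     "breadth", "artifact_flag"],
        )
        s = pav.summarize(calls)
        assert s.n_events == 1
        assert s.genes_by_n_absent_cultivars == {1: 1}

    def test_histogram_shares_match_published_style_tallies(self):
        # 854 one-cultivar + 263 two-cultivar + 84 three-cultivar + 14 wider
        rows = []
        cultivars = ["A", "B", "C", "D"]
        gid = 0
        for n_absent, n_genes in [(1, 854), (2, 263), (3, 84), (4, 14)]:
            for _ in range(n_genes):
                for cv in cultivars[:n_absent]:
                    rows.append((f"g{gid}", cv, "absent", "", 0.0, None, False))
                gid += 1
        calls = pd.DataFrame(
            rows, columns=["gene_id", "cultivar", "status", "screens", "norm",
                           "breadth", "artifact_flag"],
        )
        s = pav.summarize(calls, n_genes_universe=27427)
        assert s.n_pav_genes == 1215
        assert s.pav_fraction_of_complement == 4.4
        hist = s.genes_by_n_absent_cultivars
        assert round(100 * hist[1] / s.n_pav_genes, 1) == 70.3
        assert round(100 * hist[2] / s.n_pav_genes, 1) == 21.6  # 263/1215
        assert s.n_events == 854 + 2 * 263 + 3 * 84 + 4 * 14

    def test_event_shares_per_cultivar(self):
        rows = []
        gid = 0
        for cv, n in [("C-836", 788), ("C-1012", 334), ("T111", 250),
                      ("PI161375", 295), ("DHL92", 30)]:
            for _ in range(n):
                flag = cv == "DHL92"
                rows.append((f"g{gid}", cv, "absent", "", 0.0, None, flag))
                gid += 1
        calls = pd.DataFrame(
            rows, columns=["gene_id", "cultivar", "status", "screens", "norm",
                           "breadth", "artifact_flag"],
        )
        s = pav.summarize(calls, reference_cultivar="DHL92")
        assert s.n_events == 1697
        assert s.event_share_per_cultivar["C-836"] == 46.4
        assert s.n_reference_artifacts == 30
        # mean absent per cultivar excludes the flagged reference events
        assert s.mean_absent_per_cultivar == pytest.approx(1667 / 4, abs=0.1)


def test_absent_region_bed_merges_adjacent_genes():
    from melopav.genes import GeneTable

    genes = GeneTable(
        [
            ("g0", "s1", 0, 100, "+"),
            ("g1", "s1", 200, 300, "+"),
            ("g2", "s1", 400, 500, "+"),
            ("g3", "s1", 900, 1000, "+"),
        ]
    )
    calls = pd.DataFrame(
        [
            ("g0", "A", "absent", "", 0.0, None, False),
            ("g1", "A", "absent", "", 0.0, None, False),
            ("g3", "A", "absent", "", 0.0, None, False),
        ],
        columns=["gene_id", "cultivar", "status", "screens", "norm", "breadth",
                 "artifact_flag"],
    )
    bed = pav.absent_regions_bed(calls, genes)
    assert bed.values.tolist() == [
        ["s1", 0, 300, "A"],
        ["s1", 900, 1000, "A"],
    ]
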