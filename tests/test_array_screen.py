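import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methscreen.array_screen import (
    BetaMatrix,
    IslandRelation,
    ProbeAnnotation,
    ScreenConfig,
    ScreenResult,
    UnevaluableProbeError,
    filter_promoter_probes,
    intersect_and_collapse,
    prevalence_fraction,
    run_screen,
    screen_cohort,
)
from methscreen.synthetic_data import SimConfig, simulate_screen_inputs

from conftest import brute_force_screen

NAN = float("nan")


def probe(pid, genes=(), groups=(), island=IslandRelation.ISLAND):
    return ProbeAnnotation(pid, tuple(genes), tuple(groups), island)


def matrix(values, cohort="test"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return BetaMatrix(
        cohort_label=cohort,
        probe_ids=[f"p{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestProbeAnnotation:
    def test_parallel_lists_enforced(self):
        with pytest.raises(ValueError, match="equal length"):
            ProbeAnnotation("p1", ("A",), ("TSS200", "Body"))

    def test_island_relation_coerced_from_string(self):
        assert probe("p1", island="Shore").island_relation is IslandRelation.SHORE


class TestBetaMatrix:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            matrix([[0.5, 1.2]])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            BetaMatrix("c", ["p0"], ["s0"], np.zeros((2, 2)))

    def test_allows_missing(self):
        m = matrix([[0.5, NAN]])
        assert np.isnan(m.values[0, 1])


class TestScreenConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScreenConfig(unmeth_beta_max=0.7, meth_beta_min=0.6)

    @pytest.mark.parametrize("frac", [0.0, 1.5])
    def test_sample_fracs_in_unit_interval(self, frac):
        with pytest.raises(ValueError):
            ScreenConfig(unmeth_sample_frac=frac)


class TestFilterPromoterProbes:
    def test_tss200_included(self):
        assert filter_promoter_probes([probe("p1", ["A"], ["TSS200"])]) == {"p1"}

    def test_body_excluded(self):
        assert filter_promoter_probes([probe("p1", ["A"], ["Body"])]) == set()

    def test_enumerated_mixture(self):
        # oracle: 3 TSS1500 probes of 10, rest Body
        probes = [
            probe(f"p{i}", ["G"], ["TSS1500" if i < 3 else "Body"]) for i in range(10)
        ]
        assert filter_promoter_probes(probes) == {"p0", "p1", "p2"}

    def test_tss_alias_accepted(self):
        # loose "TSS" token counts as membership in either fine-grained group
        assert filter_promoter_probes([probe("p1", ["A"], ["TSS"])]) == {"p1"}

    def test_unknown_group_warns_and_excludes(self):
        with pytest.warns(UserWarning, match="unknown TSS group"):
            out = filter_promoter_probes([probe("p1", ["A"], ["PROMOTER??"])])
        assert out == set()

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            filter_promoter_probes([])


class TestPrevalenceFraction:
    def test_three_of_four_at_most(self):
        assert prevalence_fraction([0.1, 0.2, 0.9, 0.2], 0.25, "at_most") == 0.75

    def test_all_satisfy(self):
        assert prevalence_fraction([0.0] * 20, 0.25, "at_most") == 1.0

    def test_missing_excluded_both_sides(self):
        # count-by-hand over non-missing entries: 0.6 and 0.7 of {0.6, 0.59, 0.7}
        assert prevalence_fraction([0.6, 0.59, NAN, 0.7], 0.60, "at_least") == pytest.approx(2 / 3)

    def test_all_missing_raises(self):
        with pytest.raises(UnevaluableProbeError):
            prevalence_fraction([NAN, NAN], 0.25, "at_most")

    def test_bad_direction(self):
        with pytest.raises(ValueError, match="direction"):
            prevalence_fraction([0.1], 0.25, "below")


class TestScreenCohort:
    def test_all_low_betas_pass_unmethylated(self):
        assert screen_cohort(matrix([[0.1] * 20]), "unmethylated") == {"p0"}

    def test_nine_of_twenty_fails_methylated(self):
        # brute-force prevalence: 9/20 = 0.45 < 0.50
        assert screen_cohort(matrix([[0.9] * 9 + [0.1] * 11]), "methylated") == set()

    def test_ten_of_twenty_passes_methylated_inclusive(self):
        assert screen_cohort(matrix([[0.9] * 10 + [0.1] * 10]), "methylated") == {"p0"}

    def test_planted_recovery_complete_separation(self):
        cfg = SimConfig(seed=7, unmeth_range=(0.0, 0.15), meth_range=(0.8, 1.0))
        annotation, matrices, truth = simulate_screen_inputs(cfg)
        result = run_screen(annotation, matrices["primary"], matrices["metastasis"])
        assert result.intersect_probes == truth.candidate_probes
        assert result.candidate_genes == truth.candidate_genes

    def test_sparse_probe_dropped_as_unevaluable(self):
        row = [0.1] * 4 + [NAN] * 16  # 20% informative < 50% floor
        assert screen_cohort(matrix([row]), "unmethylated") == set()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        g = np.random.default_rng(seed)
        values = g.random((12, 9))
        values[g.random(values.shape) < 0.1] = NAN
        m = matrix(values)
        cfg = ScreenConfig()
        for mode in ("unmethylated", "methylated"):
            assert screen_cohort(m, mode, cfg) == brute_force_screen(m, mode, cfg)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, seed):
        g = np.random.default_rng(seed)
        m = matrix(g.random((10, 8)))
        loose = screen_cohort(m, "unmethylated", ScreenConfig(unmeth_beta_max=0.4))
        tight = screen_cohort(m, "unmethylated", ScreenConfig(unmeth_beta_max=0.2))
        assert tight <= loose
        lax = screen_cohort(m, "methylated", ScreenConfig(meth_sample_frac=0.3))
        strict = screen_cohort(m, "methylated", ScreenConfig(meth_sample_frac=0.7))
        assert strict <= lax

    def test_order_independence(self, rng):
        values = rng.random((8, 6))
        m = matrix(values)
        perm = rng.permutation(8)
        shuffled = BetaMatrix(
            "test",
            [m.probe_ids[i] for i in perm],
            m.sample_ids,
            values[perm],
        )
        for mode in ("unmethylated", "methylated"):
            assert screen_cohort(m, mode) == screen_cohort(shuffled, mode)


class TestIntersectAndCollapse:
    def test_single_intersection(self):
        ann = [probe("p1", ["X"], ["TSS200"]), probe("p2", ["geneA"], ["TSS200"]),
               probe("p3", ["Y"], ["TSS200"])]
        result = intersect_and_collapse({"p1", "p2"}, {"p2", "p3"}, ann)
        assert result.intersect_probes == {"p2"}
        assert result.candidate_genes == {"geneA"}

    def test_open_sea_gene_dropped(self):
        ann = [probe("p2", ["geneA"], ["TSS200"], IslandRelation.OPEN_SEA)]
        result = intersect_and_collapse({"p2"}, {"p2"}, ann)
        assert result.candidate_genes == set()
        assert result.dropped_no_island == {"geneA"}

    def test_island_gate_disabled(self):
        ann = [probe("p2", ["geneA"], ["TSS200"], IslandRelation.OPEN_SEA)]
        result = intersect_and_collapse(
            {"p2"}, {"p2"}, ann, ScreenConfig(require_island=False)
        )
        assert result.candidate_genes == {"geneA"}

    def test_multi_gene_fanout_set_union(self):
        # set-union oracle: probes mapping to {A,B} and {B} -> candidates {A,B}
        ann = [
            probe("p1", ["A", "B"], ["TSS200", "TSS1500"]),
            probe("p2", ["B"], ["TSS200"]),
        ]
        result = intersect_and_collapse({"p1", "p2"}, {"p1", "p2"}, ann)
        assert result.candidate_genes == {"A", "B"}

    def test_gene_kept_if_any_probe_on_island(self):
        ann = [
            probe("p1", ["A"], ["TSS200"], IslandRelation.SHELF),
            probe("p2", ["A"], ["TSS200"], IslandRelation.ISLAND),
        ]
        result = intersect_and_collapse({"p1", "p2"}, {"p1", "p2"}, ann)
        assert result.candidate_genes == {"A"}

    def test_unknown_probe_rejected(self):
        with pytest.raises(KeyError, match="p9"):
            intersect_and_collapse({"p9"}, {"p9"}, [probe("p1", ["A"], ["TSS200"])])

    def test_stage_counts_recorded(self):
        ann = [probe("p2", ["geneA"], ["TSS200"])]
        result = intersect_and_collapse({"p2"}, {"p2"}, ann)
        assert result.stage_counts["intersect_probes"] == 1
        assert result.stage_counts["candidate_genes"] == 1


class TestScreenResultInvariants:
    def test_intersect_subset_enforced(self):
        with pytest.raises(ValueError, match="subset"):
            ScreenResult(intersect_probes={"p1"}, unmeth_probes=set(), meth_probes={"p1"})

    def test_candidate_dropped_disjoint(self):
        with pytest.raises(ValueError, match="overlap"):
            ScreenResult(candidate_genes={"A"}, dropped_no_island={"A"})


class TestRunScreen:
    def test_promoter_filter_applied_first_and_counts_both_orders(self):
        cfg = SimConfig(seed=3, unmeth_range=(0.0, 0.15), meth_range=(0.8, 1.0))
        annotation, matrices, _ = simulate_screen_inputs(cfg)
        result = run_screen(annotation, matrices["primary"], matrices["metastasis"])
        sc = result.stage_counts
        assert sc["promoter_probes"] <= sc["annotation_probes"]
        assert sc["unmeth_probes"] <= sc["unmeth_probes_unfiltered"]
        assert sc["meth_probes"] <= sc["meth_probes_unfiltered"]
        assert list(sc)[:2] == ["annotation_probes", "promoter_probes"]
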