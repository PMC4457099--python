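import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methscreen.cobra import (
    ENZYMES,
    DigestResult,
    MethylatedSequence,
    bisulfite_convert,
    cobra_assay,
    digest,
    overall_call,
    pool_call,
)
from methscreen.synthetic_data import SimConfig, simulate_promoter

from conftest import scan_sites


def ms(seq, positions=(), states=()):
    return MethylatedSequence(seq, tuple(positions), tuple(states))


@st.composite
def methylated_sequences(draw):
    seq = draw(st.text(alphabet="ACGT", min_size=1, max_size=80))
    positions = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    states = tuple(
        draw(st.sampled_from(["methylated", "unmethylated"])) for _ in positions
    )
    return MethylatedSequence(seq, tuple(positions), states)


class TestMethylatedSequence:
    def test_rejects_non_cpg_position(self):
        with pytest.raises(ValueError, match="not the C of a CpG"):
            ms("ACGT", [0], ["methylated"])

    def test_rejects_parallel_mismatch(self):
        with pytest.raises(ValueError, match="parallel"):
            ms("ACGT", [1], [])

    def test_rejects_bad_base(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            ms("ACGN")


class TestBisulfiteConvert:
    def test_methylated_cpg_preserved(self):
        assert bisulfite_convert(ms("ACGT", [1], ["methylated"])) == "ACGT"

    def test_unmethylated_cpg_converted(self):
        assert bisulfite_convert(ms("ACGT", [1], ["unmethylated"])) == "ATGT"

    def test_non_cpg_cytosines_always_convert(self):
        # position-by-position oracle: C0->T, C1 (methylated CpG) kept, C4->T
        assert bisulfite_convert(ms("CCGAC", [1], ["methylated"])) == "TCGAT"

    def test_identity_on_c_free_sequence(self):
        assert bisulfite_convert(ms("ATGGTA")) == "ATGGTA"

    @given(methylated_sequences())
    @settings(max_examples=100, deadline=None)
    def test_only_methylated_cpg_cs_survive(self, m):
        converted = bisulfite_convert(m)
        assert len(converted) == len(m.seq)
        survivors = {i for i, b in enumerate(converted) if b == "C"}
        assert survivors == set(m.methylated_positions)

    def test_error_rate_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            bisulfite_convert(ms("CCC"), conversion_error_rate=0.5)

    def test_error_rate_one_preserves_all_cs(self):
        rng = np.random.default_rng(0)
        out = bisulfite_convert(ms("CCC"), conversion_error_rate=1.0, rng=rng)
        assert out == "CCC"


class TestDigest:
    def test_no_site_one_fragment(self):
        res = digest("AAAA", "BstUI")
        assert res.cut_positions == ()
        assert res.fragment_lengths == (4,)
        assert res.call == "unmethylated"

    def test_site_created_by_conversion(self):
        # substring-scan oracle: converting CCGAC (CpG at 1 methylated)
        # yields TCGAT, creating a TaqI site at 0 from a non-CpG C
        converted = bisulfite_convert(ms("CCGAC", [1], ["methylated"]))
        assert converted == "TCGAT"
        res = digest(converted, "TaqI")
        assert res.cut_positions == (1,)
        assert res.call == "methylated"

    def test_fully_methylated_bstui_site(self):
        # manual site scan: ACGCGT converts to itself, CGCG at 1, cut at 3
        m = ms("ACGCGT", [1, 3], ["methylated", "methylated"])
        converted = bisulfite_convert(m)
        assert converted == "ACGCGT"
        res = digest(converted, "BstUI")
        assert res.cut_positions == (3,)
        assert res.fragment_lengths == (3, 3)
        assert res.call == "methylated"

    def test_overlapping_sites_all_counted(self):
        # CGCGCG carries BstUI sites at 0 and 2 -> cuts at 2 and 4
        res = digest("CGCGCG", "BstUI")
        assert res.cut_positions == (2, 4)
        assert res.fragment_lengths == (2, 2, 2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            digest("", "BstUI")

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            digest("ACGT", "EcoRI")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=120),
           st.sampled_from(sorted(ENZYMES)))
    @settings(max_examples=200, deadline=None)
    def test_fragments_conserve_length(self, seq, enzyme):
        assert sum(digest(seq, enzyme).fragment_lengths) == len(seq)

    @given(st.text(alphabet="ACGT", min_size=4, max_size=120),
           st.sampled_from(sorted(ENZYMES)))
    @settings(max_examples=200, deadline=None)
    def test_cut_count_matches_substring_scan(self, seq, enzyme):
        site, _ = ENZYMES[enzyme]
        assert len(digest(seq, enzyme).cut_positions) == len(set(
            i + ENZYMES[enzyme][1] for i in scan_sites(seq, site)
        ))


class TestDigestResultInvariant:
    def test_call_must_match_cuts(self):
        with pytest.raises(ValueError, match="iff"):
            DigestResult("BstUI", (), (4,), "methylated")


class TestCobraAssay:
    def test_fully_unmethylated_never_cuts(self):
        m = simulate_promoter(SimConfig(seed=5), mi=0.0)
        results = cobra_assay(m)
        assert all(r.call == "unmethylated" for r in results.values())
        assert overall_call(results) == "unmethylated"

    def test_fully_methylated_island_cuts_bstui(self):
        m = simulate_promoter(SimConfig(seed=5), mi=1.0)
        results = cobra_assay(m)
        assert results["BstUI"].call == "methylated"
        assert overall_call(results) == "methylated"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_mixed_states_equal_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = simulate_promoter(SimConfig(seed=seed % 1000), mi=0.5, rng=rng)
        converted = bisulfite_convert(m)
        for enzyme, (site, offset) in ENZYMES.items():
            expected = sorted({i + offset for i in scan_sites(converted, site)})
            assert list(cobra_assay(m)[enzyme].cut_positions) == expected

    @given(methylated_sequences())
    @settings(max_examples=100, deadline=None)
    def test_destruction_property(self, m):
        # all CpGs unmethylated -> no C survives -> neither enzyme can cut
        all_unmeth = MethylatedSequence(
            m.seq, m.cpg_positions, tuple("unmethylated" for _ in m.cpg_positions)
        )
        if not all_unmeth.seq:
            return
        converted = bisulfite_convert(all_unmeth)
        assert "CG" not in converted
        for enzyme in ENZYMES:
            assert digest(converted, enzyme).call == "unmethylated"

    def test_fully_methylated_agrees_with_site_enumeration(self, rng):
        # per-allele truth: a fully methylated allele digests iff the
        # original amplicon carries a recognition site whose CGs are intact
        for seed in range(20):
            m = simulate_promoter(SimConfig(seed=seed), mi=1.0)
            converted = bisulfite_convert(m)
            has_site = any(
                scan_sites(converted, site) for site, _ in ENZYMES.values()
            )
            assert (overall_call(cobra_assay(m)) == "methylated") == has_site


class TestPoolCall:
    def test_majority_cut_pool_methylated(self):
        assert pool_call([True] * 8 + [False] * 2) == "methylated"

    def test_threshold_is_strict(self):
        assert pool_call([True] + [False] * 3, min_cut_fraction=0.25) == "unmethylated"
        assert pool_call([True, True] + [False] * 2, min_cut_fraction=0.25) == "methylated"

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_call([])
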