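import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsitemut.formats_io import MatureMiRNA
from mirsitemut.site_prediction import (
    AlignParams,
    BindingSite,
    NNParams,
    align_duplex,
    duplex_free_energy,
    find_seed_matches,
    predict_sites,
    rank_and_filter_sites,
    revcomp_rna,
)
from oracles import oracle_align_score

rna = st.text("ACGU", min_size=1)


class TestSeedMatches:
    def test_8mer(self, mirna_x):
        sites = find_seed_matches(mirna_x, "CCCCAUACUGUACCCC")
        assert [s.seed_class for s in sites] == ["8mer"]
        s = sites[0]
        assert s.tx_end - s.tx_start == 8

    def test_7mer_m8_without_final_a(self, mirna_x):
        sites = find_seed_matches(mirna_x, "CCCCAUACUGUGCCCC")
        assert [s.seed_class for s in sites] == ["7mer-m8"]

    def test_7mer_a1_and_6mer(self, mirna_x):
        # core without the m8-pairing base, with/without the A
        assert [s.seed_class for s in find_seed_matches(mirna_x, "CCCCCUACUGUACCCC")] == ["7mer-A1"]
        assert [s.seed_class for s in find_seed_matches(mirna_x, "CCCCCUACUGUGCCCC")] == ["6mer"]

    def test_no_complementarity(self, mirna_x):
        assert find_seed_matches(mirna_x, "CCCCCCCCCC") == []

    def test_short_target(self, mirna_x):
        assert find_seed_matches(mirna_x, "AUACU") == []

    def test_gu_wobble_never_satisfies_seed_class(self, mirna_x):
        """A G:U opposition inside the core breaks the seed match even
        though the duplex aligner would still pair it."""
        core = revcomp_rna(mirna_x.sequence[1:7])  # AUACUG pairs positions 2-7
        # miRNA position 5 is G; its core partner is core[2] == C.
        # Swapping that C for U leaves a G:U opposition: still a pair
        # for the aligner, never a seed match.
        assert mirna_x.sequence[4] == "G" and core[2] == "C"
        wobbled = "CCC" + core[:2] + "U" + core[3:] + "CCC"
        assert find_seed_matches(mirna_x, "CCC" + core + "CCC")
        assert find_seed_matches(mirna_x, wobbled) == []
        aln = align_duplex(mirna_x, wobbled[3:-3])
        assert any(True for _ in aln.pairs)  # the aligner still pairs it


class TestAlignDuplex:
    def test_perfect_8nt_window_score(self, mirna_x):
        """Perfect complement opposite positions 1-8: one unweighted
        match plus seven seed-weighted matches = 5 + 7*20 = 145."""
        window = revcomp_rna(mirna_x.sequence[:8])
        aln = align_duplex(mirna_x, window)
        assert aln.score == 145.0
        assert oracle_align_score(mirna_x.sequence, window) == 145.0

    def test_single_wobble_in_weighted_column_drops_16(self, mirna_x):
        """Replacing one Watson-Crick match by G:U in a seed column
        loses (5-1)*4 = 16 points."""
        window = list(revcomp_rna(mirna_x.sequence[:8]))
        # window index 3 pairs miRNA position 5 (= G); C -> U gives G:U
        assert mirna_x.sequence[4] == "G" and window[3] == "C"
        window[3] = "U"
        aln = align_duplex(mirna_x, "".join(window))
        assert aln.score == 145.0 - 16.0
        assert oracle_align_score(mirna_x.sequence, "".join(window)) == 129.0

    def test_no_complementarity_yields_no_site(self):
        m = MatureMiRNA("m", "AAAAAAAAAAAAAAAAAAAA")
        aln = align_duplex(m, "AAAAAAAA")
        assert aln.score < AlignParams().min_score

    def test_empty_window(self, mirna_x):
        aln = align_duplex(mirna_x, "")
        assert aln.score == 0.0 and aln.pairs == []

    @given(st.text("ACGU", min_size=1, max_size=10),
           st.text("ACGU", min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, mirna_seq, window):
        """The Gotoh aligner agrees with a pair-anchored enumeration of
        all local alignments on small instances."""
        got = align_duplex(mirna_seq, window).score
        want = oracle_align_score(mirna_seq, window)
        assert got == pytest.approx(want)

    def test_8mer_outscores_seed_mismatch(self, mirna_x):
        """Alignment and seed classifier agree: the intact 8mer site
        never scores below the same site with one seed mismatch."""
        window = "CCCC" + revcomp_rna(mirna_x.sequence[:8]) + "CCCC"
        broken = window[:8] + ("A" if window[8] != "A" else "G") + window[9:]
        assert align_duplex(mirna_x, window).score >= align_duplex(mirna_x, broken).score


class TestFreeEnergy:
    def test_two_stacked_gc_pairs(self):
        """5'GC3' target / 3'CG5' miRNA helix: initiation + one GC
        stack, summed by hand."""
        nn = NNParams()
        dg = duplex_free_energy([(0, 2), (1, 1)], "GC", "GC", nn)
        assert dg == pytest.approx(nn.initiation + nn.stacks[("GC", "CG")])

    def test_single_isolated_pair_is_initiation_only(self):
        nn = NNParams()
        assert duplex_free_energy([(0, 1)], "G", "C", nn) == pytest.approx(nn.initiation)
        assert duplex_free_energy([(0, 1)], "G", "C", nn) > 0

    def test_helix_concatenation_additivity(self):
        """Two helices sharing a boundary pair: total dG equals the sum
        of the parts minus one duplex initiation."""
        nn = NNParams()
        target, mirna = "GCAU", "AUGC"  # all Watson-Crick, antiparallel
        pairs = [(0, 4), (1, 3), (2, 2), (3, 1)]
        whole = duplex_free_energy(pairs, mirna, target, nn)
        left = duplex_free_energy(pairs[:2], mirna, target, nn)
        right = duplex_free_energy(pairs[1:], mirna, target, nn)
        assert whole == pytest.approx(left + right - nn.initiation)

    def test_zero_pairs_is_error(self, mirna_x):
        with pytest.raises(ValueError, match="no duplex"):
            duplex_free_energy([], mirna_x, "ACGU")

    def test_strictly_decreasing_in_helix_length(self):
        """Every Watson-Crick pair added to a helix lowers dG."""
        target = "GCAUGCAU"
        mirna = revcomp_rna(target)  # full complement, 5'->3'
        energies = []
        for n_pairs in range(2, 9):
            # target offset t pairs miRNA position len - t
            pairs = [(t, len(target) - t) for t in range(n_pairs)]
            energies.append(duplex_free_energy(pairs, mirna, target))
        assert all(b < a for a, b in zip(energies, energies[1:]))

    def test_interior_loop_penalty(self):
        nn = NNParams()
        # pairs at target 0 and 2 (gap at 1): two isolated pairs + loop
        dg = duplex_free_energy([(0, 3), (2, 1)], "CAG", "GAC"[::-1], nn)
        assert dg == pytest.approx(nn.initiation + nn.loop_penalty)


class TestRankAndFilter:
    def _sites(self, scores, mirna="m1"):
        return [
            BindingSite(region_id=f"r{i}", mirna=mirna, tx_start=0, tx_end=6,
                        seed_class="6mer", align_score=s)
            for i, s in enumerate(scores)
        ]

    def test_keeps_ceil_three_quarters(self):
        kept = rank_and_filter_sites(self._sites([10, 8, 6, 2]))
        assert sorted(s.align_score for s in kept) == [6, 8, 10]

    def test_ties_at_cutoff_all_retained(self):
        kept = rank_and_filter_sites(self._sites([5, 5, 5, 5]))
        assert len(kept) == 4

    def test_single_site_kept(self):
        assert len(rank_and_filter_sites(self._sites([1]))) == 1

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            rank_and_filter_sites(self._sites([1, 2]), keep_fraction=0.0)

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=20),
           st.integers(1, 3), st.integers(1, 3))
    @settings(derandomize=True, max_examples=100)
    def test_size_bounds_and_monotonicity(self, scores, num, den):
        import math
        sites = self._sites(scores)
        frac = min(num / (num + den) + 0.25, 1.0)
        kept = rank_and_filter_sites(sites, keep_fraction=frac)
        assert math.ceil(frac * len(scores)) <= len(kept) <= len(scores)
        larger = rank_and_filter_sites(self._sites(scores), keep_fraction=min(frac + 0.2, 1.0))
        kept_ids = {s.region_id for s in kept}
        assert kept_ids <= {s.region_id for s in larger}


class TestPredictSites:
    def test_seed_and_score_policy(self, mirna_x):
        target = "CCCC" + revcomp_rna(mirna_x.sequence[:8]) + "CCCC"
        sites = predict_sites(mirna_x, target)
        assert len(sites) == 1
        s = sites[0]
        assert s.seed_class == "8mer" and s.align_score >= 80
        assert s.delta_g < 0

    def test_align_only_policy_reports_seedless_duplex(self):
        m = MatureMiRNA("m", "ACGUACGUACGUACGUACGU")
        # full complement gives a strong duplex even if we disturb the seed
        target = "UUUU" + revcomp_rna(m.sequence) + "UUUU"
        sites = predict_sites(m, target, site_policy="align_only")
        assert sites and sites[0].align_score >= 80
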