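import pytest

from mirsitemut.formats_io import MatureMiRNA, Variant
from mirsitemut.mutation_impact import (
    intersect_variants_sites,
    score_mutation_effect,
    summarize_impacts,
    summarize_locations,
)
from mirsitemut.site_prediction import BindingSite, revcomp_rna
from mirsitemut.synthetic_data import RECURRENT_LOCI
from mirsitemut.transcript_model import TranscriptRegion, apply_variant


def _region_with_site(mirna, strand="+", start=1001, flank=40):
    """Plus-orientation transcript carrying one 8mer site of `mirna`."""
    site_seq = revcomp_rna(mirna.sequence[:8]).replace("U", "T")
    tx = "CGATTGCACG" * (flank // 10) + site_seq + "GTCAATGGCT" * (flank // 10)
    ref = tx if strand == "+" else "".join(
        {"A": "T", "T": "A", "G": "C", "C": "G"}[b] for b in reversed(tx))
    region = TranscriptRegion(
        region_id="r1", chrom="chrS", start=start, end=start + len(tx) - 1,
        strand=strand, ref_seq=ref, gene="G1", kind="utr3",
    )
    return region, flank, flank + 8  # site tx span


class TestIntersect:
    def _site(self, region, tx_start, tx_end, mirna="mirA"):
        return BindingSite(region_id=region.region_id, mirna=mirna,
                           tx_start=tx_start, tx_end=tx_end, seed_class="8mer")

    def test_genomic_overlap_offsets(self):
        """Offsets match the printed worked examples: a variant 5 bases
        into a 21-base window, and another 11 bases into a 23-base one."""
        r1 = TranscriptRegion(region_id="ez", chrom="chr7", start=148508522,
                              end=148508942, strand="-", ref_seq="A" * 421,
                              gene="EZH2", kind="exon")
        site = self._site(r1, *_tx_span(r1, 148508722, 148508742))
        v = Variant(chrom="chr7", pos=148508727, ref="A", alt="T")
        ((_, _, off),) = intersect_variants_sites([v], [site], {"ez": r1})
        assert off == 148508727 - 148508722 == 5

        r2 = TranscriptRegion(region_id="bc", chrom="chr18", start=60793236,
                              end=60793658, strand="-", ref_seq="A" * 423,
                              gene="BCL2", kind="utr3")
        site2 = self._site(r2, *_tx_span(r2, 60793436, 60793458))
        v2 = Variant(chrom="chr18", pos=60793447, ref="A", alt="T")
        ((_, _, off2),) = intersect_variants_sites([v2], [site2], {"bc": r2})
        assert off2 == 11

    def test_one_base_upstream_is_no_pair(self):
        r1 = TranscriptRegion(region_id="ez", chrom="chr7", start=148508522,
                              end=148508942, strand="-", ref_seq="A" * 421)
        site = self._site(r1, *_tx_span(r1, 148508722, 148508742))
        v = Variant(chrom="chr7", pos=148508721, ref="A", alt="T")
        assert intersect_variants_sites([v], [site], {"ez": r1}) == []

    def test_deletion_span_overlap(self):
        r = TranscriptRegion(region_id="r", chrom="c", start=100, end=199,
                             strand="+", ref_seq="A" * 100)
        site = self._site(r, 50, 58)
        # deletion anchored at 148 deletes bases 149-150; site spans 150-158
        v = Variant(chrom="c", pos=148, ref="AAA", alt="A")
        assert len(intersect_variants_sites([v], [site], {"r": r})) == 1
        # insertion anchor at 149 does not reach the site
        v2 = Variant(chrom="c", pos=149, ref="A", alt="AT")
        assert intersect_variants_sites([v2], [site], {"r": r}) == []


def _tx_span(region, g_start, g_end):
    offs = sorted([region.tx_offset_of(g_start), region.tx_offset_of(g_end)])
    return offs[0], offs[1] + 1


class TestScoreMutationEffect:
    def test_seed_core_snv_disrupts(self, mirna_x):
        region, s, e = _region_with_site(mirna_x)
        site = BindingSite(region_id="r1", mirna=mirna_x.name, tx_start=s,
                           tx_end=e, seed_class="8mer")
        # mutate the central core base (tx offset s+3 pairs position 5)
        gpos = region.genomic_pos_of(s + 3)
        ref = region.ref_seq[gpos - region.start]
        v = Variant(chrom="chrS", pos=gpos, ref=ref,
                    alt={"A": "C", "C": "A", "G": "T", "T": "G"}[ref])
        call = score_mutation_effect(mirna_x, apply_variant(region, v), site, region)
        assert call.impact == "disrupted"
        assert call.delta_score < 0
        assert call.seed_mut == "none"

    def test_flank_snv_leaves_site_unchanged(self, mirna_x):
        region, s, e = _region_with_site(mirna_x)
        site = BindingSite(region_id="r1", mirna=mirna_x.name, tx_start=s,
                           tx_end=e, seed_class="8mer")
        gpos = region.genomic_pos_of(2)  # far upstream of the site window
        ref = region.ref_seq[gpos - region.start]
        v = Variant(chrom="chrS", pos=gpos, ref=ref,
                    alt="A" if ref != "A" else "C")
        call = score_mutation_effect(mirna_x, apply_variant(region, v), site, region)
        assert call.impact == "unchanged" and call.delta_score == 0

    def test_repairing_a_seed_mismatch_gains(self, mirna_x):
        """An SNV converting a seed mismatch into a match creates a
        qualifying site that the wildtype lacked."""
        region, s, e = _region_with_site(mirna_x)
        # break the site in the reference first
        broken = list(region.ref_seq)
        site_g = region.genomic_pos_of(s + 3) - region.start
        good = broken[site_g]
        broken[site_g] = {"A": "C", "C": "A", "G": "T", "T": "G"}[good]
        region2 = TranscriptRegion(
            region_id="r1", chrom="chrS", start=region.start, end=region.end,
            strand="+", ref_seq="".join(broken), gene="G1", kind="utr3",
        )
        site = BindingSite(region_id="r1", mirna=mirna_x.name, tx_start=s,
                           tx_end=e, seed_class="8mer")
        v = Variant(chrom="chrS", pos=region.start + site_g,
                    ref=broken[site_g], alt=good)
        call = score_mutation_effect(mirna_x, apply_variant(region2, v), site, region2)
        assert call.impact in ("gained", "strengthened")
        assert call.delta_score > 0

    def test_antisymmetry(self, mirna_x):
        """Swapping wildtype and mutant alleles negates the score change
        and maps disrupted <-> gained."""
        region, s, e = _region_with_site(mirna_x)
        site = BindingSite(region_id="r1", mirna=mirna_x.name, tx_start=s,
                           tx_end=e, seed_class="8mer")
        gpos = region.genomic_pos_of(s + 3)
        ref = region.ref_seq[gpos - region.start]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        v = Variant(chrom="chrS", pos=gpos, ref=ref, alt=alt)
        fwd = score_mutation_effect(mirna_x, apply_variant(region, v), site, region)
        ap = apply_variant(region, v)
        from mirsitemut.transcript_model import AllelePair
        swapped = AllelePair(region_id=ap.region_id, wt_seq=ap.mut_seq,
                             mut_seq=ap.wt_seq, variant=v, tx_offset=ap.tx_offset)
        rev = score_mutation_effect(mirna_x, swapped, site, region)
        assert rev.delta_score == -fwd.delta_score
        assert (fwd.impact, rev.impact) == ("disrupted", "gained")

    def test_no_site_context_is_error(self, mirna_x):
        region = TranscriptRegion(region_id="r1", chrom="chrS", start=1001,
                                  end=1030, strand="+", ref_seq="CA" * 15)
        site = BindingSite(region_id="r1", mirna=mirna_x.name, tx_start=5,
                           tx_end=13, seed_class="8mer")
        v = Variant(chrom="chrS", pos=1008, ref="A", alt="G")
        with pytest.raises(ValueError, match="no site context"):
            score_mutation_effect(mirna_x, apply_variant(region, v), site, region)


class TestSummaries:
    def test_region_kind_fraction(self, mirna_x):
        region, s, e = _region_with_site(mirna_x)
        site = BindingSite(region_id="r1", mirna=mirna_x.name, tx_start=s,
                           tx_end=e, seed_class="8mer")
        gpos = region.genomic_pos_of(s + 3)
        ref = region.ref_seq[gpos - region.start]
        v = Variant(chrom="chrS", pos=gpos, ref=ref,
                    alt={"A": "C", "C": "A", "G": "T", "T": "G"}[ref])
        call = score_mutation_effect(mirna_x, apply_variant(region, v), site, region)
        summary = summarize_impacts([call] * 9)
        assert summary.fraction_by_region_kind()["utr3"] == 1.0

    def test_empty_summary(self):
        s = summarize_impacts([])
        assert s.n_calls == 0 and s.by_gene == {}

    def test_printed_table_location_counts(self):
        """The 16 recurrent loci break down as 12 in 3' UTRs, 3 exonic
        and 1 intronic."""
        variants = [
            Variant(chrom=c, pos=p, ref=r, alt=a, gene=g, location=loc)
            for g, c, p, r, a, loc, _mir, _n in RECURRENT_LOCI
        ]
        assert summarize_locations(variants) == {"utr3": 12, "exon": 3, "intron": 1}
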