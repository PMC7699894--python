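import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsitemut.cohort_filter import (
    build_ledger,
    exclusivity_summary,
    mask_artifact_regions,
    qc_filter,
    subtract_controls,
    tally_recurrence,
)
from mirsitemut.formats_io import GenomeWindows, SampleMeta, Variant


def _v(pos=100, ref="A", alt="G", sample="S1", cov=1000, vaf=0.3, chrom="chr1", gene=""):
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample,
                   coverage=cov, vaf=vaf, gene=gene)


META = [
    SampleMeta("S1", "P1", "antFL"),
    SampleMeta("S2", "P1", "tFL"),
    SampleMeta("S3", "P2", "tFL"),
    SampleMeta("S4", "P3", "ntFL"),
    SampleMeta("POOL1", "POOL1", "control_pool"),
]


class TestQC:
    def test_thresholds_are_strict(self):
        kept, removed = qc_filter(
            [_v(cov=31, vaf=0.06), _v(cov=30, vaf=0.50), _v(cov=1000, vaf=0.05)]
        )
        assert len(kept) == 1 and kept[0].coverage == 31
        assert len(removed) == 2

    def test_missing_support_is_error(self):
        bad = Variant(chrom="chr1", pos=5, ref="A", alt="G", sample_id="SX")
        with pytest.raises(ValueError, match="SX"):
            qc_filter([bad])


class TestControls:
    def test_any_pool_removes_everywhere(self):
        tumor = [_v(sample="S1"), _v(sample="S2"), _v(sample="S3")]
        pool = [_v(sample="POOL1")]
        kept, removed = subtract_controls(tumor, pool)
        assert kept == [] and len(removed) == 3

    def test_allele_exact_matching(self):
        tumor = [_v(alt="G")]
        pool = [_v(alt="T", sample="POOL1")]
        kept, removed = subtract_controls(tumor, pool)
        assert len(kept) == 1 and removed == []

    def test_absent_from_pools_kept(self):
        kept, removed = subtract_controls([_v()], [])
        assert len(kept) == 1


class TestArtifactMask:
    def _ref(self, seq, chrom="chr1", start=1):
        gw = GenomeWindows()
        gw.add(chrom, start, seq)
        return gw

    def test_snv_adjacent_to_homopolymer_removed(self):
        #            123456789012345
        ref = self._ref("GCGTCAAAAAAGTCG")
        v = _v(pos=5, ref="C", alt="T")  # one base left of the A-run
        kept, removed = mask_artifact_regions([v], ref)
        assert removed == [v]

    def test_snv_inside_dinucleotide_repeat_removed(self):
        ref = self._ref("GCGATATATATGTCG")
        v = _v(pos=6, ref="T", alt="C")
        kept, removed = mask_artifact_regions([v], ref)
        assert removed == [v]

    def test_clean_context_kept(self):
        ref = self._ref("ACGTTACGGTCAGCA")
        v = _v(pos=8, ref="G", alt="A")
        kept, removed = mask_artifact_regions([v], ref)
        assert kept == [v]

    def test_short_run_not_masked(self):
        ref = self._ref("GCGTCAAAAGTCGGC")  # run of 4 < 5
        v = _v(pos=5, ref="C", alt="T")
        kept, _ = mask_artifact_regions([v], ref)
        assert kept == [v]


class TestRecurrence:
    def test_paired_samples_count_one_patient(self):
        vs = [_v(sample="S1"), _v(sample="S2")]  # antFL + tFL of P1
        counts = tally_recurrence(vs, META)
        assert list(counts.values()) == [1]

    def test_two_patients_is_recurrent(self):
        vs = [_v(sample="S1"), _v(sample="S3")]
        counts = tally_recurrence(vs, META)
        assert list(counts.values()) == [2]

    def test_duplicate_sample_record_does_not_inflate(self):
        vs = [_v(sample="S3"), _v(sample="S3"), _v(sample="S3")]
        assert list(tally_recurrence(vs, META).values()) == [1]

    def test_unmapped_sample_is_error(self):
        with pytest.raises(ValueError, match="metadata"):
            tally_recurrence([_v(sample="nope")], META)


class TestExclusivity:
    def test_mixed_carriers(self):
        vs = [
            _v(pos=1, sample="S2"),            # P1 (tFL) only -> exclusive
            _v(pos=2, sample="S3"), _v(pos=2, sample="S4"),  # both groups
        ]
        s = exclusivity_summary(vs, META)
        assert s.n_exclusive_tfl == 1 and s.n_variants == 2
        assert s.exclusive_fraction == 50.0
        assert (s.variants_in_tfl, s.variants_in_ntfl) == (2, 1)

    def test_all_shared_gives_zero(self):
        vs = [_v(pos=1, sample="S3"), _v(pos=1, sample="S4")]
        assert exclusivity_summary(vs, META).exclusive_fraction == 0.0

    def test_single_tfl_carrier_is_total(self):
        assert exclusivity_summary([_v(sample="S3")], META).exclusive_fraction == 100.0


class TestLedger:
    def test_empty_input(self):
        led = build_ledger([])
        assert led.n_input == led.n_remaining == 0

    def test_all_control_flagged(self):
        vs = [_v(pos=p) for p in (1, 2, 3)]
        pool = [Variant(chrom="chr1", pos=p, ref="A", alt="G", sample_id="POOL1",
                        coverage=500, vaf=0.4) for p in (1, 2, 3)]
        led = build_ledger(vs, control_variants=pool)
        assert led.n_remaining == 0
        assert all(f == "control" for f in led.per_variant_fate.values())

    @given(st.lists(st.tuples(st.integers(1, 30), st.integers(0, 2000),
                              st.floats(0, 1)), max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_conservation_under_random_inputs(self, rows):
        """Input count always equals the sum of all fate counts."""
        vs = [_v(pos=pos, cov=cov, vaf=round(vaf, 3), sample=f"S{i}")
              for i, (pos, cov, vaf) in enumerate(rows)]
        pool = [Variant(chrom="chr1", pos=p, ref="A", alt="G", coverage=99,
                        vaf=0.2, sample_id="POOL1") for p in range(1, 10)]
        led = build_ledger(vs, control_variants=pool, count_unique=False)
        assert led.n_input == len(vs)
        assert led.n_input == (led.n_remaining + led.n_removed_qc
                               + led.n_removed_controls + led.n_removed_artifact)

    def test_fate_is_first_removing_filter(self):
        """A record failing QC and present in controls is recorded as a
        QC removal (fixed stage order)."""
        v = _v(pos=7, cov=5, vaf=0.01)
        pool = [Variant(chrom="chr1", pos=7, ref="A", alt="G", coverage=99,
                        vaf=0.2, sample_id="POOL1")]
        led = build_ledger([v], control_variants=pool)
        assert led.per_variant_fate[(v.key, v.sample_id)] == "qc"
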