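"""Validation-cohort variant filtering and the staged ledger.

Stages run in a fixed order — QC thresholds, control-pool subtraction,
homopolymer/repeat artifact masking — and each variant is assigned the
fate of the first stage that removes it, so the ledger counts always
conserve the input count. Downstream summaries (recurrence across
patients, transformed-vs-nontransformed exclusivity) operate on the
surviving records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mirsitemut.formats_io import GenomeWindows, SampleMeta, Variant

VariantKey = tuple[str, int, str, str]


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def qc_filter(
    variants: Sequence[Variant], min_cov: int = 30, min_vaf: float = 0.05
) -> tuple[list[Variant], list[Variant]]:
    """Keep calls with coverage strictly above ``min_cov`` and VAF
    strictly above ``min_vaf``; both thresholds are exclusive."""
    kept, removed = [], []
    for v in variants:
        if v.coverage is None or v.vaf is None:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} {v.ref}/{v.alt} (sample {v.sample_id!r}) "
                "is missing coverage or VAF"
            )
        (kept if v.coverage > min_cov and v.vaf > min_vaf else removed).append(v)
    return kept, removed


def subtract_controls(
    variants: Sequence[Variant], control_variants: Iterable[Variant]
) -> tuple[list[Variant], list[Variant]]:
    """Remove any tumor call whose normalized (chrom, pos, ref, alt) key
    appears in ANY control pool; matching is allele-exact."""
    control_keys = {c.key for c in control_variants}
    kept, removed = [], []
    for v in variants:
        (removed if v.key in control_keys else kept).append(v)
    return kept, removed


def _find_artifact_mask(seq: str, min_homopolymer: int, repeat_units: int) -> list[tuple[int, int]]:
    """0-based half-open intervals of homopolymer runs and short tandem
    repeats (2-4 nt motif, >= ``repeat_units`` exact copies) in ``seq``."""
    spans: list[tuple[int, int]] = []
    for m in re.finditer(r"(A+|C+|G+|T+|U+|N+)", seq):
        if m.end() - m.start() >= min_homopolymer:
            spans.append((m.start(), m.end()))
    for unit in (2, 3, 4):
        i = 0
        while i + unit * repeat_units <= len(seq):
            motif = seq[i : i + unit]
            if len(set(motif)) == 1:  # covered by the homopolymer rule
                i += 1
                continue
            n = 1
            while seq[i + n * unit : i + (n + 1) * unit] == motif:
                n += 1
            if n >= repeat_units:
                spans.append((i, i + n * unit))
                i += n * unit
            else:
                i += 1
    return spans


def mask_artifact_regions(
    variants: Sequence[Variant],
    reference: GenomeWindows,
    min_homopolymer: int = 5,
    repeat_units: int = 3,
    pad: int = 1,
) -> tuple[list[Variant], list[Variant]]:
    """Remove calls whose changed bases lie within ``pad`` bases of a
    homopolymer run (>= ``min_homopolymer``) or a short tandem repeat
    (2-4 nt motif, >= ``repeat_units`` copies) in the local reference.

    These tracts are the characteristic error mode of semiconductor
    amplicon sequencing, where flow-space miscalls pile up as spurious
    indels next to base runs.
    """
    context = 2 * max(min_homopolymer, 4 * repeat_units) + pad
    kept, removed = [], []
    for v in variants:
        v_start, v_end = v.changed_span
        seq, g_start = reference.context(v.chrom, v_start, v_end, context)
        spans = _find_artifact_mask(seq.upper(), min_homopolymer, repeat_units)
        lo = v_start - g_start  # 0-based offsets of changed bases in seq
        hi = v_end - g_start
        hit = any(lo <= e - 1 + pad and s - pad <= hi for s, e in spans)
        (removed if hit else kept).append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# recurrence and exclusivity
# ---------------------------------------------------------------------------


def _meta_index(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def tally_recurrence(
    variants: Sequence[Variant], meta: Iterable[SampleMeta]
) -> dict[VariantKey, int]:
    """Distinct carrier PATIENTS per variant key (paired longitudinal
    samples of one patient count once). A variant is recurrent when its
    count is >= 2."""
    idx = _meta_index(meta)
    patients: dict[VariantKey, set[str]] = {}
    for v in variants:
        if v.sample_id not in idx:
            raise ValueError(f"sample {v.sample_id!r} has no metadata record")
        patients.setdefault(v.key, set()).add(idx[v.sample_id].patient_id)
    return {k: len(p) for k, p in patients.items()}


def tally_sample_recurrence(variants: Sequence[Variant]) -> dict[VariantKey, int]:
    """Distinct carrier samples per variant key (for comparability with
    sample-level reporting)."""
    samples: dict[VariantKey, set[str]] = {}
    for v in variants:
        samples.setdefault(v.key, set()).add(v.sample_id)
    return {k: len(s) for k, s in samples.items()}


def recurrent_keys(
    variants: Sequence[Variant], meta: Iterable[SampleMeta], min_patients: int = 2
) -> set[VariantKey]:
    counts = tally_recurrence(variants, meta)
    return {k for k, n in counts.items() if n >= min_patients}


@dataclass
class CohortSummary:
    """Group-level occurrence and exclusivity of the surviving variants.

    ``variants_in_tfl``/``variants_in_ntfl`` count variant-by-patient
    occurrences within each group; ``n_exclusive_tfl`` counts distinct
    variants carried only by transformed-FL patients."""

    n_tfl_cases: int
    n_ntfl_cases: int
    variants_in_tfl: int
    variants_in_ntfl: int
    n_exclusive_tfl: int
    n_variants: int

    @property
    def exclusive_fraction(self) -> float:
        """Percentage of surviving variants exclusive to tFL."""
        if self.n_variants == 0:
            return 0.0
        return 100.0 * self.n_exclusive_tfl / self.n_variants


def exclusivity_summary(
    kept_variants: Sequence[Variant], meta: Iterable[SampleMeta]
) -> CohortSummary:
    """Summarize tFL/ntFL occurrence of the surviving variants.

    A patient counts as tFL if any of their samples is labeled tFL or
    antFL (longitudinally sampled transforming cases); control pools
    never carry variants here.
    """
    idx = _meta_index(_as_list(meta))
    patient_group: dict[str, str] = {}
    for m in idx.values():
        if m.group in ("tFL", "antFL"):
            patient_group[m.patient_id] = "tFL"
        elif m.group == "ntFL":
            patient_group.setdefault(m.patient_id, "ntFL")
    carriers: dict[VariantKey, set[str]] = {}
    for v in kept_variants:
        if v.sample_id not in idx:
            raise ValueError(f"sample {v.sample_id!r} has no metadata record")
        carriers.setdefault(v.key, set()).add(idx[v.sample_id].patient_id)
    occ_tfl = occ_ntfl = exclusive = 0
    for key, pats in carriers.items():
        groups = {patient_group[p] for p in pats}
        occ_tfl += sum(1 for p in pats if patient_group[p] == "tFL")
        occ_ntfl += sum(1 for p in pats if patient_group[p] == "ntFL")
        if groups == {"tFL"}:
            exclusive += 1
    all_groups = set(patient_group.values())
    return CohortSummary(
        n_tfl_cases=sum(1 for g in patient_group.values() if g == "tFL"),
        n_ntfl_cases=sum(1 for g in patient_group.values() if g == "ntFL"),
        variants_in_tfl=occ_tfl,
        variants_in_ntfl=occ_ntfl,
        n_exclusive_tfl=exclusive,
        n_variants=len(carriers),
    )


def _as_list(meta: Iterable[SampleMeta]) -> list[SampleMeta]:
    return list(meta)


# ---------------------------------------------------------------------------
# the ledger
# ---------------------------------------------------------------------------

FATES = ("kept", "qc", "control", "artifact")


@dataclass
class FilterLedger:
    """Staged accounting of variant records through the filters."""

    n_input: int
    n_removed_qc: int
    n_removed_controls: int
    n_removed_artifact: int
    n_remaining: int
    n_genes_remaining: int
    per_variant_fate: dict[tuple[VariantKey, str], str] = field(default_factory=dict)
    kept: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_remaining
            + self.n_removed_qc
            + self.n_removed_controls
            + self.n_removed_artifact
        )
        if total != self.n_input:
            raise ValueError(
                f"ledger does not conserve records: input {self.n_input} != "
                f"sum of fates {total}"
            )

    def to_rows(self) -> list[dict]:
        return [
            {"stage": "input", "count": self.n_input},
            {"stage": "removed_qc", "count": self.n_removed_qc},
            {"stage": "removed_controls", "count": self.n_removed_controls},
            {"stage": "removed_artifact", "count": self.n_removed_artifact},
            {"stage": "remaining", "count": self.n_remaining},
            {"stage": "genes_remaining", "count": self.n_genes_remaining},
        ]


def build_ledger(
    variants: Sequence[Variant],
    control_variants: Iterable[Variant] = (),
    reference: GenomeWindows | None = None,
    meta: Iterable[SampleMeta] = (),
    min_cov: int = 30,
    min_vaf: float = 0.05,
    min_homopolymer: int = 5,
    repeat_units: int = 3,
    pad: int = 1,
    apply_qc: bool = True,
    count_unique: bool = True,
) -> FilterLedger:
    """Run the filter stages in order QC -> controls -> artifact and
    account for every record exactly once.

    With ``count_unique`` (default) the stage counts tally distinct
    variant keys — the unit the printed ledgers use — while
    ``per_variant_fate`` and ``kept`` keep per-record resolution. A
    record's fate is the first stage that removes it.
    """
    fates: dict[tuple[VariantKey, str], str] = {}
    current = list(variants)
    if apply_qc:
        current, removed_qc = qc_filter(current, min_cov=min_cov, min_vaf=min_vaf)
    else:
        removed_qc = []
    current, removed_ctrl = subtract_controls(current, control_variants)
    if reference is not None:
        current, removed_art = mask_artifact_regions(
            current, reference, min_homopolymer=min_homopolymer,
            repeat_units=repeat_units, pad=pad,
        )
    else:
        removed_art = []
    for group, fate in (
        (removed_qc, "qc"),
        (removed_ctrl, "control"),
        (removed_art, "artifact"),
        (current, "kept"),
    ):
        for v in group:
            record_id = (v.key, v.sample_id)
            if record_id in fates:
                raise ValueError(f"record {record_id} assigned two fates")
            fates[record_id] = fate

    def _count(group: list[Variant]) -> int:
        if count_unique:
            return len({v.key for v in group})
        return len(group)

    n_qc, n_ctrl, n_art, n_kept = map(_count, (removed_qc, removed_ctrl, removed_art, current))
    n_input = n_qc + n_ctrl + n_art + n_kept if count_unique else len(variants)
    genes = {v.gene or v.key[0] for v in current}
    return FilterLedger(
        n_input=n_input,
        n_removed_qc=n_qc,
        n_removed_controls=n_ctrl,
        n_removed_artifact=n_art,
        n_remaining=n_kept,
        n_genes_remaining=len(genes),
        per_variant_fate=fates,
        kept=current,
    )
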