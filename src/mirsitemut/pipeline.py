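"""End-to-end orchestration: predict -> intersect -> rescore -> filter.

`run_discovery` is the binding-site arm (site prediction with the
per-miRNA confidence filter, variant intersection and wildtype/mutant
rescoring); `run_validation` is the cohort arm (QC, control-pool
subtraction, artifact masking, recurrence and exclusivity). Both are
deterministic for fixed inputs and log per-stage counts through the
standard logging module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mirsitemut.cohort_filter import (
    CohortSummary,
    FilterLedger,
    build_ledger,
    exclusivity_summary,
    tally_recurrence,
)
from mirsitemut.formats_io import GenomeWindows, MatureMiRNA, SampleMeta, Variant
from mirsitemut.mutation_impact import (
    SiteImpactCall,
    intersect_variants_sites,
    score_mutation_effect,
)
from mirsitemut.site_prediction import (
    AlignParams,
    BindingSite,
    NNParams,
    predict_sites,
    rank_and_filter_sites,
)
from mirsitemut.synthetic_data import TruthTable
from mirsitemut.transcript_model import TranscriptRegion, apply_variant

log = logging.getLogger("mirsitemut")


@dataclass
class DiscoveryResult:
    sites_all: list[BindingSite]
    sites_kept: list[BindingSite]
    calls: list[SiteImpactCall]
    counts: dict[str, int] = field(default_factory=dict)


def run_discovery(
    variants: Sequence[Variant],
    regions: Sequence[TranscriptRegion],
    mirnas: Sequence[MatureMiRNA],
    params: AlignParams | None = None,
    nn: NNParams | None = None,
    keep_fraction: float = 0.75,
    site_policy: str = "both",
    tol: float = 0.0,
) -> DiscoveryResult:
    """Predict sites in every region, keep each miRNA's most confident
    fraction, and rescore every variant that touches a kept site."""
    if params is None:
        params = AlignParams()
    if nn is None:
        nn = NNParams()
    region_map: Mapping[str, TranscriptRegion] = {r.region_id: r for r in regions}

    sites_all: list[BindingSite] = []
    for region in regions:
        for mir in mirnas:
            try:
                sites_all.extend(
                    predict_sites(mir, region.tx_seq, region_id=region.region_id,
                                  params=params, nn=nn, site_policy=site_policy)
                )
            except Exception as exc:  # surface stage + record context
                raise RuntimeError(
                    f"site_prediction failed on region {region.region_id} x "
                    f"{mir.name}: {exc}"
                ) from exc
    sites_kept = rank_and_filter_sites(sites_all, keep_fraction=keep_fraction)
    log.info("predicted %d sites, %d kept after confidence filter",
             len(sites_all), len(sites_kept))

    # one call per unique (variant key, site); per-sample duplicates of
    # the same somatic event are scored once
    unique: dict[tuple, Variant] = {}
    for v in variants:
        unique.setdefault(v.key, v)
    pairs = intersect_variants_sites(list(unique.values()), sites_kept, region_map)
    log.info("%d variant keys, %d (variant, site) intersections",
             len(unique), len(pairs))

    calls: list[SiteImpactCall] = []
    for v, site, _off in pairs:
        region = region_map[site.region_id]
        try:
            ap = apply_variant(region, v)
            calls.append(
                score_mutation_effect(
                    _mirna_by_name(mirnas, site.mirna), ap, site, region,
                    params=params, nn=nn, tol=tol, site_policy=site_policy,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"mutation_impact failed on {v.chrom}:{v.pos} {v.ref}/{v.alt} "
                f"x {site.mirna}: {exc}"
            ) from exc
    log.info("%d impact calls", len(calls))
    return DiscoveryResult(
        sites_all=sites_all,
        sites_kept=sites_kept,
        calls=calls,
        counts={
            "n_regions": len(regions),
            "n_mirnas": len(mirnas),
            "n_sites": len(sites_all),
            "n_sites_kept": len(sites_kept),
            "n_variant_keys": len(unique),
            "n_intersections": len(pairs),
            "n_calls": len(calls),
        },
    )


def _mirna_by_name(mirnas: Sequence[MatureMiRNA], name: str) -> MatureMiRNA:
    for m in mirnas:
        if m.name == name:
            return m
    raise KeyError(f"unknown miRNA {name!r}")


@dataclass
class ValidationResult:
    ledger: FilterLedger
    summary: CohortSummary
    recurrence: dict[tuple, int]


def run_validation(
    variants: Sequence[Variant],
    meta: Sequence[SampleMeta],
    control_variants: Iterable[Variant] = (),
    reference: GenomeWindows | None = None,
    min_cov: int = 30,
    min_vaf: float = 0.05,
    min_homopolymer: int = 5,
    repeat_units: int = 3,
    pad: int = 1,
    apply_qc: bool = True,
) -> ValidationResult:
    """Run the staged cohort filters and summarize the survivors."""
    ledger = build_ledger(
        variants, control_variants=control_variants, reference=reference,
        meta=meta, min_cov=min_cov, min_vaf=min_vaf,
        min_homopolymer=min_homopolymer, repeat_units=repeat_units, pad=pad,
        apply_qc=apply_qc,
    )
    summary = exclusivity_summary(ledger.kept, meta)
    recurrence = tally_recurrence(ledger.kept, meta) if ledger.kept else {}
    log.info(
        "ledger: %d in, qc %d, controls %d, artifact %d, kept %d (%d genes); "
        "tFL-exclusive %d/%d (%.0f%%)",
        ledger.n_input, ledger.n_removed_qc, ledger.n_removed_controls,
        ledger.n_removed_artifact, ledger.n_remaining, ledger.n_genes_remaining,
        summary.n_exclusive_tfl, summary.n_variants, summary.exclusive_fraction,
    )
    return ValidationResult(ledger=ledger, summary=summary, recurrence=recurrence)


# ---------------------------------------------------------------------------
# recovery scoring against a simulation truth table
# ---------------------------------------------------------------------------


@dataclass
class RecoveryStats:
    n_planted_disrupting: int
    n_recovered: int
    n_background: int
    n_background_called: int

    @property
    def sensitivity(self) -> float:
        if self.n_planted_disrupting == 0:
            return float("nan")
        return self.n_recovered / self.n_planted_disrupting

    @property
    def false_call_rate(self) -> float:
        if self.n_background == 0:
            return 0.0
        return self.n_background_called / self.n_background


def evaluate_recovery(truth: TruthTable, calls: Sequence[SiteImpactCall]) -> RecoveryStats:
    """Score pipeline output against the simulation truth table.

    A planted disrupting mutation is recovered when some call for its
    variant key and miRNA reports ``disrupted``; a background mutation
    is a false call when it appears in the report at all.
    """
    called: dict[tuple, set[tuple[str, str]]] = {}
    for c in calls:
        called.setdefault(c.variant.key, set()).add((c.mirna, c.impact))
    n_planted = n_rec = n_bg = n_bg_called = 0
    for m in truth.mutations:
        if m.in_site and m.expected_impact == "disrupted":
            n_planted += 1
            if (m.mirna, "disrupted") in called.get(m.key, set()):
                n_rec += 1
        elif not m.in_site:
            n_bg += 1
            if m.key in called:
                n_bg_called += 1
    return RecoveryStats(
        n_planted_disrupting=n_planted,
        n_recovered=n_rec,
        n_background=n_bg,
        n_background_called=n_bg_called,
    )


# ---------------------------------------------------------------------------
# site/report serialization helpers used by the CLI
# ---------------------------------------------------------------------------


def write_sites_bed(
    sites: Iterable[BindingSite], path: str | Path,
    regions: Mapping[str, TranscriptRegion] | None = None,
) -> None:
    """Sites as BED6+ (genomic when regions are given, else
    region-relative), score column carrying the alignment score."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.region_id, s.tx_start, s.mirna)):
            if regions is not None:
                region = regions[s.region_id]
                g_start, g_end = region.genomic_span_of(s.tx_start, s.tx_end)
                chrom, start0, end0, strand = region.chrom, g_start - 1, g_end, region.strand
            else:
                chrom, start0, end0, strand = s.region_id, s.tx_start, s.tx_end, "+"
            fh.write(
                f"{chrom}\t{start0}\t{end0}\t{s.mirna}\t{s.align_score:g}\t{strand}"
                f"\t{s.seed_class}\t{s.delta_g:.3f}\t{s.confidence_rank:.4f}\n"
            )


def write_ledger_tsv(ledger: FilterLedger, summary: CohortSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for row in ledger.to_rows():
            fh.write(f"{row['stage']}\t{row['count']}\n")
        fh.write(f"n_tfl_cases\t{summary.n_tfl_cases}\n")
        fh.write(f"n_ntfl_cases\t{summary.n_ntfl_cases}\n")
        fh.write(f"variants_in_tfl\t{summary.variants_in_tfl}\n")
        fh.write(f"variants_in_ntfl\t{summary.variants_in_ntfl}\n")
        fh.write(f"n_exclusive_tfl\t{summary.n_exclusive_tfl}\n")
        fh.write(f"exclusive_fraction_pct\t{summary.exclusive_fraction:.1f}\n")
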