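"""Intersection of somatic variants with predicted miRNA-binding sites
and wildtype-vs-mutant rescoring.

For every (variant, site, miRNA) triple the wildtype and mutant alleles
are rescored over a fixed window (the site interval widened by one
miRNA length on each side, so sites gained next to the original
footprint are seen) and the change is classified:

``disrupted``     mutant allele no longer carries a qualifying site
``weakened``      site retained but alignment score fell
``unchanged``     no score change
``strengthened``  alignment score rose
``gained``        wildtype had no qualifying site, mutant does
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mirsitemut.formats_io import MatureMiRNA, Variant
from mirsitemut.site_prediction import (
    AlignParams,
    BindingSite,
    NNParams,
    predict_sites,
)
from mirsitemut.transcript_model import AllelePair, TranscriptRegion

IMPACT_CLASSES = ("disrupted", "weakened", "unchanged", "strengthened", "gained")


@dataclass
class SiteImpactCall:
    """Scored effect of one variant on one predicted site."""

    variant: Variant
    site: BindingSite
    mirna: str
    offset_in_site: int
    wt_score: float
    mut_score: float
    wt_dg: float
    mut_dg: float
    impact: str
    seed_wt: str = "none"
    seed_mut: str = "none"
    gene: str = ""
    region_kind: str = ""

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")

    @property
    def delta_score(self) -> float:
        return self.mut_score - self.wt_score

    @property
    def delta_dg(self) -> float:
        return self.mut_dg - self.wt_dg

    def to_row(self) -> dict:
        v = self.variant
        return {
            "gene": self.gene or v.gene,
            "region_kind": self.region_kind,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "mirna": self.mirna,
            "site_start": self.site.tx_start,
            "site_end": self.site.tx_end,
            "offset": self.offset_in_site,
            "seed_wt": self.seed_wt,
            "seed_mut": self.seed_mut,
            "score_wt": self.wt_score,
            "score_mut": self.mut_score,
            "dg_wt": round(self.wt_dg, 3),
            "dg_mut": round(self.mut_dg, 3),
            "impact": self.impact,
        }


def intersect_variants_sites(
    variants: Iterable[Variant],
    sites: Iterable[BindingSite],
    regions: Mapping[str, TranscriptRegion],
) -> list[tuple[Variant, BindingSite, int]]:
    """Pair variants with the predicted sites they touch.

    A pair is emitted iff any changed reference base of the variant
    (substituted base, deleted span, or insertion anchor) overlaps the
    site's genomic interval, both inclusive. The reported offset is the
    genomic distance from the site's genomic start to the variant's
    anchored position.
    """
    site_spans = []
    for s in sites:
        region = regions[s.region_id]
        g_start, g_end = region.genomic_span_of(s.tx_start, s.tx_end)
        site_spans.append((s, region.chrom, g_start, g_end))
    out = []
    for v in variants:
        v_start, v_end = v.changed_span
        for s, chrom, g_start, g_end in site_spans:
            if chrom == v.chrom and v_start <= g_end and g_start <= v_end:
                out.append((v, s, v.pos - g_start))
    return out


def score_mutation_effect(
    mirna: MatureMiRNA,
    pair: AllelePair,
    site: BindingSite,
    region: TranscriptRegion,
    params: AlignParams | None = None,
    nn: NNParams | None = None,
    tol: float = 0.0,
    site_policy: str = "both",
) -> SiteImpactCall:
    """Rescore a site under the wildtype and mutant alleles.

    Both alleles are scanned over the site interval +- one miRNA length
    (adjusted for indel length shifts on the mutant side) and the best
    qualifying site per allele is compared. ``tol`` is the dead zone
    below which a score change counts as ``unchanged``.
    """
    if params is None:
        params = AlignParams()
    if nn is None:
        nn = NNParams()
    w = len(mirna.sequence)
    lo = max(0, site.tx_start - w)
    hi = min(len(pair.wt_seq), site.tx_end + w)
    shift = len(pair.mut_seq) - len(pair.wt_seq)
    wt_window = pair.wt_seq[lo:hi]
    mut_window = pair.mut_seq[lo : max(lo, hi + shift)]

    wt_sites = predict_sites(mirna, wt_window, region_id=pair.region_id,
                             params=params, nn=nn, site_policy=site_policy)
    mut_sites = predict_sites(mirna, mut_window, region_id=pair.region_id,
                              params=params, nn=nn, site_policy=site_policy)
    wt_best = max(wt_sites, key=lambda s: s.align_score, default=None)
    mut_best = max(mut_sites, key=lambda s: s.align_score, default=None)
    if wt_best is None and mut_best is None:
        raise ValueError(
            f"no site context: variant {pair.variant.chrom}:{pair.variant.pos} "
            f"has no qualifying {mirna.name} site in either allele"
        )

    wt_score = wt_best.align_score if wt_best else 0.0
    mut_score = mut_best.align_score if mut_best else 0.0
    wt_dg = wt_best.delta_g if wt_best else 0.0
    mut_dg = mut_best.delta_g if mut_best else 0.0
    if wt_best is not None and mut_best is None:
        impact = "disrupted"
    elif wt_best is None:
        impact = "gained"
    elif mut_score - wt_score < -tol:
        impact = "weakened"
    elif mut_score - wt_score > tol:
        impact = "strengthened"
    else:
        impact = "unchanged"

    offset = max(0, min(pair.tx_offset - site.tx_start, site.tx_end - site.tx_start - 1))
    return SiteImpactCall(
        variant=pair.variant,
        site=site,
        mirna=mirna.name,
        offset_in_site=offset,
        wt_score=wt_score,
        mut_score=mut_score,
        wt_dg=wt_dg,
        mut_dg=mut_dg,
        impact=impact,
        seed_wt=wt_best.seed_class if wt_best else "none",
        seed_mut=mut_best.seed_class if mut_best else "none",
        gene=region.gene or pair.variant.gene,
        region_kind=region.kind,
    )


@dataclass
class ImpactSummary:
    """Tallies of impact calls by region kind, gene and impact class."""

    n_calls: int = 0
    by_region_kind: dict[str, int] = field(default_factory=dict)
    by_gene: dict[str, int] = field(default_factory=dict)
    by_impact: dict[str, int] = field(default_factory=dict)

    def fraction_by_region_kind(self) -> dict[str, float]:
        if self.n_calls == 0:
            return {}
        return {k: v / self.n_calls for k, v in self.by_region_kind.items()}


def summarize_impacts(calls: Iterable[SiteImpactCall]) -> ImpactSummary:
    """Per-region-kind, per-gene and per-class tallies of impact calls."""
    summary = ImpactSummary()
    for c in calls:
        summary.n_calls += 1
        kind = c.region_kind or "unknown"
        summary.by_region_kind[kind] = summary.by_region_kind.get(kind, 0) + 1
        gene = c.gene or c.variant.gene or "unknown"
        summary.by_gene[gene] = summary.by_gene.get(gene, 0) + 1
        summary.by_impact[c.impact] = summary.by_impact.get(c.impact, 0) + 1
    return summary


def summarize_locations(variants: Iterable[Variant]) -> dict[str, int]:
    """Location tallies straight from annotated variant records (used
    for tables that print a Location column per variant)."""
    out: dict[str, int] = {}
    for v in variants:
        key = _normalize_location(v.location)
        out[key] = out.get(key, 0) + 1
    return out


def _normalize_location(loc: str) -> str:
    key = loc.strip().lower().replace("'", "").replace("′", "")
    aliases = {
        "3 utr": "utr3", "3utr": "utr3", "utr3": "utr3",
        "5 utr": "utr5", "5utr": "utr5", "utr5": "utr5",
        "exon": "exon", "intron": "intron",
    }
    return aliases.get(key, key or "unknown")
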