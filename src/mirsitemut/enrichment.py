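"""Gene-set overrepresentation by the hypergeometric upper tail.

A generic stand-in for commercial ontology tools: given a hit list
(e.g. genes with filtered miRNA-binding-site variants), a named gene
set and a universe, it reports P[X >= overlap] for X hypergeometric
(exact summation via scipy's survival function, no approximation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_universe: int
    n_set: int
    n_hits: int
    n_overlap: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_set, self.n_hits):
            raise ValueError("overlap exceeds set or hit-list size")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def _norm(genes: Iterable[str]) -> set[str]:
    return {g.strip().upper() for g in genes if g.strip()}


def hypergeometric_enrichment(
    hits: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric overrepresentation test.

    Gene names are case-normalized. Hits and the gene set must be
    subsets of the universe; offenders are listed in the error.
    """
    hits_s, set_s, uni = _norm(hits), _norm(gene_set), _norm(universe)
    missing = sorted(hits_s - uni)
    if missing:
        raise ValueError(f"hit genes absent from universe: {missing}")
    missing_set = sorted(set_s - uni)
    if missing_set:
        raise ValueError(f"gene-set members absent from universe: {missing_set}")
    n_overlap = len(hits_s & set_s)
    # P[X >= k] for X ~ Hypergeom(M=universe, n=set, N=draws)
    p = float(hypergeom.sf(n_overlap - 1, len(uni), len(set_s), len(hits_s)))
    return EnrichmentResult(
        set_name=set_name,
        n_universe=len(uni),
        n_set=len(set_s),
        n_hits=len(hits_s),
        n_overlap=n_overlap,
        p_value=min(p, 1.0),
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def enrich_gene_sets(
    hits: Iterable[str],
    gene_sets: dict[str, Sequence[str]],
    universe: Iterable[str],
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Test a hit list against every gene set; optionally apply
    Benjamini-Hochberg correction across sets (off by default, matching
    how single-ontology p-values are usually reported)."""
    hits = list(hits)
    universe = list(universe)
    results = [
        hypergeometric_enrichment(hits, members, universe, set_name=name)
        for name, members in gene_sets.items()
    ]
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        _, padj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        results = [
            EnrichmentResult(r.set_name, r.n_universe, r.n_set, r.n_hits,
                             r.n_overlap, min(float(q), 1.0))
            for r, q in zip(results, padj)
        ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))
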