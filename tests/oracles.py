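"""Independent reference implementations used only to check the
package: a pair-anchored enumeration of local alignments (a different
formulation from the production Gotoh dynamic program) and an
exhaustive-draw hypergeometric tail."""

from __future__ import annotations

from itertools import combinations
from math import comb

from mirsitemut.formats_io import to_rna
from mirsitemut.site_prediction import AlignParams, pair_type


def _gap(length: int, params: AlignParams) -> float:
    if length == 0:
        return 0.0
    return params.gap_open + (length - 1) * params.gap_extend


def _sub(params: AlignParams, t_base: str, m_base: str, m_pos: int) -> float:
    raw = {"wc": params.match, "gu": params.gu_wobble,
           "none": params.mismatch}[pair_type(t_base, m_base)]
    return raw * params.seed_weight if 2 <= m_pos <= 8 else raw


def oracle_align_score(mirna_seq: str, window: str, params: AlignParams | None = None) -> float:
    """Best local alignment score by enumerating every chain of paired
    columns: an alignment is a sequence of (target, miRNA) column pairs,
    strictly increasing on both axes, with affine gap costs for the
    skipped stretches between consecutive pairs."""
    if params is None:
        params = AlignParams()
    x = to_rna(window)
    y = to_rna(mirna_seq)[::-1]  # 3'->5'
    L = len(mirna_seq)
    n, k = len(x), len(y)
    best = 0.0
    ending: list[list[float]] = [[0.0] * k for _ in range(n)]
    for i in range(n):
        for j in range(k):
            m_pos = L - j
            base = _sub(params, x[i], y[j], m_pos)
            b = base
            for ki in range(i):
                for lj in range(j):
                    cand = (ending[ki][lj] + _gap(i - ki - 1, params)
                            + _gap(j - lj - 1, params) + base)
                    if cand > b:
                        b = cand
            ending[i][j] = b
            if b > best:
                best = b
    return best


def oracle_hypergeom_tail(n_universe: int, n_set: int, n_hits: int, k: int) -> float:
    """P[overlap >= k] by enumerating every draw of ``n_hits`` items
    from a universe in which ``n_set`` items are marked."""
    marked = set(range(n_set))
    total = comb(n_universe, n_hits)
    good = sum(
        1 for draw in combinations(range(n_universe), n_hits)
        if len(marked.intersection(draw)) >= k
    )
    return good / total
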