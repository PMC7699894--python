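"""miRNA target-site prediction.

Three layers, mirroring how canonical target predictors work:

1. **Seed-match classification** — exact Watson-Crick complementarity of
   the target to miRNA positions 2-7/2-8, giving the canonical site
   classes ``8mer > 7mer-m8 > 7mer-A1 > 6mer``. G:U wobbles never
   satisfy a seed class.
2. **Weighted local duplex alignment** — a Smith-Waterman-style local
   alignment of the miRNA (3'->5') against the target window (5'->3')
   in which columns pairing miRNA seed positions 2-8 are up-weighted,
   matches score +5, G:U wobbles +1, mismatches -3, and gaps are affine
   (open -8, extend -2). The alignment score is the confidence measure
   used for ranking.
3. **Nearest-neighbor free energy** — duplex stability as a duplex
   initiation penalty plus tabulated stacking terms over consecutive
   base pairs, with a flat penalty per interior loop/bulge event.

A reported site must both carry a seed class and reach the minimum
alignment score (``site_policy="both"``, the default); either
requirement can be dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from mirsitemut.formats_io import MatureMiRNA, to_rna

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp_rna(seq: str) -> str:
    return "".join(WC[c] for c in reversed(seq))


def pair_type(target_base: str, mirna_base: str) -> str:
    """``wc``, ``gu`` or ``none`` for one target:miRNA base opposition."""
    if WC.get(target_base) == mirna_base:
        return "wc"
    if {target_base, mirna_base} == {"G", "U"}:
        return "gu"
    return "none"


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class AlignParams:
    """Scoring scheme for the weighted local duplex alignment.

    ``seed_weight`` multiplies the substitution score of any column
    that pairs a base of miRNA positions 2-8 (gap columns are never
    weighted). ``min_score`` is the reporting threshold for a site.
    """

    match: float = 5.0
    gu_wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_weight: float = 4.0
    min_score: float = 80.0

    def __post_init__(self) -> None:
        if self.seed_weight < 1:
            raise ValueError("seed_weight must be >= 1")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


# Watson-Crick nearest-neighbor stacking free energies, kcal/mol at 37 C
# (Turner 2004 set). 10 unique duplex stacks; the 180-degree rotation
# symmetry 5'XY/3'WZ == 5'ZW/3'YX fills in all 16 target-strand
# dinucleotides. Any stack involving a G:U pair gets one flat term.
_WC_STACKS_UNIQUE = {
    "AA": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08,
    "CA": -2.11,
    "GU": -2.24,
    "GA": -2.35,
    "CG": -2.36,
    "GG": -3.26,
    "GC": -3.42,
}


def _expand_stacks() -> dict[tuple[str, str], float]:
    """Full (target 5'XY3', opposing bases read 3'->5') -> dG table for
    the 16 Watson-Crick stacks."""
    table: dict[tuple[str, str], float] = {}
    for top, dg in _WC_STACKS_UNIQUE.items():
        bottom = WC[top[0]] + WC[top[1]]
        table[(top, bottom)] = dg
        # rotated duplex: new top = reversed bottom, new bottom = reversed top
        table[(bottom[::-1], top[::-1])] = dg
    return table


@dataclass
class NNParams:
    """Nearest-neighbor duplex thermodynamics.

    ``stacks`` maps (target 5'XY3', opposing miRNA bases read 3'->5')
    to a stacking free energy; stacks touching a G:U pair fall back to
    ``gu_stack``. ``initiation`` is the duplex initiation penalty and
    ``loop_penalty`` a flat cost per interior loop or bulge event.
    All in kcal/mol.
    """

    stacks: dict[tuple[str, str], float] = field(default_factory=_expand_stacks)
    gu_stack: float = -0.5
    initiation: float = 4.09
    loop_penalty: float = 3.0

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.stacks.values()) or self.gu_stack >= 0:
            raise ValueError("all stacking terms must be negative")
        if self.initiation <= 0:
            raise ValueError("initiation penalty must be positive")

    def stack_energy(self, target_dinuc: str, mirna_dinuc: str) -> float:
        """Energy of stacking pairs (x1:m1) on (x2:m2); ``target_dinuc``
        = x1x2 read 5'->3', ``mirna_dinuc`` = m1m2 read 3'->5'."""
        key = (target_dinuc, mirna_dinuc)
        if key in self.stacks:
            return self.stacks[key]
        ok1 = pair_type(target_dinuc[0], mirna_dinuc[0]) != "none"
        ok2 = pair_type(target_dinuc[1], mirna_dinuc[1]) != "none"
        if ok1 and ok2:
            return self.gu_stack
        raise KeyError(f"not a stackable pair of pairs: {key}")


SEED_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SEED_PRECEDENCE = {c: i for i, c in enumerate(SEED_CLASSES)}


@dataclass
class BindingSite:
    """A predicted miRNA target site in one transcript region.

    ``tx_start``/``tx_end`` are 0-based half-open offsets in transcript
    orientation. ``confidence_rank`` is the per-miRNA fractional rank
    (1/n = best) filled in by :func:`rank_and_filter_sites`.
    """

    region_id: str
    mirna: str
    tx_start: int
    tx_end: int
    seed_class: str = "none"
    align_score: float = 0.0
    delta_g: float = 0.0
    confidence_rank: float = 0.0

    def __post_init__(self) -> None:
        if self.tx_end <= self.tx_start:
            raise ValueError("tx_end must exceed tx_start")
        if self.seed_class not in SEED_CLASSES and self.seed_class != "none":
            raise ValueError(f"unknown seed class {self.seed_class!r}")

    def overlaps(self, other: "BindingSite") -> bool:
        return (
            self.region_id == other.region_id
            and self.mirna == other.mirna
            and self.tx_start < other.tx_end
            and other.tx_start < self.tx_end
        )


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------


def find_seed_matches(
    mirna: MatureMiRNA, target: str, region_id: str = ""
) -> list[BindingSite]:
    """Locate canonical seed matches of ``mirna`` in a transcript-
    orientation target sequence.

    Every maximal site is reported once with the strongest applicable
    class. Site coordinates cover the matched target bases (the 8mer
    spans 8 nt including the A opposite miRNA position 1).
    """
    t = to_rna(target)
    if len(t) < 6:
        return []
    m = mirna.sequence
    core = revcomp_rna(m[1:7])  # target 5'->3' opposite miRNA 2-7
    m8_opp = WC[m[7]]  # target base pairing miRNA position 8 (5' of core)
    sites: list[BindingSite] = []
    for i in range(len(t) - 5):
        if t[i : i + 6] != core:
            continue
        has_m8 = i >= 1 and t[i - 1] == m8_opp
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            cls, s, e = "8mer", i - 1, i + 7
        elif has_m8:
            cls, s, e = "7mer-m8", i - 1, i + 6
        elif has_a1:
            cls, s, e = "7mer-A1", i, i + 7
        else:
            cls, s, e = "6mer", i, i + 6
        sites.append(
            BindingSite(region_id=region_id, mirna=mirna.name, tx_start=s,
                        tx_end=e, seed_class=cls)
        )
    return _merge_overlapping(sites)


def _merge_overlapping(sites: list[BindingSite]) -> list[BindingSite]:
    """Keep the strongest representative among overlapping same-miRNA
    sites (strongest seed class, then score, then leftmost)."""
    ranked = sorted(
        sites,
        key=lambda s: (SEED_PRECEDENCE.get(s.seed_class, 99), -s.align_score, s.tx_start),
    )
    kept: list[BindingSite] = []
    for s in ranked:
        if not any(s.overlaps(k) for k in kept):
            kept.append(s)
    return sorted(kept, key=lambda s: s.tx_start)


# ---------------------------------------------------------------------------
# weighted local duplex alignment
# ---------------------------------------------------------------------------


@dataclass
class DuplexAlignment:
    """Result of aligning a miRNA against a target window.

    ``pairs`` lists (0-based target offset in the window, 1-based miRNA
    position) for every paired column, ordered by target offset (miRNA
    positions descend: the strands are antiparallel). ``pairing`` is
    the standard mid-line notation: ``|`` Watson-Crick, ``:`` G:U.
    """

    score: float
    pairs: list[tuple[int, int]]
    target_span: tuple[int, int]  # half-open window offsets covered
    aligned_target: str = ""
    aligned_mirna: str = ""
    pairing: str = ""


def _substitution(params: AlignParams, t_base: str, m_base: str, m_pos: int) -> float:
    pt = pair_type(t_base, m_base)
    raw = {"wc": params.match, "gu": params.gu_wobble, "none": params.mismatch}[pt]
    return raw * params.seed_weight if 2 <= m_pos <= 8 else raw


def align_duplex(
    mirna: MatureMiRNA | str, target_window: str, params: AlignParams | None = None
) -> DuplexAlignment:
    """Best local alignment of the miRNA (3'->5') against the window
    (5'->3') under ``params``, Gotoh affine-gap dynamic programming.

    Columns pairing miRNA positions 2-8 carry ``seed_weight``; gap
    columns are unweighted. Returns score 0 and no pairs for an empty
    window or when nothing scores above 0. ``mirna`` may be a raw
    sequence string (any length) or a :class:`MatureMiRNA`.
    """
    if params is None:
        params = AlignParams()
    x = to_rna(target_window)
    m = mirna.sequence if isinstance(mirna, MatureMiRNA) else to_rna(mirna)
    y = m[::-1]  # 3'->5'
    n, k = len(x), len(y)
    if n == 0 or k == 0:
        return DuplexAlignment(score=0.0, pairs=[], target_span=(0, 0))
    NEG = -math.inf
    # state matrices: P ends in a paired column, GX in a target-side gap
    # (unpaired target base), GY in a miRNA-side gap
    P = [[NEG] * (k + 1) for _ in range(n + 1)]
    GX = [[NEG] * (k + 1) for _ in range(n + 1)]
    GY = [[NEG] * (k + 1) for _ in range(n + 1)]
    ptr: dict[tuple[str, int, int], tuple[str, int, int] | None] = {}

    def mpos(j: int) -> int:  # 1-based miRNA position of y[j-1]
        return len(m) - (j - 1)

    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, k + 1):
            sub = _substitution(params, x[i - 1], y[j - 1], mpos(j))
            cands = [
                (0.0, None),
                (P[i - 1][j - 1], ("P", i - 1, j - 1)),
                (GX[i - 1][j - 1], ("GX", i - 1, j - 1)),
                (GY[i - 1][j - 1], ("GY", i - 1, j - 1)),
            ]
            val, src = max(cands, key=lambda c: c[0])
            P[i][j] = sub + val
            ptr[("P", i, j)] = src
            gx_cands = [
                (P[i - 1][j] + params.gap_open, ("P", i - 1, j)),
                (GX[i - 1][j] + params.gap_extend, ("GX", i - 1, j)),
                (GY[i - 1][j] + params.gap_open, ("GY", i - 1, j)),
            ]
            GX[i][j], ptr[("GX", i, j)] = max(gx_cands, key=lambda c: c[0])
            gy_cands = [
                (P[i][j - 1] + params.gap_open, ("P", i, j - 1)),
                (GY[i][j - 1] + params.gap_extend, ("GY", i, j - 1)),
                (GX[i][j - 1] + params.gap_open, ("GX", i, j - 1)),
            ]
            GY[i][j], ptr[("GY", i, j)] = max(gy_cands, key=lambda c: c[0])
            if P[i][j] > best:
                best, best_ij = P[i][j], (i, j)

    if best_ij is None:
        return DuplexAlignment(score=0.0, pairs=[], target_span=(0, 0))

    # traceback (local alignments start and end on paired columns)
    pairs: list[tuple[int, int]] = []
    cols: list[tuple[str | None, str | None, str]] = []  # (target, mirna, mid)
    state: tuple[str, int, int] | None = ("P", *best_ij)
    while state is not None:
        kind, i, j = state
        if kind == "P":
            pt = pair_type(x[i - 1], y[j - 1])
            pairs.append((i - 1, mpos(j)))
            cols.append((x[i - 1], y[j - 1], {"wc": "|", "gu": ":"}.get(pt, " ")))
        elif kind == "GX":
            cols.append((x[i - 1], None, " "))
        else:
            cols.append((None, y[j - 1], " "))
        state = ptr[(kind, i, j)]
    pairs.reverse()
    cols.reverse()
    t_lo = min(t for t, _ in pairs)
    t_hi = max(t for t, _ in pairs) + 1
    return DuplexAlignment(
        score=best,
        pairs=pairs,
        target_span=(t_lo, t_hi),
        aligned_target="".join(c[0] or "-" for c in cols),
        aligned_mirna="".join(c[1] or "-" for c in cols),
        pairing="".join(c[2] for c in cols),
    )


# ---------------------------------------------------------------------------
# nearest-neighbor free energy
# ---------------------------------------------------------------------------


def duplex_free_energy(
    pairs: Sequence[tuple[int, int]],
    mirna: MatureMiRNA | str,
    target_window: str,
    params: NNParams | None = None,
) -> float:
    """Nearest-neighbor free energy (kcal/mol) of a duplex given as a
    list of (target offset, miRNA position) pairs.

    dG = initiation + sum of stacking terms over consecutive pairs
    (target offsets and miRNA positions both stepping by one,
    antiparallel) + ``loop_penalty`` per interior loop/bulge event.
    Raises ValueError when the pairing has no pairs.
    """
    if params is None:
        params = NNParams()
    x = to_rna(target_window)
    m = mirna.sequence if isinstance(mirna, MatureMiRNA) else to_rna(mirna)
    # mismatched alignment columns are not base pairs: they contribute
    # as loop interruptions, not stacks
    ordered = sorted(
        (t, p) for t, p in pairs if pair_type(x[t], m[p - 1]) != "none"
    )
    if not ordered:
        raise ValueError("no duplex: pairing contains zero pairs")
    dg = params.initiation
    for (t1, p1), (t2, p2) in zip(ordered, ordered[1:]):
        if t2 == t1 + 1 and p2 == p1 - 1:  # stacked
            dg += params.stack_energy(x[t1 : t1 + 2], m[p1 - 1] + m[p2 - 1])
        else:  # interior loop or bulge between helices
            dg += params.loop_penalty
    return dg


# ---------------------------------------------------------------------------
# full prediction and confidence filtering
# ---------------------------------------------------------------------------


def predict_sites(
    mirna: MatureMiRNA,
    target: str,
    region_id: str = "",
    params: AlignParams | None = None,
    nn: NNParams | None = None,
    site_policy: str = "both",
) -> list[BindingSite]:
    """Predict binding sites of one miRNA in one transcript sequence.

    ``site_policy``: ``both`` (default) requires a canonical seed match
    AND alignment score >= ``min_score``; ``seed_only`` keeps every
    seed match regardless of score; ``align_only`` keeps any local
    alignment >= ``min_score`` whether or not a seed class applies.
    """
    if site_policy not in ("both", "seed_only", "align_only"):
        raise ValueError(f"unknown site_policy {site_policy!r}")
    if params is None:
        params = AlignParams()
    if nn is None:
        nn = NNParams()
    t = to_rna(target)
    out: list[BindingSite] = []

    if site_policy in ("both", "seed_only"):
        for site in find_seed_matches(mirna, t, region_id=region_id):
            lo = max(0, site.tx_start - len(mirna.sequence))
            hi = min(len(t), site.tx_end + len(mirna.sequence))
            aln = align_duplex(mirna, t[lo:hi], params)
            if aln.pairs:
                site.align_score = aln.score
                site.delta_g = duplex_free_energy(aln.pairs, mirna, t[lo:hi], nn)
            if site_policy == "both" and site.align_score < params.min_score:
                continue
            out.append(site)
    else:  # align_only: scan overlapping windows
        w = max(2 * len(mirna.sequence), 30)
        step = max(1, len(mirna.sequence) // 2)
        starts = list(range(0, max(1, len(t) - w + 1), step))
        if starts and starts[-1] + w < len(t):
            starts.append(len(t) - w)
        for lo in starts or [0]:
            window = t[lo : lo + w]
            aln = align_duplex(mirna, window, params)
            if aln.score < params.min_score or not aln.pairs:
                continue
            s, e = aln.target_span
            site = BindingSite(
                region_id=region_id, mirna=mirna.name, tx_start=lo + s,
                tx_end=lo + e, seed_class="none", align_score=aln.score,
                delta_g=duplex_free_energy(aln.pairs, mirna, window, nn),
            )
            out.append(site)
        out = _merge_overlapping(out)
    return sorted(out, key=lambda s: s.tx_start)


def rank_and_filter_sites(
    sites: Iterable[BindingSite], keep_fraction: float = 0.75
) -> list[BindingSite]:
    """Per-miRNA confidence filter: retain the ``ceil(keep_fraction*n)``
    highest-scoring sites of each miRNA; ties at the cutoff are all
    retained. ``confidence_rank`` is set to the fractional rank
    (rank/n, ties sharing the best rank of the tie group)."""
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must lie in (0, 1]")
    by_mirna: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_mirna.setdefault(s.mirna, []).append(s)
    kept: list[BindingSite] = []
    for group in by_mirna.values():
        group = sorted(group, key=lambda s: -s.align_score)
        n = len(group)
        n_keep = math.ceil(keep_fraction * n)
        cutoff = group[n_keep - 1].align_score
        rank_of_score: dict[float, int] = {}
        for idx, s in enumerate(group, start=1):
            rank_of_score.setdefault(s.align_score, idx)
        for s in group:
            if s.align_score >= cutoff:
                s.confidence_rank = rank_of_score[s.align_score] / n
                kept.append(s)
    return sorted(kept, key=lambda s: (s.region_id, s.mirna, s.tx_start))
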