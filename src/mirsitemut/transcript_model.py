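"""Genomic <-> transcript coordinate mapping and variant application.

All prediction happens in transcript orientation (the 5'->3' mRNA
frame, where miRNA pairing is defined); the genomic plus-strand frame
is I/O only. A :class:`TranscriptRegion` stores its reference sequence
in genomic orientation and exposes the transcript-orientation view;
:func:`apply_variant` produces the wildtype/mutant sequence pair that
target prediction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from mirsitemut.formats_io import (
    GenomeWindows,
    Interval,
    Variant,
    normalize_alleles,
    revcomp_dna,
    to_dna,
)

REGION_KINDS = ("utr3", "utr5", "exon", "intron")


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the region sequence.

    A hard error by design: a silently wrong strand or offset is the
    main failure mode of this kind of analysis.
    """


@dataclass(frozen=True)
class TranscriptRegion:
    """A stranded genomic interval with its reference sequence.

    ``ref_seq`` is always stored in genomic plus-strand orientation;
    ``tx_seq`` gives the transcript (mRNA 5'->3') view.
    """

    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    ref_seq: str
    gene: str = ""
    kind: str = "utr3"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if len(self.ref_seq) != self.end - self.start + 1:
            raise ValueError(
                f"{self.region_id}: ref_seq length {len(self.ref_seq)} != span "
                f"{self.end - self.start + 1}"
            )
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def tx_seq(self) -> str:
        """Reference sequence in transcript orientation (mRNA 5'->3')."""
        return self.ref_seq if self.strand == "+" else revcomp_dna(self.ref_seq)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def tx_offset_of(self, pos: int) -> int:
        """0-based transcript offset of genomic position ``pos``."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside {self.region_id}")
        return pos - self.start if self.strand == "+" else self.end - pos

    def genomic_pos_of(self, tx_offset: int) -> int:
        """Inverse of :meth:`tx_offset_of`."""
        if not 0 <= tx_offset < len(self):
            raise ValueError(f"tx_offset {tx_offset} outside {self.region_id}")
        return self.start + tx_offset if self.strand == "+" else self.end - tx_offset

    def genomic_span_of(self, tx_start: int, tx_end: int) -> tuple[int, int]:
        """Genomic 1-based inclusive span of the half-open transcript
        interval [tx_start, tx_end)."""
        if not (0 <= tx_start < tx_end <= len(self)):
            raise ValueError("transcript interval outside region")
        a = self.genomic_pos_of(tx_start)
        b = self.genomic_pos_of(tx_end - 1)
        return (a, b) if a <= b else (b, a)


def region_from_interval(
    interval: Interval,
    genome: GenomeWindows,
    gene: str = "",
    kind: str = "utr3",
    region_id: str | None = None,
) -> TranscriptRegion:
    """Build a TranscriptRegion by pulling its sequence from a reference."""
    seq = genome.fetch(interval.chrom, interval.start, interval.end)
    return TranscriptRegion(
        region_id=region_id or interval.name or f"{interval.chrom}:{interval.start}-{interval.end}",
        chrom=interval.chrom,
        start=interval.start,
        end=interval.end,
        strand=interval.strand,
        ref_seq=seq,
        gene=gene or interval.name,
        kind=kind,
    )


def write_region_table(regions: Iterable[TranscriptRegion], path: str | Path) -> None:
    """Region table TSV: region_id, chrom, start, end, strand, gene, kind
    (1-based inclusive coordinates; sequence comes from the reference)."""
    with open(path, "w") as fh:
        fh.write("#region_id\tchrom\tstart\tend\tstrand\tgene\tkind\n")
        for r in regions:
            fh.write(
                f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t"
                f"{r.gene}\t{r.kind}\n"
            )


def read_region_table(path: str | Path, genome: GenomeWindows) -> list[TranscriptRegion]:
    """Inverse of :func:`write_region_table`, pulling sequences from the
    reference."""
    out: list[TranscriptRegion] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rid, chrom, start, end, strand, gene, kind = line.rstrip("\n").split("\t")
            out.append(
                TranscriptRegion(
                    region_id=rid, chrom=chrom, start=int(start), end=int(end),
                    strand=strand,
                    ref_seq=genome.fetch(chrom, int(start), int(end)),
                    gene=gene, kind=kind,
                )
            )
    return out


def genomic_to_transcript(
    region: TranscriptRegion, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Map a single-base genomic substitution into transcript frame.

    On the "+" strand offsets increase with ``pos`` and bases are
    unchanged; on "-" the offset axis reverses and both alleles are
    complemented (e.g. a genomic T/A on a minus-strand gene is a
    transcript A>T).
    """
    if not region.contains(pos):
        raise ValueError(
            f"position {region.chrom}:{pos} outside region "
            f"{region.region_id} ({region.start}-{region.end})"
        )
    ref, alt = ref.upper(), alt.upper()
    observed = region.ref_seq[pos - region.start]
    if observed != ref:
        raise ReferenceMismatchError(
            f"{region.region_id} at {region.chrom}:{pos}: expected REF {ref!r}, "
            f"reference sequence has {observed!r}"
        )
    off = region.tx_offset_of(pos)
    if region.strand == "+":
        return off, ref, alt
    comp = str.maketrans("ACGTN", "TGCAN")
    return off, ref.translate(comp), alt.translate(comp)


@dataclass(frozen=True)
class AllelePair:
    """Wildtype and mutant transcript-orientation sequences for one
    variant in one region."""

    region_id: str
    wt_seq: str
    mut_seq: str
    variant: Variant
    tx_offset: int  # 0-based offset of the first changed base in wt_seq

    def __post_init__(self) -> None:
        if self.wt_seq == self.mut_seq:
            raise ValueError("wildtype and mutant sequences are identical")
        if not 0 <= self.tx_offset < len(self.wt_seq):
            raise ValueError("tx_offset outside wildtype sequence")


def apply_variant(region: TranscriptRegion, variant: Variant) -> AllelePair:
    """Apply a variant to a region, returning transcript-orientation
    wildtype and mutant sequences.

    The substitution/insertion/deletion is applied in the genomic
    frame (where the anchored alleles live) and both sequences are then
    re-oriented, so plus- and minus-strand constructions agree up to
    reverse complement.
    """
    pos, ref, alt = normalize_alleles(variant.pos, variant.ref, variant.alt)
    ref_end = pos + len(ref) - 1
    if not (region.contains(pos) and region.contains(ref_end)):
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} {variant.ref}/{variant.alt} "
            f"not contained in region {region.region_id}"
        )
    i = pos - region.start
    observed = region.ref_seq[i : i + len(ref)]
    if observed != ref:
        raise ReferenceMismatchError(
            f"{region.region_id} at {region.chrom}:{pos}: expected REF {ref!r}, "
            f"reference sequence has {observed!r}"
        )
    mut_genomic = region.ref_seq[:i] + alt + region.ref_seq[i + len(ref) :]
    wt = region.tx_seq
    mut = mut_genomic if region.strand == "+" else revcomp_dna(mut_genomic)
    tx_offset = _first_difference(wt, mut)
    return AllelePair(
        region_id=region.region_id, wt_seq=wt, mut_seq=mut, variant=variant,
        tx_offset=tx_offset,
    )


def _first_difference(wt: str, mut: str) -> int:
    for k in range(min(len(wt), len(mut))):
        if wt[k] != mut[k]:
            return k
    # difference only beyond the shorter sequence (pure tail indel)
    return min(len(mut), len(wt) - 1)


def extract_flanked_window(
    region: TranscriptRegion, tx_start: int, tx_end: int, flank: int = 150
) -> tuple[str, int, int]:
    """Return the site sequence plus up to ``flank`` transcript bases on
    each side, truncated at the region boundary.

    ``tx_start``/``tx_end`` are 0-based half-open transcript offsets.
    Returns (window sequence, obtained upstream flank, obtained
    downstream flank).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seq = region.tx_seq
    if not (0 <= tx_start < tx_end <= len(seq)):
        raise ValueError("site outside region")
    lo = max(0, tx_start - flank)
    hi = min(len(seq), tx_end + flank)
    return seq[lo:hi], tx_start - lo, hi - tx_end


def write_allele_pair_fastas(
    pairs: Iterable[AllelePair], wt_path: str | Path, mut_path: str | Path
) -> None:
    """Emit the paired wildtype/mutant FASTA intermediates with headers
    ``<region_id>|<chrom>:<pos>:<ref>/<alt>|wt`` and ``...|mut``."""
    with open(wt_path, "w") as wt_fh, open(mut_path, "w") as mut_fh:
        for p in pairs:
            v = p.variant
            tag = f"{p.region_id}|{v.chrom}:{v.pos}:{v.ref}/{v.alt}"
            wt_fh.write(f">{tag}|wt\n{to_dna(p.wt_seq)}\n")
            mut_fh.write(f">{tag}|mut\n{to_dna(p.mut_seq)}\n")
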