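"""Readers/writers for the standard formats the pipeline touches.

All genomic coordinates are 1-based inclusive internally (the style used
in printed variant tables, e.g. ``chr7:148508727``); BED input is
converted at the boundary and converted back on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

_RNA = set("ACGU")
_DNA = set("ACGT")

COMPLEMENT_DNA = str.maketrans("ACGTNacgtn", "TGCANtgcan")
COMPLEMENT_RNA = str.maketrans("ACGUNacgun", "UGCANugcan")


class ParseError(ValueError):
    """Malformed record in an input file."""


def to_rna(seq: str) -> str:
    """Normalize a nucleotide string to the upper-case RNA alphabet."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(COMPLEMENT_DNA)[::-1]


# ---------------------------------------------------------------------------
# mature miRNAs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA, 5'->3', RNA alphabet.

    The seed is the 7-nt subsequence at positions 2-8 (1-based from the
    5' end); it is derived from ``sequence`` and never stored
    independently.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not (15 <= len(self.sequence) <= 30):
            raise ValueError(
                f"miRNA {self.name!r}: length {len(self.sequence)} outside [15, 30]"
            )
        bad = set(self.sequence) - _RNA
        if bad:
            raise ValueError(f"miRNA {self.name!r}: non-RNA characters {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based) of the mature sequence."""
        return self.sequence[1:8]


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read mature miRNA sequences from FASTA (miRBase-style headers).

    Sequences may use T or U; they are normalized to RNA. The name is
    the first whitespace-delimited token of the header. Duplicate names
    or non-ACGTU characters raise :class:`ParseError`.
    """
    out: list[MatureMiRNA] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ParseError(f"duplicate miRNA name {name!r} in {path}")
        seen.add(name)
        seq = str(rec.seq).upper()
        for off, ch in enumerate(seq):
            if ch not in _RNA and ch != "T":
                raise ParseError(
                    f"record {name!r}: non-ACGTU character {ch!r} at offset {off}"
                )
        out.append(MatureMiRNA(name=name, sequence=to_rna(seq)))
    return out


def write_mirna_fasta(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mirnas:
            fh.write(f">{m.name}\n{m.sequence}\n")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A somatic change with optional per-sample support.

    ``pos`` is the 1-based genomic position of the first REF base
    (anchored-first-base representation for indels, as in VCF).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    coverage: int | None = None
    vaf: float | None = None
    gene: str = ""
    location: str = ""  # region kind annotation, e.g. "utr3"/"exon"/"intron"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"REF == ALT ({self.ref!r}) at {self.chrom}:{self.pos}")
        _, nref, nalt = normalize_alleles(self.pos, self.ref, self.alt)
        if len(nref) > 1 and len(nalt) > 1:
            raise ValueError(
                f"unsupported complex variant {self.ref}/{self.alt} at "
                f"{self.chrom}:{self.pos} (no shared anchor)"
            )
        if self.coverage is not None and self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError("vaf must lie in [0, 1]")

    @property
    def kind(self) -> str:
        """One of ``snv``, ``insertion`` or ``deletion`` (after
        normalization; exactly one holds for any accepted variant)."""
        _, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        if len(ref) == 1 and len(alt) == 1:
            return "snv"
        if len(alt) > len(ref):
            return "insertion"
        return "deletion"

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Canonical (chrom, pos, ref, alt) identity after normalization."""
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)

    @property
    def changed_span(self) -> tuple[int, int]:
        """Genomic interval (1-based inclusive) of the changed REF bases.

        For an SNV this is the single substituted base, for a deletion
        the span of deleted bases, and for an insertion the anchor base
        (the inserted bases have no reference coordinates).
        """
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        if len(ref) == len(alt) == 1:
            return (pos, pos)
        if len(ref) > len(alt):  # deletion: bases after the anchor
            return (pos + 1, pos + len(ref) - 1)
        return (pos, pos)  # insertion: anchor base only


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix, keeping an anchor base for indels.

    Produces the minimal left-anchored representation used as the
    canonical variant key for control subtraction and recurrence.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


_COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<pos>\d+)$")


def _parse_coord_tsv(path: str | Path) -> Iterator[Variant]:
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = re.split(r"[\t ]+", line.strip())
            if line.startswith("#"):
                header = [f.lstrip("#").lower() for f in fields]
                continue
            m = _COORD_RE.match(fields[0])
            if m is None:
                raise ParseError(
                    f"{path}:{lineno}: malformed position token {fields[0]!r}"
                )
            if len(fields) < 2 or "/" not in fields[1]:
                raise ParseError(f"{path}:{lineno}: missing REF/ALT token")
            ref, _, alt = fields[1].partition("/")
            extra: dict[str, str] = {}
            if header is not None:
                extra = dict(zip(header[2:], fields[2:]))
            else:
                for key, val in zip(("sample_id", "coverage", "vaf", "gene"), fields[2:]):
                    extra[key] = val
            try:
                yield Variant(
                    chrom=m["chrom"],
                    pos=int(m["pos"]),
                    ref=ref.upper(),
                    alt=alt.upper(),
                    sample_id=extra.get("sample_id", ""),
                    coverage=int(extra["coverage"]) if extra.get("coverage") else None,
                    vaf=float(extra["vaf"]) if extra.get("vaf") else None,
                    gene=extra.get("gene", ""),
                    location=extra.get("location", ""),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def _parse_vcf(path: str | Path) -> Iterator[Variant]:
    """VCF v4.x via cyvcf2/htslib: splits multi-allelic records, emits
    one Variant per carrier sample with per-sample DP and AF (from
    FORMAT AF, or AD when AF is absent)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples: list[str] = list(vcf.samples)
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            if alt in (".", "<NON_REF>", "*"):
                continue
            if not samples:
                yield Variant(chrom=rec.CHROM, pos=rec.POS,
                              ref=rec.REF.upper(), alt=alt.upper())
                continue
            def _fmt(key: str):
                try:
                    return rec.format(key)
                except KeyError:
                    return None

            dp, af, ad = _fmt("DP"), _fmt("AF"), _fmt("AD")
            for si, sample in enumerate(samples):
                alleles = rec.genotypes[si][:-1]  # drop phasing flag
                if (ai + 1) not in alleles:
                    continue
                cov = int(dp[si][0]) if dp is not None and dp[si][0] >= 0 else None
                vaf: float | None = None
                if af is not None:
                    row = af[si]
                    vaf = float(row[ai] if ai < len(row) else row[0])
                elif ad is not None and cov:
                    vaf = int(ad[si][ai + 1]) / cov
                yield Variant(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF.upper(),
                              alt=alt.upper(), sample_id=sample, coverage=cov,
                              vaf=vaf)


def read_variants(path: str | Path, dialect: str = "coord_tsv") -> list[Variant]:
    """Read somatic variants from ``coord_tsv`` (``chrN:pos REF/ALT``
    rows, case-insensitive alleles) or plain-text ``vcf``."""
    if dialect == "coord_tsv":
        return list(_parse_coord_tsv(path))
    if dialect == "vcf":
        return list(_parse_vcf(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_variants_tsv(variants: Iterable[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#position\tmutation\tsample_id\tcoverage\tvaf\tgene\tlocation\n")
        for v in variants:
            cov = "" if v.coverage is None else str(v.coverage)
            vaf = "" if v.vaf is None else f"{v.vaf:.4f}"
            fh.write(
                f"{v.chrom}:{v.pos}\t{v.ref}/{v.alt}\t{v.sample_id}\t{cov}\t{vaf}\t"
                f"{v.gene}\t{v.location}\n"
            )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

GROUPS = ("antFL", "tFL", "ntFL", "control_pool")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    group: str
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV: sample_id, patient_id, group[, timepoint]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            out.append(
                SampleMeta(
                    sample_id=fields[0],
                    patient_id=fields[1],
                    group=fields[2],
                    timepoint=fields[3] if len(fields) > 3 else "",
                )
            )
    return out


def write_sample_meta(meta: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\tpatient_id\tgroup\ttimepoint\n")
        for m in meta:
            fh.write(f"{m.sample_id}\t{m.patient_id}\t{m.group}\t{m.timepoint}\n")


# ---------------------------------------------------------------------------
# stranded intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """Stranded genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")


def read_regions(path: str | Path) -> list[Interval]:
    """Read stranded intervals from BED6 (0-based half-open) or an
    internal TSV (1-based inclusive, ``chrom start end strand [name]``).

    The dialect is chosen per file: files ending in ``.bed`` are BED;
    anything else is the internal TSV. Both land in the internal 1-based
    inclusive representation (BED converted losslessly).
    """
    is_bed = str(path).endswith(".bed")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = re.split(r"[\t ]+", line.strip())
            try:
                if is_bed:
                    if len(fields) < 6:
                        raise ValueError("BED6 requires 6 columns")
                    chrom, start0, end0, name, _score, strand = fields[:6]
                    start, end = int(start0) + 1, int(end0)
                    if int(end0) <= int(start0):
                        raise ValueError("zero-length or inverted BED interval")
                else:
                    chrom, start_s, end_s, strand = fields[:4]
                    strand = {"−": "-"}.get(strand, strand)
                    name = fields[4] if len(fields) > 4 else ""
                    start, end = int(start_s), int(end_s)
                out.append(Interval(chrom=chrom, start=start, end=end, name=name, strand=strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_regions_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED6 (lossless inverse of :func:`read_regions`)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# windowed reference sequence
# ---------------------------------------------------------------------------


class GenomeWindows:
    """Reference sequence stored as (possibly partial) windows per
    chromosome, addressed in genomic 1-based coordinates.

    FASTA headers of the form ``chrom:start-end`` place a record at
    genomic offset ``start``; a bare ``chrom`` header starts at 1. This
    lets fixtures carry real-scale coordinates without a full genome.
    """

    def __init__(self) -> None:
        self._windows: dict[str, list[tuple[int, str]]] = {}

    def add(self, chrom: str, start: int, seq: str) -> None:
        self._windows.setdefault(chrom, []).append((start, seq.upper()))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return reference bases for chrom:start-end (1-based inclusive).

        Raises KeyError if the span is not covered by a single window.
        """
        for wstart, seq in self._windows.get(chrom, []):
            if wstart <= start and end <= wstart + len(seq) - 1:
                return seq[start - wstart : end - wstart + 1]
        raise KeyError(f"no reference window covering {chrom}:{start}-{end}")

    def context(self, chrom: str, start: int, end: int, flank: int) -> tuple[str, int]:
        """Fetch ``flank`` bases around [start, end], truncated at the
        containing window; returns (sequence, genomic start of it)."""
        for wstart, seq in self._windows.get(chrom, []):
            wend = wstart + len(seq) - 1
            if wstart <= start and end <= wend:
                s = max(start - flank, wstart)
                e = min(end + flank, wend)
                return seq[s - wstart : e - wstart + 1], s
        raise KeyError(f"no reference window covering {chrom}:{start}-{end}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeWindows":
        gw = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            m = re.match(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$", rec.id)
            if m:
                gw.add(m["chrom"], int(m["start"]), str(rec.seq))
            else:
                gw.add(rec.id, 1, str(rec.seq))
        return gw

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._windows):
                for start, seq in self._windows[chrom]:
                    if start == 1 and len(self._windows[chrom]) == 1:
                        fh.write(f">{chrom}\n{seq}\n")
                    else:
                        fh.write(f">{chrom}:{start}-{start + len(seq) - 1}\n{seq}\n")


# ---------------------------------------------------------------------------
# impact report I/O (column contract shared with mutation_impact)
# ---------------------------------------------------------------------------

IMPACT_COLUMNS = [
    "gene",
    "region_kind",
    "chrom",
    "pos",
    "ref",
    "alt",
    "mirna",
    "site_start",
    "site_end",
    "offset",
    "seed_wt",
    "seed_mut",
    "score_wt",
    "score_mut",
    "dg_wt",
    "dg_mut",
    "impact",
]


def write_impact_report(calls: Iterable, path: str | Path) -> None:
    """Write SiteImpactCalls as a TSV with a deterministic column order
    and a stable (chrom, pos, mirna) sort; round-trips via
    :func:`read_impact_report`."""
    import pandas as pd

    rows = [c.to_row() for c in calls]
    df = pd.DataFrame(rows, columns=IMPACT_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "pos", "mirna"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def write_annotated_vcf(calls: Iterable, path: str | Path) -> None:
    """Impact calls as a minimal annotated VCF (INFO keys MIRSITE,
    SITECLASS, DSCORE, DDG, IMPACT)."""
    rows = sorted(calls, key=lambda c: (c.variant.chrom, c.variant.pos, c.mirna))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, desc in (
            ("MIRSITE", "miRNA predicted to bind the overlapping site"),
            ("SITECLASS", "Canonical seed-match class of the wildtype site"),
            ("DSCORE", "Mutant minus wildtype duplex alignment score"),
            ("DDG", "Mutant minus wildtype duplex free energy (kcal/mol)"),
            ("IMPACT", "Binding-change classification"),
        ):
            num, typ = ("1", "Float") if key in ("DSCORE", "DDG") else ("1", "String")
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in rows:
            v = c.variant
            info = (f"MIRSITE={c.mirna};SITECLASS={c.seed_wt};"
                    f"DSCORE={c.delta_score:g};DDG={c.delta_dg:.3f};IMPACT={c.impact}")
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")


def read_impact_report(path: str | Path):
    import pandas as pd

    return pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("gene", "region_kind", "chrom", "ref", "alt", "mirna",
                                 "seed_wt", "seed_mut", "impact")},
        keep_default_na=False,
    )
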