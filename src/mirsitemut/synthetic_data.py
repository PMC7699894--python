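"""Self-contained synthetic inputs for every pipeline stage.

Three generators:

* :func:`generate_cohort` — a randomized cohort with planted
  miRNA-response elements, in-site and background somatic mutations,
  per-call coverage/VAF, control-pool contamination and homopolymer
  tracts, plus a truth table for recovery scoring.
* :func:`make_study_fixtures` — the printed worked-example records: 16
  recurrently mutated loci and 6 luciferase-candidate site windows,
  with a synthetic reference consistent with the printed alleles and
  strands (flanking bases are seeded random; real-genome content is
  deliberately not reproduced, so these fixtures exercise coordinate
  and strand logic only).
* :func:`make_validation_fixture` — a validation-cohort input whose
  staged filtering yields the published ledger arithmetic
  (85 variants -> 36 removed in controls -> 26 removed as artifacts ->
  23 kept in 21 genes, 10 of them exclusive to transformed cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mirsitemut.cohort_filter import mask_artifact_regions
from mirsitemut.formats_io import (
    GenomeWindows,
    MatureMiRNA,
    SampleMeta,
    Variant,
    revcomp_dna,
    to_dna,
)
from mirsitemut.site_prediction import find_seed_matches, revcomp_rna
from mirsitemut.transcript_model import TranscriptRegion

BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration and truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Knobs of the cohort simulator.

    Cohort structure defaults mirror the study design this pipeline is
    meant for: 34 transformed-FL patients sampled longitudinally (one
    antecedent and one post-transformation sample each), 21
    non-transforming patients, five healthy control pools, amplicon
    coverage in the thousands and somatic VAFs centred around 0.25.
    """

    n_genes: int = 20
    utr_len_range: tuple[int, int] = (300, 700)
    n_mirnas: int = 10
    planted_sites_per_gene: int = 1
    p_site_mutation: float = 0.5
    p_background_mutation_per_kb: float = 1.0
    n_patients_tfl: int = 34
    n_patients_ntfl: int = 21
    n_control_pools: int = 5
    coverage_mean: float = 2270.0
    coverage_dispersion: float = 5.0  # negative-binomial shape
    vaf_alpha: float = 2.0
    vaf_beta: float = 6.0
    homopolymer_rate: float = 1.0  # planted runs per kb of UTR
    control_fraction: float = 0.4  # fraction of variant keys copied into pools
    artifact_fraction: float = 0.3  # fraction of background variants in tracts
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_site_mutation", "control_fraction", "artifact_fraction"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_genes, self.n_mirnas, self.n_control_pools) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PlantedSite:
    gene: str
    mirna: str
    region_id: str
    tx_start: int
    tx_end: int
    seed_class: str = "8mer"


@dataclass
class PlantedMutation:
    key: tuple[str, int, str, str]
    in_site: bool
    expected_impact: str  # "disrupted" for seed hits, "unchanged" for background
    mirna: str
    carrier_patients: list[str]
    in_controls: bool = False
    in_artifact_tract: bool = False


@dataclass
class TruthTable:
    sites: list[PlantedSite] = field(default_factory=list)
    mutations: list[PlantedMutation] = field(default_factory=list)


@dataclass
class SimResult:
    reference: GenomeWindows
    regions: list[TranscriptRegion]
    mirnas: list[MatureMiRNA]
    variants: list[Variant]
    control_variants: list[Variant]
    meta: list[SampleMeta]
    truth: TruthTable


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, max_run: int = 10) -> str:
    out: list[str] = []
    for _ in range(length):
        b = BASES[rng.integers(4)]
        while len(out) >= max_run and all(x == b for x in out[-max_run:]):
            b = BASES[rng.integers(4)]
        out.append(b)
    return "".join(out)


def _simulate_mirnas(rng: np.random.Generator, n: int) -> list[MatureMiRNA]:
    """Random 22-mers with pairwise-distinct seeds whose 6-nt core does
    not recur inside the miRNA's own full-length complement."""
    mirnas: list[MatureMiRNA] = []
    seeds: set[str] = set()
    while len(mirnas) < n:
        seq = "".join("ACGU"[rng.integers(4)] for _ in range(22))
        seed = seq[1:8]
        if seed in seeds or len(set(seq[1:7])) < 2:
            continue
        core = revcomp_rna(seq[1:7])
        full_site = revcomp_rna(seq)
        if full_site.count(core) != 1:
            continue
        seeds.add(seed)
        mirnas.append(MatureMiRNA(name=f"sim-miR-{len(mirnas) + 1}", sequence=seq))
    return mirnas


def _cohort_meta(n_tfl: int, n_ntfl: int, n_pools: int) -> list[SampleMeta]:
    meta: list[SampleMeta] = []
    for i in range(1, n_tfl + 1):
        pid = f"PT{i:03d}"
        meta.append(SampleMeta(f"{pid}-A", pid, "antFL", timepoint="pre"))
        meta.append(SampleMeta(f"{pid}-T", pid, "tFL", timepoint="post"))
    for i in range(1, n_ntfl + 1):
        pid = f"PN{i:03d}"
        meta.append(SampleMeta(f"{pid}-S", pid, "ntFL"))
    for i in range(1, n_pools + 1):
        meta.append(SampleMeta(f"POOL{i}", f"POOL{i}", "control_pool"))
    return meta


def _draw_support(rng: np.random.Generator, cfg: SimConfig) -> tuple[int, float]:
    shape = cfg.coverage_dispersion
    p = shape / (shape + cfg.coverage_mean)
    cov = int(rng.negative_binomial(shape, p))
    vaf = float(rng.beta(cfg.vaf_alpha, cfg.vaf_beta))
    return cov, min(max(vaf, 0.0), 1.0)


# ---------------------------------------------------------------------------
# the cohort simulator
# ---------------------------------------------------------------------------


def generate_cohort(cfg: SimConfig) -> SimResult:
    """Simulate a full validation-cohort input set.

    Planted sites are full-length complements of the simulated miRNA
    embedded in otherwise random UTR sequence (so every planted site of
    a miRNA attains that miRNA's maximal alignment score, which makes
    planted-site recovery a deterministic property rather than a race
    against random 3'-pairing bonuses). Site mutations hit seed-core
    positions and are verified at generation time to abolish the seed
    match; background mutations avoid planted sites. Identical seeds
    give identical outputs.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    mirnas = _simulate_mirnas(rng, cfg.n_mirnas)
    meta = _cohort_meta(cfg.n_patients_tfl, cfg.n_patients_ntfl, cfg.n_control_pools)
    tumor_patients = sorted({m.patient_id for m in meta if m.group != "control_pool"})
    samples_of: dict[str, list[str]] = {}
    for m in meta:
        if m.group != "control_pool":
            samples_of.setdefault(m.patient_id, []).append(m.sample_id)

    reference = GenomeWindows()
    regions: list[TranscriptRegion] = []
    truth = TruthTable()
    variant_specs: list[tuple[str, int, str, str, str, bool, str]] = []
    # (chrom, pos, ref, alt, gene, in_site, mirna)

    lo, hi = cfg.utr_len_range
    for g in range(cfg.n_genes):
        gene = f"SG{g + 1:03d}"
        chrom = f"sim_{gene}"
        strand = "+" if g % 2 == 0 else "-"
        length = int(rng.integers(lo, hi + 1))
        tx = list(_random_seq(rng, length, max_run=4))

        # sprinkle homopolymer tracts
        n_runs = rng.poisson(cfg.homopolymer_rate * length / 1000.0)
        tract_spans: list[tuple[int, int]] = []
        for _ in range(n_runs):
            run_len = int(rng.integers(6, 10))
            start = int(rng.integers(0, max(1, length - run_len)))
            base = BASES[rng.integers(4)]
            tx[start : start + run_len] = base * run_len
            tract_spans.append((start, start + run_len))

        # plant sites (round-robin over miRNAs), full-length complements
        planted: list[tuple[int, int, MatureMiRNA]] = []
        site_counter = g * cfg.planted_sites_per_gene
        for s in range(cfg.planted_sites_per_gene):
            mir = mirnas[(site_counter + s) % len(mirnas)]
            site_seq = to_dna(revcomp_rna(mir.sequence))
            w = len(site_seq)
            for _ in range(200):  # find a spot clear of other plantings/tracts
                pos = int(rng.integers(w, length - 2 * w))
                if all(pos + w <= a or b <= pos for a, b, _ in
                       [(a - w, b + w, m) for a, b, m in planted]) and all(
                       pos + w <= a or b <= pos for a, b in tract_spans):
                    break
            else:
                raise ValueError(f"UTR of {gene} too short for requested sites")
            tx[pos : pos + w] = site_seq
            planted.append((pos, pos + w, mir))

        # remove accidental extra seed cores of the planted miRNAs
        tx_str = "".join(tx)
        for pos, end, mir in planted:
            core = to_dna(revcomp_rna(mir.sequence[1:7]))
            search = 0
            while True:
                hit = tx_str.find(core, search)
                if hit < 0:
                    break
                if not (pos <= hit and hit + 6 <= end):
                    repl = [b for b in BASES if b != tx_str[hit + 2]]
                    tx_str = tx_str[: hit + 2] + repl[int(rng.integers(3))] + tx_str[hit + 3 :]
                    continue
                search = hit + 1
        tx = list(tx_str)

        region_start = 1000 + int(rng.integers(0, 500))
        genomic = "".join(tx) if strand == "+" else revcomp_dna("".join(tx))
        region = TranscriptRegion(
            region_id=f"{gene}_utr3", chrom=chrom, start=region_start,
            end=region_start + length - 1, strand=strand, ref_seq=genomic,
            gene=gene, kind="utr3",
        )
        reference.add(chrom, region_start, genomic)
        regions.append(region)

        for pos, end, mir in planted:
            truth.sites.append(
                PlantedSite(gene=gene, mirna=mir.name, region_id=region.region_id,
                            tx_start=pos, tx_end=end)
            )
            # seed-core hit with probability p_site_mutation
            if rng.random() < cfg.p_site_mutation:
                spec = _plant_disrupting_snv(rng, "".join(tx), pos, end, mir)
                if spec is not None:
                    tx_off, alt_base = spec
                    gpos = region.genomic_pos_of(tx_off)
                    g_ref = region.ref_seq[gpos - region.start]
                    g_alt = alt_base if strand == "+" else revcomp_dna(alt_base)
                    variant_specs.append(
                        (chrom, gpos, g_ref, g_alt, gene, True, mir.name)
                    )

        # background mutations away from planted sites
        n_bg = rng.poisson(cfg.p_background_mutation_per_kb * length / 1000.0)
        forbidden = [(a - 8, b + 8) for a, b, _ in planted]
        for _ in range(n_bg):
            for _ in range(50):
                tx_off = int(rng.integers(0, length))
                if all(not (a <= tx_off < b) for a, b in forbidden):
                    break
            else:
                continue
            gpos = region.genomic_pos_of(tx_off)
            g_ref = region.ref_seq[gpos - region.start]
            g_alt = BASES[(BASES.index(g_ref) + 1 + int(rng.integers(3))) % 4]
            in_tract = any(a - 1 <= tx_off < b + 1 for a, b in tract_spans)
            variant_specs.append((chrom, gpos, g_ref, g_alt, gene, False,
                                  "tract" if in_tract else ""))

    # assign carriers, support values and control-pool membership
    variants: list[Variant] = []
    control_variants: list[Variant] = []
    for chrom, gpos, ref, alt, gene, in_site, mir_tag in variant_specs:
        n_carriers = 1 + int(rng.poisson(0.8))
        carriers = list(
            rng.choice(tumor_patients, size=min(n_carriers, len(tumor_patients)),
                       replace=False)
        )
        key = Variant(chrom=chrom, pos=gpos, ref=ref, alt=alt).key
        in_controls = (not in_site) and rng.random() < cfg.control_fraction
        in_tract = mir_tag == "tract"
        for pid in carriers:
            for sid in samples_of[pid]:
                cov, vaf = _draw_support(rng, cfg)
                variants.append(
                    Variant(chrom=chrom, pos=gpos, ref=ref, alt=alt, sample_id=sid,
                            coverage=cov, vaf=vaf, gene=gene, location="utr3")
                )
        if in_controls:
            pool = f"POOL{1 + int(rng.integers(cfg.n_control_pools))}"
            control_variants.append(
                Variant(chrom=chrom, pos=gpos, ref=ref, alt=alt, sample_id=pool,
                        coverage=1000, vaf=0.5, gene=gene)
            )
        truth.mutations.append(
            PlantedMutation(
                key=key, in_site=in_site,
                expected_impact="disrupted" if in_site else "unchanged",
                mirna=mir_tag if in_site else "",
                carrier_patients=sorted(str(c) for c in carriers),
                in_controls=in_controls,
                in_artifact_tract=in_tract,
            )
        )
    return SimResult(
        reference=reference, regions=regions, mirnas=mirnas, variants=variants,
        control_variants=control_variants, meta=meta, truth=truth,
    )


def _plant_disrupting_snv(
    rng: np.random.Generator, tx: str, site_start: int, site_end: int,
    mir: MatureMiRNA,
) -> tuple[int, str] | None:
    """Pick a seed-core position and ALT base that abolish every seed
    match of ``mir`` in the local window; verified by re-running the
    seed classifier on the mutated window."""
    w = len(mir.sequence)
    # target offsets pairing miRNA 2-7 in a full-length complement site:
    # miRNA position p pairs target offset site_end - 1 - (p - 1)
    core_offsets = [site_end - 1 - (p - 1) for p in range(2, 8)]
    rng.shuffle(core_offsets)
    lo = max(0, site_start - w)
    hi = min(len(tx), site_end + w)
    for off in core_offsets:
        for alt in BASES:
            if alt == tx[off]:
                continue
            mut = tx[lo:off] + alt + tx[off + 1 : hi]
            if not find_seed_matches(mir, mut):
                return off, alt
    return None


# ---------------------------------------------------------------------------
# printed worked-example fixtures
# ---------------------------------------------------------------------------

# 16 recurrently mutated loci: gene, chrom, pos, ref, alt, location,
# miRNA, carrier-case count (of 55).
RECURRENT_LOCI: list[tuple[str, str, int, str, str, str, str, int]] = [
    ("EZH2", "chr7", 148508727, "T", "A", "exon", "hsa-mir-144", 8),
    ("ARMC10", "chr7", 102739179, "A", "G", "utr3", "hsa-mir-222", 18),
    ("TUBB", "chr6", 30692754, "C", "CTT", "utr3", "hsa-mir-1302", 7),
    ("MEF2B", "chr19", 19260045, "T", "A", "exon", "hsa-mir-1265", 3),
    ("METTL15", "chr11", 28353434, "G", "A", "utr3", "hsa-mir-4313", 12),
    ("ZNF195", "chr11", 3380000, "T", "TC", "utr3", "hsa-mir-1915", 16),
    ("BCL2", "chr18", 60793447, "G", "A", "utr3", "hsa-mir-5008", 2),
    ("THOC3", "chr5", 175386586, "A", "G", "utr3", "hsa-mir-371a", 15),
    ("TXNDC2", "chr18", 9887493, "T", "C", "exon", "hsa-mir-2110", 3),
    ("PCDH7", "chr4", 30732983, "GTA", "G", "intron", "hsa-mir-329", 4),
    ("RC3H1", "chr1", 173901940, "A", "AAAT", "utr3", "hsa-mir-548an", 2),
    ("AQP3", "chr9", 33441702, "C", "A", "utr3", "hsa-mir-146b", 8),
    ("DPY19L2", "chr12", 63953768, "T", "C", "utr3", "hsa-mir-1303", 11),
    ("MYO5B", "chr18", 47352742, "T", "G", "utr3", "hsa-mir-216b", 55),
    ("MYO5B", "chr18", 47352754, "A", "G", "utr3", "hsa-mir-2681", 55),
    ("YY2", "chrX", 21876221, "A", "G", "utr3", "hsa-mir-448", 36),
]

# Luciferase-candidate site windows: gene, chrom, window start/end,
# strand, miRNA, transcript-frame change (c.-style label), genomic pos,
# genomic ref/alt, total patients, tFL carriers, ntFL carriers.
CANDIDATE_SITE_WINDOWS: list[tuple] = [
    ("ARMC10", "chr7", 102739177, 102739198, "+", "hsa-mir-222",
     "c.1320A>G", 102739179, "A", "G", 18, 13, 7),
    ("BCL2", "chr18", 60793436, 60793458, "-", "hsa-mir-5008",
     "c.3623C>T", 60793447, "G", "A", 2, 2, 0),
    ("METTL15", "chr11", 28353429, 28353448, "+", "hsa-mir-4313",
     "c.2588G>A", 28353434, "G", "A", 12, 1, 11),
    ("EZH2", "chr7", 148508722, 148508742, "-", "hsa-mir-144",
     "c.2115A>T", 148508727, "T", "A", 8, 11, 2),
    ("EZH2", "chr7", 148508722, 148508742, "-", "hsa-mir-144",
     "c.2114T>A", 148508728, "A", "T", 5, 4, 2),
    ("MEF2B", "chr19", 19260038, 19260055, "-", "hsa-mir-1265",
     "c.336A>T", 19260045, "T", "A", 3, 3, 1),
]

_FIXTURE_STRANDS = {"EZH2": "-", "BCL2": "-", "MEF2B": "-",
                    "ARMC10": "+", "METTL15": "+"}
_FIXTURE_FLANK = 200


@dataclass
class StudyFixtures:
    """Worked-example records rebuilt from the printed tables, on a
    synthetic reference (filename and docstring say synthetic because
    only the printed alleles, strands and windows are real; all
    surrounding bases are seeded random)."""

    variants: list[Variant]  # one record per carrier patient sample
    unique_variants: list[Variant]  # one record per table row
    site_windows: list[tuple]  # CANDIDATE_SITE_WINDOWS
    regions: dict[str, TranscriptRegion]
    reference: GenomeWindows
    meta: list[SampleMeta]
    genome_build: str = "hg19 (as printed; not verified)"


def make_study_fixtures(seed: int = 0) -> StudyFixtures:
    """Rebuild the printed worked-example loci on a synthetic reference.

    Emits the 16 recurrent variant records (expanded to one record per
    carrier case, 55 cases total in the cohort), the 6 candidate site
    windows with their transformed/non-transformed splits, and
    reference windows whose bases agree with every printed REF allele
    and strand.
    """
    rng = np.random.default_rng(seed)
    reference = GenomeWindows()
    regions: dict[str, TranscriptRegion] = {}

    # fixed REF bases demanded by the printed rows
    pinned: dict[tuple[str, int], str] = {}
    for _gene, chrom, pos, ref, _alt, *_ in RECURRENT_LOCI:
        for k, base in enumerate(ref):
            pinned[(chrom, pos + k)] = base
    for row in CANDIDATE_SITE_WINDOWS:
        chrom, gpos, gref = row[1], row[7], row[8]
        pinned[(chrom, gpos)] = gref

    # one window per gene locus
    loci: dict[str, list[int]] = {}
    gene_info: dict[str, tuple[str, str, str]] = {}  # gene -> chrom, strand, kind
    for gene, chrom, pos, ref, _alt, loc, _mir, _n in RECURRENT_LOCI:
        loci.setdefault(gene, []).extend([pos, pos + len(ref) - 1])
        gene_info[gene] = (chrom, _FIXTURE_STRANDS.get(gene, "+"), loc)
    for row in CANDIDATE_SITE_WINDOWS:
        gene, chrom = row[0], row[1]
        loci.setdefault(gene, []).extend([row[2], row[3], row[7]])
        if gene not in gene_info:
            gene_info[gene] = (chrom, _FIXTURE_STRANDS.get(gene, "+"), "utr3")

    for gene, positions in loci.items():
        chrom, strand, kind = gene_info[gene]
        start = min(positions) - _FIXTURE_FLANK
        end = max(positions) + _FIXTURE_FLANK
        seq = list(_random_seq(rng, end - start + 1, max_run=3))
        for (pchrom, ppos), base in pinned.items():
            if pchrom == chrom and start <= ppos <= end:
                seq[ppos - start] = base
        ref_seq = "".join(seq)
        reference.add(chrom, start, ref_seq)
        regions[gene] = TranscriptRegion(
            region_id=f"{gene}_site", chrom=chrom, start=start, end=end,
            strand=strand, ref_seq=ref_seq, gene=gene, kind=kind,
        )

    # cohort of 55 cases; carriers assigned round-robin per row
    meta = _cohort_meta(34, 21, 5)
    tfl = [f"PT{i:03d}" for i in range(1, 35)]
    ntfl = [f"PN{i:03d}" for i in range(1, 22)]
    all_patients = tfl + ntfl
    sample_of = {m.patient_id: m.sample_id for m in meta if m.group in ("tFL", "ntFL")}

    variants: list[Variant] = []
    unique_variants: list[Variant] = []
    offset = 0
    for gene, chrom, pos, ref, alt, loc, mir, n_cases in RECURRENT_LOCI:
        unique_variants.append(
            Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    location=loc, coverage=1000, vaf=0.3)
        )
        carriers = [all_patients[(offset + i) % len(all_patients)] for i in range(n_cases)]
        offset += 7  # stagger carrier assignment between rows
        for pid in carriers:
            variants.append(
                Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                        sample_id=sample_of[pid], coverage=1000, vaf=0.3,
                        gene=gene, location=loc)
            )
    return StudyFixtures(
        variants=variants, unique_variants=unique_variants,
        site_windows=list(CANDIDATE_SITE_WINDOWS), regions=regions, reference=reference,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# validation-ledger fixture
# ---------------------------------------------------------------------------


@dataclass
class ValidationFixture:
    """Synthetic validation-cohort call set reproducing the published
    staged-filter arithmetic when run through the real filters."""

    variants: list[Variant]
    control_variants: list[Variant]
    reference: GenomeWindows
    meta: list[SampleMeta]
    kept_keys: list[tuple[str, int, str, str]]


def make_validation_fixture(
    seed: int = 0,
    n_total: int = 85,
    n_controls: int = 36,
    n_artifacts: int = 26,
    n_genes_kept: int = 21,
    n_exclusive_tfl: int = 10,
    occ_tfl: int = 73,
    occ_ntfl: int = 46,
) -> ValidationFixture:
    """Construct a call set that the staged filters resolve into the
    published ledger: ``n_total`` variant keys of which ``n_controls``
    also occur in healthy control pools, ``n_artifacts`` sit beside
    homopolymer tracts, and the remainder survive across
    ``n_genes_kept`` genes with the stated transformed/non-transformed
    occurrence structure. All removals happen through the real filter
    logic (allele-exact control matching; reference-context masking),
    not by labeling.
    """
    rng = np.random.default_rng(seed)
    n_kept = n_total - n_controls - n_artifacts
    if n_kept < max(n_genes_kept - 1, n_exclusive_tfl):
        raise ValueError("inconsistent ledger construction")
    meta = _cohort_meta(34, 21, 5)
    tfl = [f"PT{i:03d}" for i in range(1, 35)]
    ntfl = [f"PN{i:03d}" for i in range(1, 22)]
    samples_of: dict[str, list[str]] = {}
    for m in meta:
        if m.group in ("antFL", "tFL", "ntFL"):
            samples_of.setdefault(m.patient_id, []).append(m.sample_id)

    reference = GenomeWindows()
    variants: list[Variant] = []
    control_variants: list[Variant] = []
    kept_keys: list[tuple[str, int, str, str]] = []

    # per-variant carrier counts for the kept set: exclusive variants in
    # tFL only, shared variants in both groups, summing to the stated
    # occurrence totals
    n_shared = n_kept - n_exclusive_tfl
    excl_tfl_counts = _partition(occ_tfl, n_exclusive_tfl, n_shared, rng=None)
    tfl_counts = excl_tfl_counts[:n_exclusive_tfl] + excl_tfl_counts[n_exclusive_tfl:]
    ntfl_counts = [0] * n_exclusive_tfl + _partition_simple(occ_ntfl, n_shared)

    def _mk_window(chrom: str, pos: int, ref_base: str, artifact: bool) -> None:
        flank = 15
        for _ in range(100):
            seq = list(_random_seq(rng, 2 * flank + 1, max_run=2))
            seq[flank] = ref_base
            if artifact:
                seq[flank + 1 : flank + 7] = "A" * 6
                if ref_base == "A":
                    seq[flank] = ref_base  # adjacent to the run either way
            window = "".join(seq)
            reference.add(chrom, pos - flank, window)
            probe = Variant(chrom=chrom, pos=pos, ref=ref_base,
                            alt="G" if ref_base != "G" else "C",
                            coverage=100, vaf=0.3)
            _, removed = mask_artifact_regions([probe], reference)
            if bool(removed) == artifact:
                return
            reference._windows[chrom].pop()  # resample a cleaner window
        raise RuntimeError("could not build reference window")

    ti = ni = 0
    for i in range(n_total):
        gene = f"VG{(i % n_genes_kept) + 1:02d}" if i < n_kept else f"RG{i:02d}"
        chrom = f"val_{i:03d}"
        pos = 5000 + i
        ref_base = BASES[int(rng.integers(4))]
        alt_base = BASES[(BASES.index(ref_base) + 1) % 4]
        fate = "kept" if i < n_kept else (
            "control" if i < n_kept + n_controls else "artifact")
        _mk_window(chrom, pos, ref_base, artifact=(fate == "artifact"))
        if fate == "kept":
            n_t, n_n = tfl_counts[i], ntfl_counts[i]
            carriers = [tfl[(ti + k) % len(tfl)] for k in range(n_t)]
            ti += n_t
            carriers += [ntfl[(ni + k) % len(ntfl)] for k in range(n_n)]
            ni += n_n
            kept_keys.append(
                Variant(chrom=chrom, pos=pos, ref=ref_base, alt=alt_base).key
            )
        else:
            pid = (tfl + ntfl)[i % 55]
            carriers = [pid]
        for pid in carriers:
            for sid in samples_of[pid]:
                variants.append(
                    Variant(chrom=chrom, pos=pos, ref=ref_base, alt=alt_base,
                            sample_id=sid, coverage=int(rng.integers(200, 3000)),
                            vaf=float(rng.uniform(0.1, 0.6)), gene=gene,
                            location="utr3")
                )
        if fate == "control":
            pool = f"POOL{(i % 5) + 1}"
            control_variants.append(
                Variant(chrom=chrom, pos=pos, ref=ref_base, alt=alt_base,
                        sample_id=pool, coverage=2000, vaf=0.45, gene=gene)
            )
    return ValidationFixture(
        variants=variants, control_variants=control_variants,
        reference=reference, meta=meta, kept_keys=kept_keys,
    )


def _partition(total: int, n_first: int, n_second: int, rng=None) -> list[int]:
    """Split ``total`` occurrences over ``n_first + n_second`` variants,
    each getting at least one."""
    n = n_first + n_second
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


def _partition_simple(total: int, n: int) -> list[int]:
    if n == 0:
        return []
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]
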