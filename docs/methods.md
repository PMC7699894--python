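# Methods

## Coordinate model

All genomic coordinates are 1-based inclusive, matching the
`chrN:pos REF/ALT` style used in printed variant tables; BED input is
converted at the boundary (and back on output, losslessly). Indels use
the VCF anchored-first-base representation and every matching operation
(control subtraction, recurrence) runs on the left-normalized
`(chrom, pos, ref, alt)` key: shared suffix then prefix trimmed, one
anchor base retained. Allele parsing is case-insensitive.

Prediction operates entirely in transcript orientation (mRNA 5′→3′),
because miRNA pairing is defined on the mRNA; the genomic plus-strand
frame is I/O only. A region stores its plus-strand sequence and maps
offsets both ways; on the minus strand offsets reverse and alleles are
complemented. A REF allele that disagrees with the region sequence is a
hard error, never a warning — a silently wrong strand or offset is the
dominant failure mode of this kind of analysis, and every genuinely
observed mismatch should stop the run.

## Site model

**Seed classes.** The seed is miRNA positions 2–8. A site is classified
by exact Watson–Crick complementarity of the target to positions 2–7
(6mer core), extended by the base pairing position 8 (m8) and/or an A
opposite position 1 (A1): `8mer > 7mer-m8 > 7mer-A1 > 6mer`. G:U
wobbles never satisfy a seed class (they do count in alignment and
energy). Overlapping sites of the same miRNA are merged to the
strongest representative so one mutation is never double-counted.

**Duplex alignment.** A local (Smith–Waterman/Gotoh, affine-gap)
alignment of the miRNA read 3′→5′ against the target window 5′→3′:

| parameter | default | meaning |
|---|---|---|
| match | +5 | Watson–Crick pair |
| gu_wobble | +1 | G:U pair |
| mismatch | −3 | non-pairing column |
| gap_open / gap_extend | −8 / −2 | affine gap (gaps are never seed-weighted) |
| seed_weight | ×4 | multiplies substitution columns pairing miRNA 2–8 |
| min_score | 80 | reporting threshold |

A perfect 8-nt complement opposite positions 1–8 scores
5 + 7·(5·4) = 145. The defaults are this package's own, chosen so that
a bare 6mer core (6·20 = 120) passes `min_score` while shorter chance
complementarity does not; all are configurable. "Confidence" of a site
is its alignment score; `rank_and_filter_sites` keeps, per miRNA, the
⌈0.75·n⌉ best-scoring sites with all ties at the cutoff retained.

The default `site_policy="both"` requires a canonical seed class AND
`min_score`; `seed_only` and `align_only` relax either requirement
(whether the original analysis intersected or unioned its two
predictors is not recoverable, so the policy is explicit).

**Free energy.** Nearest-neighbor model:
ΔG = ΔG_init + Σ stacks + n_events·ΔG_loop (kcal/mol, 37 °C), with the
Turner-2004 Watson–Crick stack table (16 stacks after rotational
symmetry), a single constant (−0.5) for any stack touching a G:U pair,
initiation +4.09 and a flat +3.0 per interior loop/bulge event.
Mismatched alignment columns are loop positions, not pairs. This is a
deliberate simplification of full Turner loop tables: the pipeline only
needs *relative* wildtype-vs-mutant stability, and a flat loop cost
keeps the model exactly hand-summable (which is how the tests verify
it). The uniform negative G:U term departs from the true Turner set
(which contains destabilizing G:U stacks) to keep "every stack
stabilizes" as a model invariant.

## Impact calls

Each variant touching a kept site is rescored over a fixed window — the
site interval widened by one miRNA length each side (mutant side
adjusted for indel length shift) — so a site *gained* next to the
original footprint is visible. Classification compares the best
qualifying site per allele: `disrupted` (mutant has none), `gained`
(wildtype had none), otherwise `weakened`/`strengthened` when the score
moves beyond a dead zone `tol` (default 0: the default scheme is
integer-valued, so any change is meaningful), else `unchanged`. The
construction is antisymmetric: swapping alleles negates Δscore and
exchanges disrupted↔gained, weakened↔strengthened. Deletion overlap is
tested against the span of deleted bases, insertion overlap against the
anchor base.

## Cohort filters

Stages run in fixed order **QC → controls → artifact**; a record's fate
is the first stage that removes it, so the ledger conserves counts by
construction. Stage counts tally distinct variant keys (the unit used
in published ledgers); per-record fates are kept alongside, and a key
removed for one sample but surviving in another contributes to both
stage tallies.

* QC: coverage > 30× AND VAF > 5 %, both strict per the usual wording
  of such thresholds (configurable).
* Controls: any tumor call whose normalized key occurs in *any* healthy
  control pool is removed everywhere; matching is allele-exact.
* Artifact: a call whose changed bases lie within 1 base of a
  homopolymer run ≥ 5 nt or of ≥ 3 exact tandem copies of a 2–4-nt
  motif is removed. No published rule defines "homopolymer or
  repetitive region" for this assay class; these defaults follow common
  amplicon-artifact practice (semiconductor sequencing's flow-space
  errors concentrate beside base runs) and are configurable.
* Recurrence counts distinct *patients* (paired longitudinal samples of
  one patient count once); sample-level counts are available separately
  for comparability. Exclusivity labels a patient transformed if any of
  their samples is tFL or antFL, and reports the percentage of
  surviving variants carried only by transformed patients.

## Enrichment

Exact hypergeometric upper tail (scipy `hypergeom.sf`), gene names
case-normalized, GMT input. Benjamini–Hochberg across sets is available
but off by default, since single-ontology p-values are conventionally
reported uncorrected.

## Synthetic cohorts

`generate_cohort` emulates the validation-cohort structure: 34
transformed patients with paired pre/post samples, 21 non-transforming
patients, 5 control pools of healthy donors, negative-binomial coverage
(mean 2270×, the depth typical of amplicon panels), Beta(2, 6) VAFs.
UTRs are random sequence (300–700 nt) with planted miRNA-response
elements, Poisson background mutations, planted homopolymer tracts, and
a configurable fraction of variant keys copied into control pools.

Two deliberate idealizations:

* **Planted elements are full-length complements** of their miRNA, not
  bare seed matches. Every planted site of a miRNA therefore attains
  that miRNA's maximal alignment score, so the per-miRNA 75 % filter
  can only cut below them (or tie, in which case ties are kept) —
  planted-site recovery becomes a deterministic property instead of a
  race against random 3′-pairing bonuses. Real response elements pair
  far less extensively.
* **Disrupting mutations are verified at generation time**: the chosen
  seed-core substitution is re-checked to abolish every seed match of
  that miRNA in the local window, so `expected_impact="disrupted"` in
  the truth table is true by construction.

Simulated miRNAs are random 22-mers with pairwise-distinct seeds whose
core does not recur inside their own complement. Consequently, passing
recovery tests demonstrates the pipeline's bookkeeping, coordinate
logic and classifier wiring — not performance on real UTR composition,
overlapping miRNA families, or conservation-type signals, which the
model does not represent.

The worked-example fixtures rebuild the printed recurrent-variant and
candidate-site tables on a *synthetic* reference: printed alleles,
windows, strands and carrier counts are real; all flanking bases are
seeded random (no sequence data is deposited for these loci), so
fixture tests exercise coordinate/strand arithmetic only. Strand
assignments derive from the printed genomic↔transcript allele
correspondences. The validation-ledger fixture constructs an 85-key
call set whose control-pool membership and homopolymer contexts drive
the *real* filters to the published arithmetic (36 + 26 removed, 23
kept in 21 genes, 10 exclusive to transformed cases).

## Problem sizes and numerics

Test and acceptance runs use 6-gene/4-miRNA cohorts over 10–20 seeds
and oracle checks on sequences ≤ 12 nt — sizes at which the brute-force
oracles (pair-anchored alignment enumeration, exhaustive draw counting
for the hypergeometric) are exact and fast; the pipeline itself scales
linearly in regions × miRNAs. Alignment ties are broken toward the
pair state in traceback; ranking ties share the best rank of their tie
group; degenerate inputs (empty windows, zero-pair duplexes,
zero-length intervals, empty cohorts) raise typed errors or return
empty results as documented per function.
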