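# mirsitemut

Somatic mutations in predicted miRNA-binding sites: prediction, impact
scoring and cohort-level filtering.

## The problem

Most cancer-genomics pipelines stop at coding consequences. Yet a single
somatic substitution inside a miRNA-response element of a 3′ UTR can
abolish repression of an oncogene — the kind of event reported for
follicular lymphoma, where recurrent variants in the *BCL2* and *EZH2*
binding sites of *miR-5008* and *miR-144* impair miRNA binding.
`mirsitemut` is a desk-scale, fully reproducible implementation of that
analysis for anyone with somatic calls, UTR/exon coordinates, a
reference sequence and a set of mature miRNAs:

1. **Site prediction** — canonical seed-match classes
   (`8mer > 7mer-m8 > 7mer-A1 > 6mer`, Watson–Crick only), a weighted
   Smith–Waterman duplex alignment of the miRNA (3′→5′) against the
   target (5′→3′), and nearest-neighbor duplex free energy
   ΔG = ΔG_init + Σ ΔG_stack + n_loops·ΔG_loop. Per miRNA, only the
   most confident 75 % of sites (by alignment score) are kept.
2. **Impact scoring** — each variant touching a kept site is applied in
   transcript orientation and the wildtype/mutant alleles rescored over
   the same window; calls are classified `disrupted / weakened /
   unchanged / strengthened / gained`.
3. **Cohort filtering** — the staged validation ledger: per-call QC
   (coverage > 30×, VAF > 5 %), allele-exact subtraction of variants
   seen in pooled healthy controls, masking of calls beside homopolymer
   runs or short tandem repeats, then patient-level recurrence and
   transformed-vs-non-transformed exclusivity summaries.
4. **Enrichment** — an exact hypergeometric upper-tail test of the
   surviving genes against GMT gene sets.

A first-class synthetic-data module (`mirsitemut.synthetic_data`)
generates complete cohorts with planted response elements, in-site and
background mutations, coverage/VAF draws, control-pool contamination
and homopolymer tracts — plus a truth table, so recovery is measurable.

## Worked example

```bash
mirsitemut run-all --seed 7 --out out/
```

prints

```
sensitivity 1.000, false-call rate 0.000; ledger 20 -> 16; outputs in out
```

meaning: on a simulated cohort every planted seed-disrupting mutation
was recovered as a `disrupted` call, no background mutation produced a
call, and of 20 candidate variant keys 16 survived the staged filters
(the rest failed QC or matched a control pool). `out/impact_report.tsv`
holds one row per (variant, miRNA, site) with wildtype/mutant scores
and ΔG; `out/sites.bed` the kept sites; `out/ledger.tsv` the staged
counts.

From Python:

```python
from mirsitemut import pipeline
from mirsitemut.synthetic_data import SimConfig, generate_cohort

sim = generate_cohort(SimConfig(rng_seed=7))
disc = pipeline.run_discovery(sim.variants, sim.regions, sim.mirnas)
print(disc.counts)          # per-stage counts
val = pipeline.run_validation(sim.variants, sim.meta,
                              control_variants=sim.control_variants,
                              reference=sim.reference)
print(val.ledger.to_rows()) # staged filter ledger
```

Individual subcommands (`simulate`, `predict`, `impact`, `filter`,
`enrich`) expose every threshold as a flag (`--keep-fraction 0.75`,
`--min-cov 30`, `--min-vaf 0.05`, `--min-homopolymer 5`, ...).

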