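# trioscope

Trio-based clinical variant analysis: filter annotated variants in
parent–parent–child trios, classify them by inheritance pattern (de novo,
X-linked, autosomal recessive homozygous / compound heterozygous, inherited
dominant via ClinVar highlighting, parental mosaicism), assemble per-family
candidate reports, and compute cohort-level diagnostic-yield statistics.
A seeded synthetic-cohort simulator generates complete, realistic input
bundles (PED + phenotype table + annotated VCFs + truth table) so every
stage is testable without access to patient data.

## Pipeline

```bash
# 1. simulate a cohort (or bring your own PED/phenotypes/VCFs/panel)
trioscope simulate --out sim/ --seed 1 --n-families 100

# 2. filter + classify + report every trio
trioscope prioritize \
    --ped sim/cohort.ped --phenotypes sim/phenotypes.tsv \
    --vcf-dir sim/families --panel sim/panel.txt \
    --classes sim/classes.tsv --out reports/

# 3. cohort summary (yields per phenotype subgroup, inheritance-mode
#    distribution, consanguinity statistics)
trioscope summarize --reports reports/ --out summary/

# 4. reanalysis accounting: re-run prioritize with an updated panel, then
trioscope reanalyze --before reports_old/ --after reports_new/
```

`prioritize` writes one `<family>.report.tsv` (reportable candidates) and a
JSON sidecar per family, a cohort-wide `filter_trail.tsv`, and a
`manifest.json` with input digests and the thresholds in force. All outputs
are deterministic for fixed inputs and seed.

### Input formats

- **PED**: standard 6 columns; `0` = missing parent; sex 1/2/0; phenotype 2=affected.
- **Phenotype table** (TSV, header required): `family_id`, `hpo_terms`
  (semicolon-joined; the pseudo-terms `CAT:CM` / `CAT:NMD` encode the
  congenital-malformation and neuromuscular categories), `fetus` (0/1),
  `consanguineous` (0/1).
- **Annotated VCF** (4.2, per family): INFO keys `GENE`, `POP_AF`,
  `CSQ_CLASS` (missense, nonsense, frameshift, inframe_indel, splice_region,
  synonymous, start_or_stop_altering, intronic_deep, other), `CLNSIG`
  (`pathogenic_only` or other); FORMAT `GT`, `AD`, `DP`, `GQ`. Multi-allelic
  records are split on read. Hemizygous X calls are haploid (`GT 1`);
  GRCh37 PAR1/PAR2 are treated as autosomal.
- **Gene panel**: one symbol per line, `#` comments allowed. Re-running with
  a newer panel file models reanalysis.
- **ACMG classes** (TSV, optional): `family_id`, `variant_id`
  (`chrom:pos:ref:alt`), `acmg_class` (class3/class4/class5), `phenotype_concordant`
  (0/1). Classification is a clinical input, not computed. A candidate is
  reportable when class 4/5, or class 3 with concordance ("class 3+").

### Thresholds

De novo / mosaic read-support defaults (override with `--config`):
min depth 10, min proband alt reads 4, min GQ 20, parent alt reads ≤ 1 for a
clean de novo; a hom-ref parent with ≥ 2 alt reads at fraction ≤ 0.15 flags
parental mosaicism, and a higher fraction voids the de novo call.
Population-frequency cutoff: AF strictly below 1% (`--af-threshold`).

## Layout

| module | role |
| --- | --- |
| `trioscope.ped` | PED/phenotype readers, subgroup + symptom-category assignment |
| `trioscope.variants` | annotated-variant model, VCF dialect reader/writer |
| `trioscope.filters` | frequency / region / panel filters with audit trail |
| `trioscope.inheritance` | trio classification, comp-het pairing, mosaic detection |
| `trioscope.reports` | per-family report assembly and reporting semantics |
| `trioscope.stats` | cohort summaries, mode distribution, reanalysis uplift |
| `trioscope.simulate` | seeded synthetic-cohort generator (+ `presets/published_cohort.yaml`) |
| `trioscope.cli` / `trioscope.pipeline` | command-line wiring and manifests |
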