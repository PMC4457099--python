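# methscreen

A toolkit for promoter CpG-island hypermethylation candidate screening in
metastatic tumour cohorts. It implements the full desk-side analysis chain:

1. **Array screen** (`methscreen.array_screen`) — filter 450K-style probes to
   promoter groups (TSS200/TSS1500), apply two-cohort beta-value prevalence
   screens (β ≤ 0.25 in ≥ 75% of one cohort; β ≥ 0.60 in ≥ 50% of the other),
   intersect, collapse probes to genes and gate candidates on CpG-island
   membership.
2. **In-silico CoBRA** (`methscreen.cobra`) — bisulfite-convert an amplicon
   given per-CpG methylation states, predict BstUI (`CG^CG`) and TaqI
   (`T^CGA`) digestion of the converted strand, and emit a categorical
   methylation call (any cut ⇒ methylated; a configurable cut-fraction
   supports allele pools).
3. **Methylation index** (`methscreen.methylation_index`) — pooled MI from
   clone bisulfite-sequencing matrices, with bands MI ≥ 60 methylated,
   MI < 40 unmethylated, [40, 60) ambiguous, plus CoBRA/MI concordance.
4. **Cohort statistics** (`methscreen.cohort_stats`) — per-gene frequencies
   from categorical call tables (failed assays excluded), the inclusive
   ≥ 50% frequent / ≤ 45% infrequent filters, and two-sided Fisher's exact
   tests by exact integer hypergeometric summation (optional BH adjustment).
5. **Paired analysis** (`methscreen.paired_analysis`) — early/late
   epimutation timing from matched primary/metastasis pairs: among pairs with
   a methylated metastasis, the fraction with a methylated primary decides
   early (≥ 0.5) vs late (≤ 0.5), configurable.
6. **Synthetic data** (`methscreen.synthetic_data`) — seeded generators for
   every input (beta matrices from a Beta(8,2)/Beta(2,8) mixture, GC-rich
   amplicons with guaranteed restriction motifs, Bernoulli clone matrices,
   paired cohorts with planted early/late genes) with recorded ground truth.

A small reference dataset (`methscreen.datasets`) bundles the per-gene cohort
frequencies and matched-pair calls used by the validation suite.

## Tests

```sh
python -m pytest tests/
```

The suite includes unit tests per module, hypothesis property tests
(fragment conservation, screen monotonicity, count conservation, …) and
`tests/test_acceptance.py`, which checks the headline behaviours: the 21-gene
frequent set, the 3-gene combined selection, matched-pair counts and timing,
MI band edges, exhaustive Fisher-oracle agreement for all 2×2 tables with
totals ≤ 60, brute-force screen equivalence, and end-to-end recovery of
planted candidates over 20 seeded replicates.

## CLI

```sh
methscreen simulate --seed 7 --outdir fixtures/          # all inputs + truth
methscreen screen --unmeth-cohort fixtures/beta_primary.tsv \
    --meth-cohort fixtures/beta_metastasis.tsv \
    --annotation fixtures/annotation.csv --out screen.json
methscreen cobra --fasta fixtures/amplicons.fa \
    --states fixtures/amplicon_states.csv --out calls.csv
methscreen mi --clones fixtures/clones/ --out mi.csv
methscreen stats --calls fixtures/calls.csv --out diff.json
methscreen pairs --pairs fixtures/pairs.csv --out timing.json
methscreen run-all --seed 7 --out all.json               # full synthetic run
```

All commands accept `--config config.yaml` (see `methscreen.io_cli.config`);
reports are JSON with TSV twins for tabular sections.

### File formats

- annotation CSV: `probe_id, gene_symbols(;-sep), tss_groups(;-sep),
  island_relation`
- beta matrix TSV: first column `probe_id`, one column per sample, missing as
  empty or `NA`
- amplicons: FASTA plus a sidecar CSV of 0-based CpG positions and `M`/`U`
  states
- clone matrices: one CSV per `gene__sample`, cells `M`/`U`/`.`
- call table CSV: `sample_id, cohort, gene, call`
- pairs CSV: `patient_id, gene, primary_call, metastasis_call, normal_call`

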