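# nstrat

A tested pipeline for surveying microbial nitrogen (N) acquisition
strategies in genome collections: position-specific profile models detect
marker-protein homologs in per-genome protein sets, a monotone rule engine
converts hits into calls for 10 N-acquisition strategies (plus five
amino-acid transporter-family sub-flags), and downstream modules estimate
bootstrapped strategy prevalence and fit the standard association analyses
(genome-size scaling, metabolism-group contrasts, presence/absence and
habitat models with family-level adjustment, host vs. free-living
contrasts, and linear / logistic-PCA ordination).

A seeded synthetic-community generator with planted effect structure makes
every stage testable end-to-end without any external download.

## The ten strategies

ammonium uptake (AmtB), biological nitrogen fixation (NifH+NifD+NifK),
ferredoxin-dependent nitrite reduction (NirA), NADH-dependent nitrite
reduction (NirB+NirD), assimilatory nitrate reduction (NasA co-occurring
with a nitrite route), urea (UreC), cyanate (CynS), chitin
depolymerization (chitinase), HexNAc assimilation (hexosaminidase), and
amino-acid uptake (any of the APC / AGCS / BCCT / LIVCS / HAAAP
transporter families).

## Package layout

| module | contents |
| --- | --- |
| `nstrat.markers` | alignment I/O, profile construction, local forward scoring, Gumbel null calibration, proteome search, HMMER3 tblout interop |
| `nstrat.strategies` | rule engine, QC filter (high-quality genome criteria), strategy counts, inorganic fraction, energetic cost table |
| `nstrat.simulate` | seeded synthetic communities with planted markers, decoys and logistic effect structure |
| `nstrat.prevalence` | bootstrap prevalence (plain and taxon-balanced), strategy ranking |
| `nstrat.associations` | OLS count scaling, Kruskal-Wallis + pairwise rank-sum (Holm), logistic / Poisson GLMs, Welch contrast, PCA and logistic PCA |
| `nstrat.pipeline`, `nstrat.cli` | stage orchestration, manifests, `nstrat` command |

## Command line

```bash
nstrat all --config config.yaml --out outdir --seed 1
```

Stages: `simulate`, `build-profiles`, `search`, `call`, `prevalence`,
`associate`, or `all`. Example config:

```yaml
seed: 11
simulate:
  n_genomes: 60
  baseline_logit: 0.0
  beta_size: 1.0
  n_families: 5
  decoys_per_genome: 5
profiles:
  n_calibration: 150
bootstrap:
  n_boot: 1000
  scheme: plain
call:
  require_nird: true
models:
  family_effects: fixed
```

Each stage writes its declared TSV/JSON artifacts (`hits.tsv`,
`strategies.tsv`, `dropped.tsv`, `prevalence.tsv`, `associations.json`,
`ordination.tsv`) plus a manifest with content hashes; re-running with the
same config and seed reproduces identical bytes. Real HMMER3 search output
can be substituted for the native scorer via
`nstrat.markers.read_hmmer_tblout`.

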