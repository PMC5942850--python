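# mutcloud

Analysis toolkit for serial-transfer evolution experiments in asexual
microbes: pooled-sequencing diversity metrics, a replicate-convergence test
for putatively beneficial genes, effective-population-size and
fluctuation-assay mutation-rate estimators, growth/stress phenotype scoring,
and a bundled serial-dilution Wright–Fisher simulator so every stage can be
exercised on synthetic data with known ground truth.

## Modules

| Module | Purpose |
| --- | --- |
| `mutcloud.simulate` | Haplotype-based Wright–Fisher simulator for daily growth–dilution cycles; samplers for pooled reads, Luria–Delbrück mutant counts, logistic growth curves and endpoint plate readings |
| `mutcloud.popgen` | Mutant-cloud spread `C`, consensus distance `D`, nucleotide site diversity `π`, high-frequency derived-allele counts, folded 6-class mutational spectra |
| `mutcloud.enrich` | Length-proportional null test for genes mutated at high frequency in improbably many replicate populations (exact subset enumeration, equivalent dynamic program, Monte-Carlo oracle) |
| `mutcloud.effective_size` | Within-cycle population-size ladder and nominal `N_e` as the harmonic mean over all per-generation sizes; pluggable hook for external linkage corrections |
| `mutcloud.fluctuation` | Luria–Delbrück pmf (Lea–Coulson model, optional partial plating), maximum-likelihood mutant-count estimation with profile-likelihood CIs, per-bp/genomic rate conversion |
| `mutcloud.phenotype` | Logistic growth-curve fitting, relative fitness, AUC, endpoint `B` scores, noise thresholds, concentration-well selection, gain/loss calls, normalized stress fold change `G` |
| `mutcloud.io` / `mutcloud.cli` | TSV/CSV/GFF3 readers and writers, YAML run configuration, and the `mutcloud` CLI |

A note on site diversity: the per-site statistic is computed as mismatching
read pairs over total read pairs, `m_p (m − m_p) / (m (m − 1) / 2)`, where
`m_p` is the majority-allele read count out of `m` reads. A sometimes-seen
variant with a proportion in the numerator is dimensionally inconsistent
with pairwise read counting and is not used.

The enrichment statistic `P_g` is a *point* probability (exactly `n_g`
replicates hit), not an upper tail; `mutcloud.enrich.monte_carlo_null`
reports both for comparison. No multiple-testing correction is applied
beyond the fixed significance threshold (default 5×10⁻⁵).

## CLI

```sh
mutcloud simulate  --config cfg.yaml --out run/ [--seed N]   # full synthetic experiment
mutcloud diversity --variants v.tsv --genome-length 4641652 --out metrics.tsv
mutcloud enrich    --variants v.tsv --genes g.gff --out enrichment.tsv
mutcloud ne        --counts c.csv --dilution 1e5 --out ne.tsv
mutcloud fluctuation --counts f.csv --correction 71 --genome-length 4641652
mutcloud growth    --curves curves.csv --out fits.tsv
mutcloud biolog    --plate plate.csv --pairs evo1:anc1,evo2:anc2 --out calls.tsv
mutcloud stress    --readings r.csv --control DM1000 --out g.tsv
```

`mutcloud simulate` (alias `run`) chains simulate → diversity → enrichment →
effective size → fluctuation → growth fitting and writes a `manifest.json`
with config, seeds and output checksums; identical config + seed reruns are
byte-identical.

Interchange formats are plain text (documented in `mutcloud.io`); genome
coordinates are 1-based inclusive everywhere.

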