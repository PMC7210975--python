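# scatlas

Statistics for single-cell tumor-atlas cohorts: expression-matrix QC and
normalization, expression-inferred CNV malignancy calling, threshold-based
marker selection and signature scoring, subset-by-tissue composition
statistics, permutation-based receptor–ligand interaction networks,
GO-Jaccard gene networks, and a seeded synthetic cohort generator that makes
the whole pipeline testable without any external download.

## Modules

| module | what it does |
| --- | --- |
| `scatlas.io_core` | MTX/TSV loading, cell QC (mito ≤ 20%, UMI 100–150k, genes 200–10k), gene prevalence filter, log2 TPM-like normalization, per-gene centering |
| `scatlas.cnv_malignancy` | normal-cell spike-in, gene filter, Z-clip (±3), 100-gene moving-average windows per chromosome, per-cell centering, mean-squares / top-5%-profile-correlation malignancy call |
| `scatlas.markers` | expressing-fraction gate, log2FC, equal-variance t-test with Bonferroni, signature scores, variable-gene selection, PC1 two-way partition, quartile survival strata with 10-year censoring + log-rank |
| `scatlas.composition` | subset × origin contingency: Pearson residuals, observed/expected ratios, chi-square; per-sample immune proportions and group t-tests |
| `scatlas.interactions` | mean-expression interaction scores, seeded label-permutation p-values, four-step filtering, significant-interaction count matrix |
| `scatlas.go_network` | Jaccard similarity of GO BP term sets, thresholded gene–gene network |
| `scatlas.synthetic_data` | seeded negative-binomial cohorts with planted markers, CNV segments, composition, and ligand–receptor signals |
| `scatlas.pipeline_cli` | the `atlas` CLI and the end-to-end runner with a checksummed manifest |

## CLI

```sh
atlas simulate --out cohort/ --seed 1          # synthetic fixture (MTX + TSV + truth JSON)
atlas qc --counts cohort/ --metadata cohort/metadata.tsv --out qc.tsv
atlas cnv --counts cohort/ --metadata cohort/metadata.tsv --genes cohort/genes.tsv \
          --out cnv.tsv --window 100 --ms-thr 0.02 --corr-thr 0.2 --seed 1
atlas markers --counts cohort/ --metadata cohort/metadata.tsv \
              --group-a Malignant --group-b AT2 --out markers.tsv
atlas composition --metadata cohort/metadata.tsv --out composition.tsv
atlas interactions --counts cohort/ --metadata cohort/metadata.tsv \
                   --pairs pairs.tsv --out interactions.tsv --n-perm 1000 --seed 1
atlas gonet --markers markers.tsv --go-terms go.tsv --out edges.tsv
atlas survival --table survival.tsv --low-q 0.25 --high-q 0.75 --censor-years 10
atlas run --config run.json                    # all stages + manifest.json
```

Exit codes: 0 ok, 2 validation error, 3 stage failure.

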