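# pausekit

Analysis toolkit for RNA polymerase II promoter-proximal pausing from
nascent-transcription sequencing (GRO-seq-style) coverage, written for
regulatory-genomics studies that ask how a perturbation — a knockout or
degron of a pausing factor such as a NELF subunit — shifts engaged
polymerase from promoters into gene bodies.

## What it computes

The central statistic is the **pausing release ratio (PRR)** of a gene,

```
PRR = (body density + pc) / (promoter density + pc)
```

where densities are coverage per bp per million total library signal over
the gene-body window (TSS+300 → TES by default) and the promoter window
(TSS−50 → TSS+300), read from the gene's sense strand, and `pc` is a small
pseudocount. A low PRR means polymerase piles up near the promoter
(paused); a high PRR means it has been released into elongation. Between a
control and a treatment condition,

```
log2 PRR_FC = log2(PRR_treat / PRR_ctrl)
```

classifies genes: `log2 PRR_FC > 0.585` (>1.5-fold release) is **Group I
(Pol II paused)** — the genes whose pausing the perturbation releases —
`|log2 PRR_FC| < 0.585` is **Group II (others)**, and `< −0.585` is
**Decreased**. Genes whose control promoter density falls in the bottom
quantile (default 25%) are excluded as insufficiently active.

Around this core the package provides:

- **genome_io** — GTF/BED12 annotations, bedGraph (optionally bigWig)
  coverage, narrowPeak/BED6+ peak calls, all converted to one 0-based
  half-open convention at the I/O boundary;
- **pausing** — windows, densities, PRR, classification, ECDF tables and
  the two-sample Kolmogorov–Smirnov comparison used for every distribution
  contrast;
- **peaks** — replicate/assay consensus peaks under an FDR filter and an
  occupancy rule, cross-assay intersection, annotation to
  promoter/exon/intron/distal features, and Spearman correlation of
  per-peak log2 fold changes between two assays;
- **metaplot** — TSS-anchored and peak-centered signal matrices with
  orientation-aware rows, averaged profiles with seeded bootstrap bands,
  and optional line/heatmap plots;
- **enrichment** — upper-tail hypergeometric over-representation of a gene
  group against GMT gene sets with Benjamini–Hochberg adjustment;
- **synthetic** — a generator that writes a complete synthetic study
  (annotation, stranded coverage for two conditions, replicate peak calls
  with decoys, gene sets, and a truth table) with a controllable
  pause-release effect, so the whole pipeline is testable without any
  download;
- **pipeline / CLI** — one YAML config driving every stage end to end with
  provenance sidecars and a digest manifest; reruns are byte-identical.

## Worked example

Generate a 300-gene synthetic study (30% of genes get a 3-fold pause
release in the "knockout" condition) and run the full analysis:

```bash
pausekit generate --out bundle --seed 7 --config gen.yaml   # gen.yaml: {n_genes: 300, chrom_length: 4000000}
pausekit run-all --config run.yaml --out results/
```

with `run.yaml` pointing at the bundle's files (see
`pausekit.pipeline.RunConfig`). The run prints the group table

```
        group  n_genes
     Excluded       74
GroupII_other      151
GroupI_paused       75
```

— 74 genes (25%) fail the activity filter, and essentially all truly
released genes land in Group I. `results/ks_report.tsv` holds the
distribution contrasts:

```
comparison                 n_a  n_b  ks_statistic  p_value
prr_treat_vs_ctrl_all      226  226  0.367         3.6e-14
prr_treat_vs_ctrl_groupI    75   75  1.000         0
prr_treat_vs_ctrl_groupII  151  151  0.066         0.87
log2fc_groupI_vs_groupII    75  151  1.000         0
```

Group I's PRR distribution shifts completely on treatment (D = 1.0) while
Group II's is statistically indistinguishable between conditions
(p = 0.87) — the release signature concentrates in the released genes.
The two synthetic accessibility assays' per-peak log2 fold changes over
the 300 consensus promoter peaks correlate (Spearman ρ = 0.64), and ORA of
Group I against the bundled gene sets ranks the pause-enriched set first
(adjusted p ≈ 2e-29, overlap 63/76).

## Documentation

`docs/methods.md` describes the model, the window geometry, the synthetic
generator's assumptions and limits, and the numerical choices (pseudocount,
boundary handling, tie-breaking, bootstrap).
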