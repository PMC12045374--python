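# Methods

## Model and quantities

Promoter-proximal pausing is quantified per gene from stranded
base-resolution coverage of transcriptionally engaged polymerase. For a
gene with TSS/TES on its sense strand, two windows are defined in the
gene's orientation:

- promoter: `[TSS − promoter_up, TSS + promoter_down)`, default −50/+300 bp;
- body: `[TSS + body_gap, TES)`, default gap 300 bp (a fixed body extent
  clipped at the TES is available for very long genes).

The window geometry follows the pausing-index convention of the
nascent-transcription literature; all four bounds are configuration
parameters because no single choice is canonical. Genes shorter than the
body gap are omitted (with a logged reason), never truncated to an empty
window.

Densities are `signal sum / window length × 10^6 / library total`, with
the library total defaulting to the summed signal of the condition's
tracks (both strands). Stranded data are quantified on the gene's sense
strand only; unstranded tracks (accessibility assays) use the combined
signal. The pausing release ratio is

```
PRR = (body_density + pc) / (promoter_density + pc)
```

with pseudocount `pc = 0.1` density units by default: large enough to keep
silent promoters from producing unstable ratios, small relative to the
promoter densities of active genes, and configurable. As `pc → 0` the PRR
approaches the raw density ratio and becomes scale-invariant.

### Classification

`log2 PRR_FC = log2(PRR_treat / PRR_ctrl)` is oriented treatment-over-
control so that pause *release* in the treatment gives positive values.
With threshold t (default 0.585 ≈ log2 1.5): strictly above t → Group I
(paused, released); strictly below −t → Decreased; otherwise Group II.
Boundary equality is a measure-zero event but needs a deterministic rule;
it falls to Group II. Before classification, genes whose control promoter
density lies below the 25th percentile (configurable quantile) are
excluded: pausing is a property of actively transcribed genes, and ratios
at silent promoters are pseudocount noise.

### Distribution comparisons

All distribution contrasts use the two-sample Kolmogorov–Smirnov test.
The statistic D is the exact supremum of the ECDF difference over pooled
sample points; the p-value uses the asymptotic two-sided distribution
(effective n = n_a·n_b/(n_a+n_b)), appropriate for the thousands of genes
per group this package targets — no exact small-sample enumeration is
attempted. ECDF tables are right-continuous with ties collapsed and the
final cumulative fraction pinned to exactly 1.

### Consensus peaks

Within one assay, replicate peak calls are first filtered to
`FDR ≤ fdr_max` (default 0.05; FDR values are consumed from the input
columns, never recomputed). Under the default `any_bp` rule, a base is
*supported* when at least `min_sets` distinct replicate sets cover it
(default: all replicates, the strictest reading of replicate consensus);
each consensus peak is the union extent of a maximal supported run plus
every passing input peak that touches it, inheriting the minimum FDR of
its contributors. A reciprocal-overlap rule (components of peaks linked by
mutual fractional overlap across ≥ min_sets sets) is available. Book-ended
regions coalesce, so the output matches a per-base covered-set oracle
exactly; consensus of a consensus is the identity.

Cross-assay intersection defaults to the strict base-wise intersection —
it can never exceed either parent, keeping downstream windows conservative
— with union extent as an option. Peaks are annotated by precedence
promoter > exon > intron > distal, where "promoter" is any overlap with a
±2,000 bp TSS window (configurable); the nearest gene is chosen by
midpoint-to-TSS distance, signed in the gene's orientation. For
annotations without exon structure, the whole gene extent counts as
exonic. Cross-assay agreement of the perturbation response is summarised
as the Spearman correlation of per-peak `log2((treat+pc)/(ctrl+pc))`
between two assays.

### Metaplots

Anchor matrices hold mean per-bp, per-million signal in fixed bins over
`[−upstream, +downstream)` (default −100/+2,000 bp, 10 bp bins — the span
divisibility by the bin is enforced). Minus-strand rows are
orientation-flipped so column 0 is always 5′-most; the flip is an
involution. Bases beyond a chromosome edge are padded with NaN, not zero —
zero-fill would bias column means downward — and ignored by the profile.
Profiles are column means with a 95% band from a seeded bootstrap over
rows (default B = 1,000 in the API, 200 in the pipeline defaults).
Metaplots are library-normalised by default; any other normalisation can
be injected through `library_total`.

### Over-representation

ORA is the one-sided upper-tail hypergeometric probability
`P[X ≥ overlap]` with the universe defaulting, in the pipeline, to the
classified gene list (not the whole annotation): the question is whether a
group is enriched relative to the genes that could have been classified at
all. p-values are Benjamini–Hochberg adjusted across the tested sets and
reported significant below adjusted p 0.05.

## Synthetic data generator

The generator emulates the minimal structure a pausing study needs:
non-overlapping genes (log-uniform lengths 2–20 kb, random strand,
jittered ≥1 kb spacing) on one synthetic chromosome, each with a per-bp
Poisson signal rate on its sense strand: body rate log-normal across genes
(mean 0.5 reads/bp), promoter window rate `promoter_enrichment` (default
10×) times the body rate, over a sparse two-strand background
(0.01 reads/bp). A fraction of genes (default 30%) is marked
`paused_released`: in the treatment their promoter rate is divided by d
and body rate multiplied by f/d, with d chosen per gene so the expected
total gene signal is exactly conserved — the expected PRR fold change is
exactly `release_fold` (default 3) while the library total stays fixed, so
the ratio effect is cleanly separated from expression change and untouched
genes keep identical per-million densities across conditions.

Promoter windows are drawn at single-base resolution; gene bodies are
drawn per 25-bp tile (the tile total is Poisson with the tile-summed rate,
stored as a constant per-bp value). Window sums over bodies therefore keep
the exact Poisson count distribution while the representation stays small;
`body_tile_bp = 1` restores full per-base drawing. Optional
gamma-multiplier overdispersion turns the noise negative-binomial-like.

Replicate peak calls put one low-FDR (<0.01) peak over each promoter with
±20 bp boundary jitter per replicate, plus intergenic decoys with FDR in
[0.05, 1], so the default FDR filter separates them perfectly. Two
unstranded accessibility-style tracks per condition (independent noise,
signal proportional to the condition's promoter rate) support the
peak-centered metaplot and cross-assay correlation stages. All randomness
derives from one root seed through fixed-index child streams, so every
artefact is independently reproducible.

What the generator does *not* emulate: fragment-length and GC effects,
mappability, enhancer transcription, antisense/divergent initiation,
multi-isoform TSS heterogeneity, or read-level alignment artefacts.
Passing recovery tests therefore demonstrates the estimators' correctness
under the stated generative model, not robustness to every artefact of
real libraries.

## Problem sizes and numerical choices

- The default synthetic study is 2,000 genes on a 25 Mb chromosome; the
  file-based pipeline demonstrations use 300 genes on 4 Mb. These sizes
  give tight Poisson window counts (promoter sums ≈ 10³) while keeping a
  full run in seconds.
- Classification recovery is assessed among genes passing the activity
  filter; with the default 25% exclusion quantile, recovery over all genes
  is bounded by construction.
- K-S p-values below ~1e-308 underflow to 0; they are reported as 0.
- Coordinates are validated at construction (0 ≤ start < end); bedGraph
  overlap and negative values, q-value scale mismatches, and duplicate
  gene ids are rejected at read time with the offending line.
- TSVs are written with `%.6g` floats; reruns from identical config and
  inputs are byte-identical, and the run manifest stores SHA-256 digests
  to verify it. Provenance sidecars deliberately contain no timestamps.
- Nearest-gene ties (equidistant TSSs) resolve to the first gene in
  (position, strand, id) order — deterministic by construction.

## Known limitations

- Pausing-index variants that use a maximal sliding promoter window are
  out of scope; the promoter window is fixed relative to the annotated TSS.
- Transcription-unit calling from coverage is not attempted; the
  annotation is taken as given.
- The K-S p-value is asymptotic and anti-conservative below a few dozen
  observations per sample; at such sizes prefer the statistic itself.
- bigWig input requires pyBigWig; it is an optional extra, and all shipped
  workflows use bedGraph.
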