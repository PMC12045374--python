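"""Synthetic GRO-seq-like data with known pausing structure.

The generator lays out non-overlapping genes on one synthetic chromosome
and gives each a per-bp Poisson signal rate: an elevated rate over the
promoter-proximal window (the paused-polymerase peak) and a lower rate over
the gene body, on the gene's sense strand only, over a sparse intergenic
background. A "knockout" treatment releases pausing for a chosen subset of
genes by moving rate from promoter to body (promoter / d, body * f/d with
d chosen per gene so the gene's expected total signal is exactly
conserved), so the expected pausing-release-ratio fold change is exactly
``release_fold`` while the library total stays fixed — the ratio effect is
isolated from expression change. Replicate peak calls over promoters (with low FDR) plus
higher-FDR decoy peaks exercise the consensus machinery, and the truth
table records every gene's generative rates and intended class for
recovery testing.

All randomness derives from one root seed via fixed-index child streams,
so each artefact is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    runs_from_dense,
)
from .enrichment import GeneSet

CLASS_PAUSED = "paused_released"
CLASS_UNCHANGED = "unchanged"
CLASS_GAINED = "pause_gained"

_STREAM_GENOME = 0
_STREAM_CTRL = 1
_STREAM_TREAT = 2
_STREAM_PEAKS = 3
_STREAM_SETS = 4
_STREAM_ACCESS = 5


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Rates are per-bp Poisson means (read counts per base). The default
    geometry — ~8 kb genes with a ten-fold promoter-over-body enrichment,
    0.5 reads/bp mean body depth and a three-fold pause release in 30% of
    genes — emulates a well-sequenced nascent-transcription experiment with
    a strong but not saturating knockout effect.
    """

    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_length: int = 25_000_000
    fraction_paused: float = 0.3
    fraction_gained: float = 0.0
    promoter_enrichment: float = 10.0
    release_fold: float = 3.0
    body_rate_mean: float = 0.5
    body_rate_log_sd: float = 0.5
    background_rate: float = 0.01
    noise_model: str = "poisson"
    overdispersion: float | None = None  # gamma shape; None = pure Poisson
    body_tile_bp: int = 25
    replicates: int = 3
    n_decoys: int = 200
    min_gene_length: int = 2_000
    max_gene_length: int = 20_000
    spacing: int = 1_000
    promoter_up: int = 50
    promoter_down: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_paused", "fraction_gained"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.fraction_paused + self.fraction_gained > 1.0:
            raise ValidationError("class fractions exceed 1")
        for name in ("promoter_enrichment", "release_fold", "body_rate_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_model not in ("poisson",):
            raise ValidationError(f"unknown noise_model {self.noise_model!r}")
        if self.min_gene_length < self.promoter_down + 1:
            raise ValidationError("genes must be longer than the promoter window")

    def rng(self, stream: int, *sub: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream, *sub))
        )


def generate_genome(config: GeneratorConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out genes and draw their generative rates and true classes.

    Gene lengths are log-uniform in [min_gene_length, max_gene_length],
    strands random, placement sequential with jittered spacing. Body rates
    are log-normal across genes with mean ``body_rate_mean``; the promoter
    rate is ``promoter_enrichment`` times the body rate in control. Raises
    if the genes cannot fit on the chromosome.
    """
    rng = config.rng(_STREAM_GENOME)
    n = config.n_genes
    lengths = np.exp(
        rng.uniform(np.log(config.min_gene_length), np.log(config.max_gene_length), n)
    ).astype(np.int64)
    gaps = rng.integers(config.spacing, 2 * config.spacing, size=n)
    margin = 2 * (config.promoter_up + config.spacing)
    starts = margin + np.concatenate(([0], np.cumsum(lengths + gaps)[:-1]))
    ends = starts + lengths
    if ends[-1] + margin > config.chrom_length:
        raise ValidationError(
            f"{n} genes need {int(ends[-1] + margin)} bp but chrom_length is "
            f"{config.chrom_length}"
        )
    strands = rng.choice(["+", "-"], size=n)

    u = rng.uniform(size=n)
    classes = np.where(
        u < config.fraction_paused,
        CLASS_PAUSED,
        np.where(
            u < config.fraction_paused + config.fraction_gained,
            CLASS_GAINED,
            CLASS_UNCHANGED,
        ),
    )
    ln_mean = np.log(config.body_rate_mean) - config.body_rate_log_sd**2 / 2.0
    body_ctrl = np.exp(rng.normal(ln_mean, config.body_rate_log_sd, size=n))
    prom_ctrl = body_ctrl * config.promoter_enrichment
    # Split the fold change f between a promoter divisor d and a body
    # multiplier m = f/d so each gene's expected total signal is exactly
    # conserved: with body length L and promoter-signal mass S = span * E
    # (E = enrichment), conservation gives d = (L*f + S) / (L + S). Exact
    # conservation keeps the library total fixed, so per-million densities
    # of untouched genes are unaffected by the treatment.
    prom_span = config.promoter_up + config.promoter_down
    body_len = (lengths - config.promoter_down).astype(np.float64)
    s_mass = prom_span * config.promoter_enrichment
    f_eff = np.where(
        classes == CLASS_PAUSED, config.release_fold,
        np.where(classes == CLASS_GAINED, 1.0 / config.release_fold, 1.0),
    )
    d = (body_len * f_eff + s_mass) / (body_len + s_mass)
    m = f_eff / d
    prom_treat = prom_ctrl / d
    body_treat = body_ctrl * m

    genes = [
        GeneModel(
            f"g{i:04d}",
            GenomicInterval(config.chrom, int(starts[i]), int(ends[i]), str(strands[i])),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "true_class": classes,
            "promoter_rate_ctrl": prom_ctrl,
            "body_rate_ctrl": body_ctrl,
            "promoter_rate_treat": prom_treat,
            "body_rate_treat": body_treat,
            "seed": config.seed,
        }
    )
    return genes, truth


def _gene_signal_region(g: GeneModel, config: GeneratorConfig) -> tuple[int, int]:
    """Genomic extent carrying gene signal: promoter window plus body."""
    if g.strand == "+":
        return g.tss - config.promoter_up, g.tes
    return g.tes, g.tss + config.promoter_up


def simulate_coverage(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: GeneratorConfig,
    condition: str,
) -> dict[str, CoverageTrack]:
    """Draw Poisson counts for one condition.

    Returns ``{"+": track, "-": track}``. Each gene's sense strand carries
    its promoter-rate window ``[TSS - promoter_up, TSS + promoter_down)``
    at single-base resolution and body-rate signal downstream to the TES
    drawn per ``body_tile_bp`` tile (the tile total is Poisson with the
    tile-summed rate and stored as a constant per-bp value, so any window
    sum over whole tiles is an exact Poisson count); intergenic background
    is Poisson at ``background_rate`` per bp on each strand. Set
    ``body_tile_bp=1`` for single-base bodies.
    """
    if condition not in ("ctrl", "treat"):
        raise ValidationError(f"condition must be 'ctrl' or 'treat', got {condition!r}")
    stream = _STREAM_CTRL if condition == "ctrl" else _STREAM_TREAT
    rng = config.rng(stream)
    prom_col = f"promoter_rate_{condition}"
    body_col = f"body_rate_{condition}"
    rates = truth.set_index("gene_id")
    prom_span = config.promoter_up + config.promoter_down

    runs: dict[str, dict[str, list]] = {
        "+": {"starts": [], "ends": [], "values": []},
        "-": {"starts": [], "ends": [], "values": []},
    }
    tile = max(int(config.body_tile_bp), 1)
    occupied: list[tuple[int, int]] = []
    for strand in ("+", "-"):
        strand_genes = [g for g in genes if g.strand == strand]
        if not strand_genes:
            continue
        # Each gene contributes draw units: one per base over the promoter
        # window and one per body tile. A unit's Poisson mean is
        # rate * span; the drawn count is stored as count/span per bp, so
        # window sums recover exact Poisson totals.
        starts_l, spans_l, lam_l = [], [], []
        for g in strand_genes:
            w_start, w_end = _gene_signal_region(g, config)
            occupied.append((w_start, w_end))
            prom_rate = float(rates.at[g.gene_id, prom_col])
            body_rate = float(rates.at[g.gene_id, body_col])
            body_len = (w_end - w_start) - prom_span
            n_tiles = (body_len + tile - 1) // tile
            tile_spans = np.full(n_tiles, tile, dtype=np.int64)
            if body_len % tile:
                tile_spans[-1] = body_len % tile
            if strand == "+":
                unit_spans = np.concatenate(
                    (np.ones(prom_span, dtype=np.int64), tile_spans)
                )
                unit_rates = np.concatenate(
                    (np.full(prom_span, prom_rate), np.full(n_tiles, body_rate))
                )
            else:
                unit_spans = np.concatenate(
                    (tile_spans[::-1], np.ones(prom_span, dtype=np.int64))
                )
                unit_rates = np.concatenate(
                    (np.full(n_tiles, body_rate), np.full(prom_span, prom_rate))
                )
            unit_starts = w_start + np.concatenate(
                ([0], np.cumsum(unit_spans)[:-1])
            )
            starts_l.append(unit_starts)
            spans_l.append(unit_spans)
            lam_l.append(unit_rates * unit_spans)
        unit_starts = np.concatenate(starts_l)
        unit_spans = np.concatenate(spans_l)
        lam = np.concatenate(lam_l)
        if config.overdispersion is not None:
            shape = config.overdispersion
            lam = lam * rng.gamma(shape, 1.0 / shape, size=len(lam))
        counts = rng.poisson(lam)
        keep = counts > 0
        d = runs[strand]
        d["starts"].append(unit_starts[keep])
        d["ends"].append(unit_starts[keep] + unit_spans[keep])
        d["values"].append(counts[keep] / unit_spans[keep])

    # sparse intergenic background on both strands
    occupied.sort()
    gaps: list[tuple[int, int]] = []
    cursor = 0
    pad = 10
    for s, e in occupied:
        if s - pad > cursor:
            gaps.append((cursor, s - pad))
        cursor = max(cursor, e + pad)
    if cursor < config.chrom_length:
        gaps.append((cursor, config.chrom_length))
    gap_starts = np.array([g[0] for g in gaps], dtype=np.int64)
    gap_lens = np.array([g[1] - g[0] for g in gaps], dtype=np.int64)
    total_gap = int(gap_lens.sum())
    gap_cum = np.concatenate(([0], np.cumsum(gap_lens)))
    for strand in ("+", "-"):
        k = rng.poisson(config.background_rate * total_gap)
        if k > 0:
            flat = rng.integers(0, total_gap, size=k)
            gi = np.searchsorted(gap_cum, flat, side="right") - 1
            pos = gap_starts[gi] + (flat - gap_cum[gi])
            upos, ucnt = np.unique(pos, return_counts=True)
            d = runs[strand]
            d["starts"].append(upos)
            d["ends"].append(upos + 1)
            d["values"].append(ucnt.astype(np.float64))

    out = {}
    for strand in ("+", "-"):
        d = runs[strand]
        if not d["starts"]:
            arr = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
        elif len(d["starts"]) == 1:
            arr = (d["starts"][0], d["ends"][0], d["values"][0])
        else:
            # gene runs and background runs are each sorted and mutually
            # disjoint; merge them by insertion instead of a global sort
            gs, ge, gv = d["starts"][0], d["ends"][0], d["values"][0]
            bs, be, bv = d["starts"][1], d["ends"][1], d["values"][1]
            ins = np.searchsorted(gs, bs)
            arr = (
                np.insert(gs, ins, bs),
                np.insert(ge, ins, be),
                np.insert(gv, ins, bv),
            )
        out[strand] = CoverageTrack({config.chrom: arr}, strand=strand, _presorted=True)
    return out


def simulate_peaks(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: GeneratorConfig,
    assay_index: int = 0,
) -> list[list[Peak]]:
    """Replicate peak calls: one low-FDR peak per promoter plus decoys.

    True peaks span TSS +/- 200 bp with boundaries jittered +/- 20 bp per
    replicate and FDR uniform in (0, 0.01); decoys are intergenic with FDR
    uniform in [0.05, 1], so the default FDR filter removes them all.
    """
    if config.replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = config.rng(_STREAM_PEAKS, assay_index)
    rates = truth.set_index("gene_id")
    half = 200
    reps: list[list[Peak]] = []
    gene_extent = [(g.interval.start, g.interval.end) for g in genes]
    gene_extent.sort()
    for _ in range(config.replicates):
        peaks: list[Peak] = []
        for g in genes:
            j1, j2 = rng.integers(-20, 21, size=2)
            center = g.tss if g.strand == "+" else g.tss - 1
            s = max(center - half + int(j1), 0)
            e = center + half + int(j2)
            fdr = float(rng.uniform(0.0, 0.01))
            score = float(rates.at[g.gene_id, "promoter_rate_ctrl"])
            peaks.append(Peak(GenomicInterval(config.chrom, s, e), score, fdr))
        for _ in range(config.n_decoys):
            length = int(rng.integers(200, 401))
            for _attempt in range(20):
                s = int(rng.integers(0, config.chrom_length - length))
                i = np.searchsorted([ge[0] for ge in gene_extent], s + length)
                clash = (i > 0 and gene_extent[i - 1][1] > s - 2 * half)
                if not clash:
                    break
            fdr = float(rng.uniform(0.05, 1.0))
            peaks.append(Peak(GenomicInterval(config.chrom, s, s + length), 0.0, fdr))
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        reps.append(peaks)
    return reps


def simulate_accessibility(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: GeneratorConfig,
    condition: str,
    assay_index: int = 0,
) -> CoverageTrack:
    """Unstranded accessibility-style coverage over promoters.

    Each promoter carries Poisson signal proportional to that condition's
    promoter rate over TSS +/- promoter_down bp, so a pause-releasing
    treatment (which lowers promoter rates) shows reduced accessibility at
    the same promoters. Separate ``assay_index`` values give independent
    noise, emulating two assays reading the same underlying chromatin state.
    """
    if condition not in ("ctrl", "treat"):
        raise ValidationError(f"condition must be 'ctrl' or 'treat', got {condition!r}")
    cond_idx = 0 if condition == "ctrl" else 1
    rng = config.rng(_STREAM_ACCESS, assay_index, cond_idx)
    rates = truth.set_index("gene_id")
    half = config.promoter_down
    starts_l, ends_l, values_l = [], [], []
    for g in genes:
        rate = float(rates.at[g.gene_id, f"promoter_rate_{condition}"]) * 0.5
        center = g.tss if g.strand == "+" else g.tss - 1
        w_start, w_end = max(center - half, 0), center + half
        counts = rng.poisson(rate, size=w_end - w_start).astype(np.float64)
        s, e, v = runs_from_dense(counts, offset=w_start)
        keep = v != 0
        starts_l.append(s[keep])
        ends_l.append(e[keep])
        values_l.append(v[keep])
    if starts_l:
        arr = (
            np.concatenate(starts_l),
            np.concatenate(ends_l),
            np.concatenate(values_l),
        )
    else:  # pragma: no cover
        arr = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
    return CoverageTrack({config.chrom: arr}, strand=".")


def make_gene_sets(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    n_random_sets: int = 8,
    set_size: int = 100,
) -> list[GeneSet]:
    """Annotation sets for ORA testing: paused-enriched, unchanged-enriched,
    and random sets drawn from all genes."""
    rng = config.rng(_STREAM_SETS)
    all_ids = truth["gene_id"].to_numpy()
    paused = truth.loc[truth["true_class"] == CLASS_PAUSED, "gene_id"].to_numpy()
    unchanged = truth.loc[truth["true_class"] == CLASS_UNCHANGED, "gene_id"].to_numpy()
    sets: list[GeneSet] = []

    def sample(pool: np.ndarray, k: int) -> frozenset[str]:
        k = min(k, len(pool))
        return frozenset(rng.choice(pool, size=k, replace=False).tolist())

    if len(paused):
        mix = sample(paused, int(set_size * 0.8)) | sample(all_ids, set_size // 5)
        sets.append(GeneSet("paused_enriched", frozenset(mix)))
    if len(unchanged):
        mix = sample(unchanged, int(set_size * 0.8)) | sample(all_ids, set_size // 5)
        sets.append(GeneSet("unchanged_enriched", frozenset(mix)))
    for i in range(n_random_sets):
        sets.append(GeneSet(f"random_{i}", sample(all_ids, set_size)))
    return sets


def generate_bundle(config: GeneratorConfig, out_dir: str) -> dict:
    """Write a complete synthetic study to disk and return its file map.

    Emits the annotation (GTF), stranded GRO-seq-like bedGraphs for both
    conditions, two unstranded accessibility bedGraph pairs ("atac" and
    "h3k27ac" style), replicate narrowPeak files per assay, ORA gene sets
    (GMT), the truth table (TSV) and a provenance JSON recording the
    generator parameters and seed. The returned dict maps straight onto
    the pipeline's run-config fields.
    """
    import json
    import os

    from .genome_io import write_bedgraph, write_gtf, write_peaks_narrowpeak
    from .enrichment import write_gmt

    os.makedirs(out_dir, exist_ok=True)
    genes, truth = generate_genome(config)

    paths: dict = {}
    annotation = os.path.join(out_dir, "genes.gtf")
    write_gtf(genes, annotation)
    paths["annotation"] = annotation

    truth_path = os.path.join(out_dir, "truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")
    paths["truth"] = truth_path

    paths["coverage"] = {}
    for cond in ("ctrl", "treat"):
        tracks = simulate_coverage(genes, truth, config, cond)
        cond_paths = {}
        for strand, label in (("+", "plus"), ("-", "minus")):
            p = os.path.join(out_dir, f"groseq_{cond}_{label}.bedgraph")
            write_bedgraph(tracks[strand], p)
            cond_paths[strand] = p
        paths["coverage"][cond] = cond_paths

    paths["assay_coverage"] = {}
    for ai, assay in enumerate(("atac", "h3k27ac")):
        cond_paths = {}
        for cond in ("ctrl", "treat"):
            track = simulate_accessibility(genes, truth, config, cond, assay_index=ai)
            p = os.path.join(out_dir, f"{assay}_{cond}.bedgraph")
            write_bedgraph(track, p)
            cond_paths[cond] = p
        paths["assay_coverage"][assay] = cond_paths

    paths["peaks"] = {}
    for ai, assay in enumerate(("atac", "h3k27ac")):
        reps = simulate_peaks(genes, truth, config, assay_index=ai)
        rep_paths = []
        for ri, rep in enumerate(reps, 1):
            p = os.path.join(out_dir, f"{assay}_rep{ri}.narrowPeak")
            write_peaks_narrowpeak(rep, p)
            rep_paths.append(p)
        paths["peaks"][assay] = rep_paths

    sets_path = os.path.join(out_dir, "gene_sets.gmt")
    write_gmt(make_gene_sets(truth, config), sets_path)
    paths["gene_sets"] = sets_path

    prov = {
        "generator": "pausekit.synthetic",
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
    }
    prov_path = os.path.join(out_dir, "provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    paths["provenance"] = prov_path
    return paths
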