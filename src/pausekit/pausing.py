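"""Pausing release ratio (PRR) computation and gene-group classification.

The PRR of a gene is the ratio of engaged-polymerase signal density in its
body to the density at its promoter::

    PRR = (body_density + pc) / (promoter_density + pc)

where both densities are signal per bp per million total library signal and
``pc`` is a small pseudocount guarding silent promoters. A high PRR means
polymerase has been released into productive elongation; a low PRR means it
sits paused near the promoter. Between a control and a treatment condition,

    log2 PRR_FC = log2(PRR_treat / PRR_ctrl)

quantifies pause release: genes with log2 PRR_FC above a threshold (default
0.585, i.e. a 1.5-fold change) form Group I ("Pol II paused" genes, whose
pausing is released by the treatment), genes inside (-threshold, threshold)
form Group II ("others"), and genes below -threshold are "Decreased".
Genes with negligible control promoter activity are excluded before
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genome_io import CoverageTrack, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

GROUP_I = "GroupI_paused"
GROUP_II = "GroupII_other"
GROUP_DECREASED = "Decreased"
GROUP_EXCLUDED = "Excluded"

DEFAULT_LOG2_THRESHOLD = 0.585  # log2(1.5), rounded as conventionally quoted
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class PausingWindows:
    """Promoter and body quantification windows of one gene.

    Both windows lie on the gene's chromosome; the body is 3' of the
    promoter in the gene's orientation and the two are disjoint.
    """

    gene_id: str
    promoter: GenomicInterval
    body: GenomicInterval


@dataclass(frozen=True)
class ECDFComparison:
    """Two samples, their K-S statistic D, and the asymptotic p-value."""

    sample_a: np.ndarray
    sample_b: np.ndarray
    ks_statistic: float
    p_value: float


def build_windows(
    genes: list[GeneModel],
    promoter_up: int = 50,
    promoter_down: int = 300,
    body_gap: int = 300,
    body_extent: int | str = "to-tes",
) -> list[PausingWindows]:
    """Derive promoter/body windows around each gene's TSS.

    The promoter spans ``[TSS - promoter_up, TSS + promoter_down)`` in the
    gene's orientation; the body starts ``body_gap`` downstream of the TSS
    and runs to the TES (``body_extent="to-tes"``) or for a fixed number of
    bp clipped at the TES. Genes whose body window would be empty — shorter
    than ``body_gap`` — are omitted with a logged reason, not truncated.

    Windows may extend upstream past position 0 conceptually; they are
    clipped at 0 (with the promoter shortened) since coverage is undefined
    there.
    """
    if promoter_up < 0 or promoter_down < 0 or body_gap < 0:
        raise ValidationError("window extents must be non-negative")
    fixed = None if body_extent == "to-tes" else int(body_extent)
    if fixed is not None and fixed <= 0:
        raise ValidationError("fixed body_extent must be positive")
    out: list[PausingWindows] = []
    n_skipped = 0
    for g in genes:
        tss, tes = g.tss, g.tes
        if g.strand == "+":
            prom = (tss - promoter_up, tss + promoter_down)
            body_end = tes if fixed is None else min(tss + body_gap + fixed, tes)
            body = (tss + body_gap, body_end)
        else:
            prom = (tss - promoter_down, tss + promoter_up)
            body_start = tes if fixed is None else max(tss - body_gap - fixed, tes)
            body = (body_start, tss - body_gap)
        prom = (max(prom[0], 0), prom[1])
        body = (max(body[0], 0), body[1])
        if body[1] <= body[0]:
            logger.info("gene %s omitted: body window empty (gene too short)", g.gene_id)
            n_skipped += 1
            continue
        if prom[1] <= prom[0]:
            logger.info("gene %s omitted: promoter window empty", g.gene_id)
            n_skipped += 1
            continue
        out.append(
            PausingWindows(
                g.gene_id,
                GenomicInterval(g.chrom, prom[0], prom[1], g.strand),
                GenomicInterval(g.chrom, body[0], body[1], g.strand),
            )
        )
    if n_skipped:
        logger.info("build_windows: omitted %d/%d genes", n_skipped, len(genes))
    return out


def window_density(
    track: CoverageTrack,
    window: GenomicInterval,
    library_total: float,
) -> float:
    """Mean signal per bp per million total library signal over a window.

    density = (window signal sum / window length) * (1e6 / library_total).
    The window length in the denominator is the full requested length even
    when the window runs past the end of covered territory (uncovered bases
    contribute zero signal).
    """
    if library_total <= 0:
        raise ValidationError("library_total must be positive")
    if window.length <= 0:
        raise ValidationError("zero-length window")
    total = track.window_sum(window.chrom, window.start, window.end)
    return (total / window.length) * (1e6 / library_total)


def compute_prr(
    promoter_density: float,
    body_density: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Pausing release ratio: body over promoter density, pseudocounted.

    PRR = (body + pc) / (promoter + pc). As pc -> 0 this approaches the raw
    density ratio and is invariant to common rescaling of both densities.
    """
    if promoter_density < 0 or body_density < 0:
        raise ValidationError("densities must be non-negative")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return (body_density + pseudocount) / (promoter_density + pseudocount)


def classify_gene(
    log2_prr_fc: float,
    threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> str:
    """Assign the group label from a gene's log2 PRR fold change.

    Strictly above ``threshold`` is Group I (paused, released by treatment);
    strictly below ``-threshold`` is Decreased; everything else — including
    exact boundary equality, a measure-zero case needing a deterministic
    rule — is Group II.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if log2_prr_fc > threshold:
        return GROUP_I
    if log2_prr_fc < -threshold:
        return GROUP_DECREASED
    return GROUP_II


def prr_table(
    windows: list[PausingWindows],
    ctrl_tracks: dict[str, CoverageTrack],
    treat_tracks: dict[str, CoverageTrack],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    min_activity_quantile: float = 0.25,
    ctrl_total: float | None = None,
    treat_total: float | None = None,
) -> pd.DataFrame:
    """Per-gene densities, PRRs, log2 fold change, and group label.

    ``ctrl_tracks``/``treat_tracks`` map strand labels to tracks: keys
    ``"+"`` and ``"-"`` for stranded data (each gene is quantified on its
    sense strand) or a single ``"."`` entry for unstranded data. Library
    totals default to the summed total signal of each condition's tracks.

    Genes whose control promoter density falls below the
    ``min_activity_quantile`` quantile across all genes are labelled
    Excluded before classification (pausing is a property of actively
    transcribed genes; ratios at silent promoters are pseudocount noise).
    """
    if not windows:
        raise ValidationError("no pausing windows supplied")
    if not (0.0 <= min_activity_quantile < 1.0):
        raise ValidationError("min_activity_quantile must be in [0, 1)")
    ctrl_total = ctrl_total or sum(t.total_signal for t in ctrl_tracks.values())
    treat_total = treat_total or sum(t.total_signal for t in treat_tracks.values())

    def pick(tracks: dict[str, CoverageTrack], strand: str) -> CoverageTrack:
        if strand in tracks:
            return tracks[strand]
        if "." in tracks:
            return tracks["."]
        raise ValidationError(f"no coverage track for strand {strand!r}")

    rows = []
    for w in windows:
        strand = w.promoter.strand
        tc, tt = pick(ctrl_tracks, strand), pick(treat_tracks, strand)
        pc = window_density(tc, w.promoter, ctrl_total)
        bc = window_density(tc, w.body, ctrl_total)
        pt = window_density(tt, w.promoter, treat_total)
        bt = window_density(tt, w.body, treat_total)
        prr_c = compute_prr(pc, bc, pseudocount)
        prr_t = compute_prr(pt, bt, pseudocount)
        rows.append((w.gene_id, pc, bc, pt, bt, prr_c, prr_t, np.log2(prr_t / prr_c)))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "promoter_density_ctrl", "body_density_ctrl",
            "promoter_density_treat", "body_density_treat",
            "prr_ctrl", "prr_treat", "log2_prr_fc",
        ],
    )
    cutoff = (
        float(np.quantile(df["promoter_density_ctrl"], min_activity_quantile))
        if min_activity_quantile > 0
        else -np.inf
    )
    active = df["promoter_density_ctrl"] >= cutoff
    df["group"] = [
        classify_gene(fc, log2_threshold) if ok else GROUP_EXCLUDED
        for fc, ok in zip(df["log2_prr_fc"], active)
    ]
    return df


def ks_two_sample(a, b) -> ECDFComparison:
    """Two-sample Kolmogorov-Smirnov comparison.

    D is the exact supremum over pooled sample points of the absolute ECDF
    difference; the p-value comes from the asymptotic two-sided K-S
    distribution with effective n = n_a*n_b/(n_a+n_b), appropriate at the
    thousands-of-genes scale this package targets.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("K-S test requires two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return ECDFComparison(a, b, float(res.statistic), float(res.pvalue))


def ecdf_table(sample) -> pd.DataFrame:
    """Right-continuous ECDF as (value, cumulative_fraction) step points.

    Ties collapse to one step; the final fraction is exactly 1.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise ValidationError("empty sample")
    values, counts = np.unique(x, return_counts=True)
    frac = np.cumsum(counts) / x.size
    frac[-1] = 1.0
    return pd.DataFrame({"value": values, "cumulative_fraction": frac})
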