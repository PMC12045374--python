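"""Anchor-centred signal matrices and averaged metagene profiles.

A :class:`MetaMatrix` holds, for many anchors (TSSs or peak midpoints), the
mean per-bp signal in fixed-width bins at offsets relative to the anchor.
Minus-strand anchor rows are orientation-flipped so column 0 is always the
5'-most (upstream) bin; profiles are column means with a seeded bootstrap
confidence band. Bases falling off the start or known end of a chromosome
are padded with NaN, not zero, so edge genes do not drag column means down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import CoverageTrack
from .peaks import ConsensusPeakSet


@dataclass
class MetaMatrix:
    """Rows = anchors, columns = offset bins of mean per-bp signal."""

    row_ids: list[str]
    bin_edges: np.ndarray  # offsets in bp, length n_bins + 1, 5'->3'
    values: np.ndarray     # (n_rows, n_bins), NaN where off-chromosome

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.bin_edges) - 1):
            raise ValidationError("MetaMatrix shape mismatch")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{int(a)}:{int(b)}" for a, b in zip(self.bin_edges[:-1], self.bin_edges[1:])]
        return pd.DataFrame(self.values, index=self.row_ids, columns=cols)


def _resolve_track(track, strand: str) -> CoverageTrack:
    """Accept a single track or a {strand: track} mapping (sense-strand pick)."""
    if isinstance(track, CoverageTrack):
        return track
    if strand in track:
        return track[strand]
    if "." in track:
        return track["."]
    raise ValidationError(f"no track for strand {strand!r}")


def matrix_at_anchors(
    track,
    anchors: list[tuple[str, int, str]],
    upstream: int = 100,
    downstream: int = 2000,
    bin_size: int = 10,
    library_total: float | None = None,
    chrom_sizes: dict[str, int] | None = None,
    row_ids: list[str] | None = None,
) -> MetaMatrix:
    """Per-anchor binned signal over ``[-upstream, +downstream)`` bp.

    ``anchors`` are ``(chrom, position, strand)`` triples; for minus-strand
    anchors the window is mirrored and the row reversed so that offsets read
    5'->3'. Each cell is the mean per-bp signal in its bin, scaled to
    per-million-library units. ``track`` may be a single
    :class:`CoverageTrack` or a ``{"+"/"-"/".": track}`` mapping, in which
    case each anchor reads its sense strand.

    ``chrom_sizes`` bounds the chromosomes; windows past a boundary (or
    below 0) get NaN in the affected bins. Without sizes, the rightmost
    covered base of each chromosome in the (first) track is used.
    """
    if not anchors:
        raise ValidationError("no anchors supplied")
    span = upstream + downstream
    if span <= 0 or bin_size <= 0 or span % bin_size != 0:
        raise ValidationError(
            f"window span {span} must be a positive multiple of bin {bin_size}"
        )
    n_bins = span // bin_size
    some_track = track if isinstance(track, CoverageTrack) else next(iter(track.values()))
    if library_total is None:
        if isinstance(track, CoverageTrack):
            library_total = track.total_signal
        else:
            library_total = sum(t.total_signal for t in track.values())
    if library_total <= 0:
        raise ValidationError("library_total must be positive")
    scale = 1e6 / library_total

    values = np.empty((len(anchors), n_bins))
    for r, (chrom, pos, strand) in enumerate(anchors):
        t = _resolve_track(track, strand)
        size = (
            chrom_sizes.get(chrom)
            if chrom_sizes is not None
            else max(t.chrom_max_end(chrom), some_track.chrom_max_end(chrom))
        )
        if strand == "-":
            win_start, win_end = pos - downstream, pos + upstream
        else:
            win_start, win_end = pos - upstream, pos + downstream
        base = t.dense(chrom, win_start, win_end) * scale
        # mask off-chromosome bases with NaN
        offsets = np.arange(win_start, win_end)
        invalid = offsets < 0
        if size is not None:
            invalid |= offsets >= size
        base[invalid] = np.nan
        if strand == "-":
            base = base[::-1]
        values[r] = base.reshape(n_bins, bin_size).mean(axis=1)
    edges = np.arange(-upstream, downstream + 1, bin_size)
    ids = row_ids if row_ids is not None else [f"anchor_{i}" for i in range(len(anchors))]
    return MetaMatrix(list(ids), edges, values)


def centered_matrix(
    track,
    peaks: ConsensusPeakSet,
    flank: int = 1000,
    bin_size: int = 10,
    library_total: float | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> MetaMatrix:
    """Peak-midpoint-centred matrix over the symmetric window [-flank, +flank)."""
    if len(peaks) == 0:
        raise ValidationError("empty peak set")
    anchors = [(p.interval.chrom, p.interval.midpoint, ".") for p in peaks.peaks]
    ids = [
        f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}" for p in peaks.peaks
    ]
    return matrix_at_anchors(
        track, anchors,
        upstream=flank, downstream=flank, bin_size=bin_size,
        library_total=library_total, chrom_sizes=chrom_sizes, row_ids=ids,
    )


def profile(
    matrix: MetaMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Column means (ignoring NaN padding) with a bootstrap confidence band.

    Rows are resampled with replacement ``n_boot`` times under a seeded
    generator; the band is the (1-ci)/2 and 1-(1-ci)/2 quantiles of the
    resampled column means.
    """
    if matrix.values.shape[0] == 0:
        raise ValidationError("empty matrix")
    vals = matrix.values
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
    n = vals.shape[0]
    rng = np.random.default_rng(seed)
    if n == 1:
        lo = hi = mean.copy()
    else:
        boots = np.empty((n_boot, vals.shape[1]))
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            with np.errstate(invalid="ignore"):
                boots[i] = np.nanmean(vals[idx], axis=0)
        alpha = (1.0 - ci) / 2.0
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "offset": matrix.bin_centers,
            "mean": mean,
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )


def plot_profile(profiles: dict[str, pd.DataFrame], path: str, title: str = "") -> None:
    """Line plot of one or more metagene profiles with confidence bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof["offset"], prof["mean"], label=label)
        ax.fill_between(prof["offset"], prof["ci_lower"], prof["ci_upper"], alpha=0.2)
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("signal (per bp per million)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: MetaMatrix, path: str, title: str = "") -> None:
    """Heatmap with rows sorted by decreasing total signal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with np.errstate(invalid="ignore"):
        order = np.argsort(-np.nansum(matrix.values, axis=1), kind="stable")
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(
        matrix.values[order],
        aspect="auto",
        interpolation="nearest",
        extent=(matrix.bin_edges[0], matrix.bin_edges[-1], len(matrix.row_ids), 0),
        cmap="viridis",
    )
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("anchors (sorted by signal)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="signal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
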