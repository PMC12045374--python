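"""Consensus peak construction, cross-assay intersection, and annotation.

A *consensus peak set* collapses replicate (or assay) peak calls into one
non-overlapping set of regions supported by at least ``min_sets`` of the
inputs after an FDR filter. Supported cores are bases covered by enough
distinct input sets; each consensus peak is the union extent of the cores
plus every contributing input peak touching them, and inherits the minimum
FDR of its contributors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .genome_io import CoverageTrack, GeneModel, GenomicInterval, Peak

FEATURE_PROMOTER = "promoter"
FEATURE_EXON = "exon"
FEATURE_INTRON = "intron"
FEATURE_DISTAL = "distal_intergenic"


@dataclass
class ConsensusPeakSet:
    """Non-overlapping, sorted peaks plus the provenance of their derivation."""

    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start)
        )
        prev: Peak | None = None
        for p in self.peaks:
            if (
                prev is not None
                and prev.interval.chrom == p.interval.chrom
                and p.interval.start < prev.interval.end
            ):
                raise ValidationError(
                    "consensus peak set contains overlapping peaks at "
                    f"{p.interval.chrom}:{p.interval.start}"
                )
            prev = p

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass(frozen=True)
class PeakAnnotation:
    """A peak's genomic feature class and nearest gene."""

    peak: Peak
    feature_class: str
    nearest_gene_id: str | None
    distance_to_tss: int | None


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended [start, end) pairs."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def consensus(
    peak_sets: list[list[Peak]],
    min_sets: int | None = None,
    fdr_max: float = 0.05,
    overlap_rule: str = "any_bp",
    reciprocal_fraction: float = 0.5,
) -> ConsensusPeakSet:
    """Build the consensus of several peak sets.

    Peaks with ``fdr > fdr_max`` are dropped first. Under ``any_bp`` (the
    default) a base is supported where >= ``min_sets`` distinct input sets
    cover it; each consensus peak is the union extent of a maximal run of
    supported bases together with every passing input peak overlapping it.
    Under ``reciprocal_fraction`` two peaks from different sets are linked
    when each covers at least that fraction of the other; connected
    components spanning >= ``min_sets`` sets become consensus peaks (union
    extent). ``min_sets`` defaults to all input sets, the strictest
    "across all replicates" reading.
    """
    if not peak_sets:
        raise ValidationError("consensus requires at least one peak set")
    if not (0.0 < fdr_max <= 1.0):
        raise ValidationError("fdr_max must be in (0, 1]")
    n_sets = len(peak_sets)
    min_sets = n_sets if min_sets is None else int(min_sets)
    if not (1 <= min_sets <= n_sets):
        raise ValidationError(f"min_sets must be in [1, {n_sets}]")

    filtered = [[p for p in ps if p.fdr <= fdr_max] for ps in peak_sets]
    if overlap_rule == "any_bp":
        peaks = _consensus_any_bp(filtered, min_sets)
    elif overlap_rule == "reciprocal_fraction":
        peaks = _consensus_reciprocal(filtered, min_sets, reciprocal_fraction)
    else:
        raise ValidationError(f"unknown overlap_rule {overlap_rule!r}")
    prov = {
        "operation": "consensus",
        "n_input_sets": n_sets,
        "min_sets": min_sets,
        "fdr_max": fdr_max,
        "overlap_rule": overlap_rule,
    }
    if overlap_rule == "reciprocal_fraction":
        prov["reciprocal_fraction"] = reciprocal_fraction
    return ConsensusPeakSet(peaks, prov)


def _consensus_any_bp(filtered: list[list[Peak]], min_sets: int) -> list[Peak]:
    chroms = sorted({p.interval.chrom for ps in filtered for p in ps})
    out: list[Peak] = []
    for chrom in chroms:
        # distinct-set occupancy: merge within each set before sweeping
        events: list[tuple[int, int]] = []
        for ps in filtered:
            ivs = [(p.interval.start, p.interval.end)
                   for p in ps if p.interval.chrom == chrom]
            for s, e in _merge(ivs):
                events.append((s, 1))
                events.append((e, -1))
        if not events:
            continue
        events.sort()
        cores: list[tuple[int, int]] = []
        occ, core_start = 0, None
        for x, delta in events:
            new_occ = occ + delta
            if occ < min_sets <= new_occ:
                core_start = x
            elif new_occ < min_sets <= occ and core_start is not None:
                cores.append((core_start, x))
                core_start = None
            occ = new_occ
        cores = _merge(cores)
        if not cores:
            continue
        # attach every passing input peak overlapping a core; union extent
        core_starts = np.array([c[0] for c in cores])
        core_ends = np.array([c[1] for c in cores])
        members: list[tuple[int, int, float, float]] = [
            (s, e, np.inf, 0.0) for s, e in cores
        ]
        for ps in filtered:
            for p in ps:
                if p.interval.chrom != chrom:
                    continue
                i = int(np.searchsorted(core_ends, p.interval.start, side="right"))
                if i < len(cores) and core_starts[i] < p.interval.end:
                    members.append(
                        (p.interval.start, p.interval.end, p.fdr, p.score)
                    )
        for s, e, f, sc in _merge_scored(members):
            out.append(Peak(GenomicInterval(chrom, s, e), sc, 1.0 if np.isinf(f) else f))
    return out


def _merge_scored(
    members: list[tuple[int, int, float, float]],
) -> list[tuple[int, int, float, float]]:
    """Merge (start, end, fdr, score) tuples; book-ended regions coalesce
    so the result matches a per-base covered-set oracle. Merged regions take
    the min FDR and max score of their members."""
    members = sorted(members)
    merged: list[list[float]] = [list(members[0])]
    for s, e, f, sc in members[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = min(merged[-1][2], f)
            merged[-1][3] = max(merged[-1][3], sc)
        else:
            merged.append([s, e, f, sc])
    return [(int(s), int(e), f, sc) for s, e, f, sc in merged]


def _consensus_reciprocal(
    filtered: list[list[Peak]], min_sets: int, frac: float
) -> list[Peak]:
    if not (0.0 < frac <= 1.0):
        raise ValidationError("reciprocal_fraction must be in (0, 1]")
    tagged = [
        (p.interval.chrom, p.interval.start, p.interval.end, si, p)
        for si, ps in enumerate(filtered)
        for p in ps
    ]
    tagged.sort(key=lambda t: (t[0], t[1]))
    parent = list(range(len(tagged)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    active: list[int] = []
    for i, (chrom, s, e, si, _p) in enumerate(tagged):
        active = [
            j for j in active
            if tagged[j][0] == chrom and tagged[j][2] > s
        ]
        for j in active:
            _, s2, e2, sj, _ = tagged[j]
            if sj == si:
                continue
            ov = min(e, e2) - max(s, s2)
            if ov >= frac * (e - s) and ov >= frac * (e2 - s2):
                union(i, j)
        active.append(i)
    groups: dict[int, list[int]] = {}
    for i in range(len(tagged)):
        groups.setdefault(find(i), []).append(i)
    raw: list[Peak] = []
    for idxs in groups.values():
        if len({tagged[i][3] for i in idxs}) < min_sets:
            continue
        chrom = tagged[idxs[0]][0]
        s = min(tagged[i][1] for i in idxs)
        e = max(tagged[i][2] for i in idxs)
        f = min(tagged[i][4].fdr for i in idxs)
        sc = max(tagged[i][4].score for i in idxs)
        raw.append(Peak(GenomicInterval(chrom, s, e), sc, f))
    # components may still touch after taking union extents; coalesce
    by_chrom: dict[str, list[tuple[int, int, float, float]]] = {}
    for p in raw:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end, p.fdr, p.score)
        )
    out: list[Peak] = []
    for chrom in sorted(by_chrom):
        for s, e, f, sc in _merge_scored(by_chrom[chrom]):
            out.append(Peak(GenomicInterval(chrom, s, e), sc, f))
    return out


def intersect_assays(
    a: ConsensusPeakSet,
    b: ConsensusPeakSet,
    extent: str = "strict",
) -> ConsensusPeakSet:
    """Regions supported by both consensus sets (any-bp overlap).

    ``extent="strict"`` (default) emits the base-wise intersection, which
    can never exceed either parent; ``extent="union"`` emits the merged
    union extent of every pair of mutually overlapping parent peaks.
    """
    if extent not in ("strict", "union"):
        raise ValidationError(f"unknown extent rule {extent!r}")
    by_chrom_b: dict[str, list[Peak]] = {}
    for p in b.peaks:
        by_chrom_b.setdefault(p.interval.chrom, []).append(p)
    pieces: dict[str, list[tuple[int, int, float, float]]] = {}
    for p in a.peaks:
        for q in by_chrom_b.get(p.interval.chrom, []):
            if not p.interval.overlaps(q.interval):
                continue
            if extent == "strict":
                s = max(p.interval.start, q.interval.start)
                e = min(p.interval.end, q.interval.end)
            else:
                s = min(p.interval.start, q.interval.start)
                e = max(p.interval.end, q.interval.end)
            pieces.setdefault(p.interval.chrom, []).append(
                (s, e, min(p.fdr, q.fdr), max(p.score, q.score))
            )
    out: list[Peak] = []
    for chrom in sorted(pieces):
        for s, e, f, sc in _merge_scored(pieces[chrom]):
            out.append(Peak(GenomicInterval(chrom, s, e), sc, f))
    prov = {
        "operation": "intersect_assays",
        "extent": extent,
        "parents": [a.provenance, b.provenance],
    }
    return ConsensusPeakSet(out, prov)


def annotate_peaks(
    peaks: ConsensusPeakSet,
    genes: list[GeneModel],
    promoter_window: int = 2000,
) -> list[PeakAnnotation]:
    """Classify each peak as promoter/exon/intron/distal and find its gene.

    Precedence is promoter > exon > intron > distal_intergenic: any overlap
    with a +/- ``promoter_window`` bp window around a TSS wins regardless of
    other overlaps. The nearest gene is the one whose TSS is closest to the
    peak midpoint; the distance is signed in the gene's orientation
    (positive downstream of the TSS).
    """
    if promoter_window <= 0:
        raise ValidationError("promoter_window must be positive")
    by_chrom: dict[str, dict[str, list]] = {}
    for g in genes:
        d = by_chrom.setdefault(g.chrom, {"prom": [], "exon": [], "gene": [], "tss": []})
        d["prom"].append((max(g.tss - promoter_window, 0), g.tss + promoter_window))
        exons = g.exons if g.exons else (g.interval,)
        for ex in exons:
            d["exon"].append((ex.start, ex.end))
        d["gene"].append((g.interval.start, g.interval.end))
        d["tss"].append((g.tss, g.strand, g.gene_id))

    index: dict[str, dict] = {}
    for chrom, d in by_chrom.items():
        idx = {}
        for key in ("prom", "exon", "gene"):
            merged = _merge(d[key])
            idx[key] = (
                np.array([m[0] for m in merged], dtype=np.int64),
                np.array([m[1] for m in merged], dtype=np.int64),
            )
        tss_sorted = sorted(d["tss"])
        idx["tss_pos"] = np.array([t[0] for t in tss_sorted], dtype=np.int64)
        idx["tss_meta"] = tss_sorted
        index[chrom] = idx

    def hits(idx_pair, start: int, end: int) -> bool:
        starts, ends = idx_pair
        if len(starts) == 0:
            return False
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    out: list[PeakAnnotation] = []
    for p in peaks.peaks:
        iv = p.interval
        idx = index.get(iv.chrom)
        if idx is None:
            out.append(PeakAnnotation(p, FEATURE_DISTAL, None, None))
            continue
        if hits(idx["prom"], iv.start, iv.end):
            cls = FEATURE_PROMOTER
        elif hits(idx["exon"], iv.start, iv.end):
            cls = FEATURE_EXON
        elif hits(idx["gene"], iv.start, iv.end):
            cls = FEATURE_INTRON
        else:
            cls = FEATURE_DISTAL
        mid = iv.midpoint
        pos = idx["tss_pos"]
        i = int(np.searchsorted(pos, mid))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pos):
                cand = idx["tss_meta"][j]
                d_abs = abs(mid - cand[0])
                if best is None or d_abs < best[0]:
                    best = (d_abs, cand)
        tss, strand, gid = best[1]
        signed = (mid - tss) if strand == "+" else (tss - 1 - mid)
        out.append(PeakAnnotation(p, cls, gid, int(signed)))
    return out


def signal_fold_change_correlation(
    peaks: ConsensusPeakSet,
    assay_a: tuple[CoverageTrack, CoverageTrack],
    assay_b: tuple[CoverageTrack, CoverageTrack],
    pseudocount: float = 0.1,
) -> float:
    """Spearman correlation of per-peak log2 fold changes between two assays.

    For each assay the per-peak log2FC is
    ``log2((treat_density + pc) / (ctrl_density + pc))`` with densities in
    per-bp-per-million units; the return value is the rank correlation of
    the two log2FC vectors over the shared consensus peaks.
    """
    if len(peaks) < 3:
        raise ValidationError("need at least 3 peaks for a rank correlation")
    from .pausing import window_density  # local import avoids a cycle

    def fold_changes(ctrl: CoverageTrack, treat: CoverageTrack) -> np.ndarray:
        tc, tt = ctrl.total_signal, treat.total_signal
        if tc <= 0 or tt <= 0:
            raise ValidationError("coverage tracks must carry signal")
        fc = np.empty(len(peaks))
        for i, p in enumerate(peaks.peaks):
            dc = window_density(ctrl, p.interval, tc)
            dt = window_density(treat, p.interval, tt)
            fc[i] = np.log2((dt + pseudocount) / (dc + pseudocount))
        return fc

    fa = fold_changes(*assay_a)
    fb = fold_changes(*assay_b)
    rho = stats.spearmanr(fa, fb).statistic
    return float(rho)
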