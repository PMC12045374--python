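"""Genomic domain types and readers/writers for the standard formats.

Everything in memory uses one coordinate convention: 0-based, half-open
``[start, end)``, the BED convention. GTF (1-based, closed) is converted at
the I/O boundary and converted back on write, so a read/write round trip
restores the original 1-based coordinates exactly.

Chromosome names are taken verbatim from the input; no ``chr`` prefix
normalisation is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError

STRANDS = ("+", "-", ".")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: its extent, strand, and strand-aware TSS/TES anchors.

    The TSS/TES are boundary coordinates in the half-open convention: for a
    plus-strand gene the TSS equals ``interval.start``; for a minus-strand
    gene it equals ``interval.end`` (the 5'-most template base is
    ``interval.end - 1``). ``exons``, when present, are the gene's exonic
    intervals; an empty tuple means the transcript structure is unknown and
    the whole gene extent is treated as exonic.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: genes must be stranded (+ or -)"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Peak:
    """A scored interval with a linear-scale false discovery rate."""

    interval: GenomicInterval
    score: float = 0.0
    fdr: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(
                f"peak {self.interval.chrom}:{self.interval.start}-"
                f"{self.interval.end}: fdr {self.fdr} outside [0, 1]"
            )


class CoverageTrack:
    """Base-resolution non-negative signal, run-length encoded per chromosome.

    Stored as sorted, non-overlapping ``(start, end, value)`` runs, the
    bedGraph contract. Window sums are O(log n) via cumulative weighted sums;
    dense per-base views are materialised on demand.
    """

    def __init__(
        self,
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        strand: str = ".",
        _presorted: bool = False,
    ):
        if strand not in STRANDS:
            raise ValidationError(f"invalid strand {strand!r}")
        self.strand = strand
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        if runs:
            for chrom, (starts, ends, values) in runs.items():
                self._add_chrom(chrom, np.asarray(starts, dtype=np.int64),
                                np.asarray(ends, dtype=np.int64),
                                np.asarray(values, dtype=np.float64),
                                _presorted)

    def _add_chrom(self, chrom: str, starts, ends, values, presorted: bool = False) -> None:
        if not (len(starts) == len(ends) == len(values)):
            raise ValidationError(f"{chrom}: run arrays differ in length")
        if len(starts) == 0:
            self._runs[chrom] = (starts, ends, values)
            self._cum[chrom] = np.zeros(1)
            return
        if not presorted:
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts) or starts[0] < 0:
                raise ValidationError(f"{chrom}: malformed run coordinates")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"{chrom}: overlapping intervals near position {int(starts[i + 1])}"
                )
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative signal values")
        self._runs[chrom] = (starts, ends, values)
        cum = np.zeros(len(starts) + 1)
        np.cumsum(values * (ends - starts), out=cum[1:])
        self._cum[chrom] = cum

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        strand: str = ".",
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        runs = {}
        for chrom, recs in by_chrom.items():
            a = np.array(recs, dtype=np.float64).reshape(-1, 3)
            runs[chrom] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
        return cls(runs, strand=strand)

    @classmethod
    def from_dense(
        cls, dense: Mapping[str, np.ndarray], strand: str = "."
    ) -> "CoverageTrack":
        """Build a track from per-base arrays (index 0 = chromosome start)."""
        runs = {}
        for chrom, arr in dense.items():
            starts, ends, values = runs_from_dense(np.asarray(arr, dtype=np.float64))
            keep = values != 0
            runs[chrom] = (starts[keep], ends[keep], values[keep])
        return cls(runs, strand=strand)

    # -- queries ------------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    @property
    def total_signal(self) -> float:
        """Sum of value x span over all runs (library-size scaling basis)."""
        return float(sum(cum[-1] for cum in self._cum.values()))

    def chrom_max_end(self, chrom: str) -> int:
        starts, ends, _ = self._runs.get(chrom, (None, None, None))
        return int(ends[-1]) if ends is not None and len(ends) else 0

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total signal in ``[start, end)``; 0 outside covered regions."""
        if end <= start:
            raise ValidationError("window_sum: zero-length window")
        if chrom not in self._runs or len(self._runs[chrom][0]) == 0:
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0.0
        cum = self._cum[chrom]
        total = cum[j] - cum[i]
        if start > starts[i]:
            total -= (start - starts[i]) * values[i]
        if ends[j - 1] > end:
            total -= (ends[j - 1] - end) * values[j - 1]
        return float(total)

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over ``[start, end)`` (0 where uncovered).

        ``start`` may be negative or ``end`` beyond the last run; such bases
        are simply 0 — edge semantics are the caller's concern.
        """
        if end <= start:
            raise ValidationError("dense: zero-length window")
        out = np.zeros(end - start)
        if chrom not in self._runs:
            return out
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        for k in range(i, j):
            a = max(int(starts[k]), start) - start
            b = min(int(ends[k]), end) - start
            out[a:b] = values[k]
        return out

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.strand != other.strand or set(self._runs) != set(other._runs):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._runs[c], other._runs[c]))
            for c in self._runs
        )


def runs_from_dense(arr: np.ndarray, offset: int = 0):
    """Run-length encode a per-base array into (starts, ends, values)."""
    n = len(arr)
    if n == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change)).astype(np.int64)
    ends = np.concatenate((change, [n])).astype(np.int64)
    return starts + offset, ends + offset, arr[starts]


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"((?:[^"\\]|\\.)*)"')


def _gtf_attributes(field9: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(field9))


def read_annotation(path: str, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF or BED12.

    GTF coordinates (1-based, closed) are converted to the internal 0-based
    half-open convention. ``gene`` features define gene extents; ``exon``
    features, when present, populate per-gene exon lists. A GTF with only
    exon features gets gene extents from the exon span. Duplicate gene_ids
    raise :class:`ValidationError`.
    """
    if format == "gtf":
        genes = _read_gtf(path)
    elif format == "bed12":
        genes = _read_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _read_gtf(path: str) -> list[GeneModel]:
    extents: dict[str, list] = {}  # gene_id -> [chrom, start, end, strand, explicit]
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    path, lineno,
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"invalid 1-based closed coordinates {start1}-{end1}", path, lineno
                )
            if strand not in ("+", "-"):
                if feature in ("gene", "transcript", "exon"):
                    raise ParseError(f"gene feature with strand {strand!r}", path, lineno)
                continue
            gid = _gtf_attributes(attrs).get("gene_id")
            if gid is None:
                raise ParseError("missing gene_id attribute", path, lineno)
            start, end = start1 - 1, end1  # to 0-based half-open
            if feature == "gene":
                if gid in extents and extents[gid][4]:
                    raise ValidationError(f"duplicate gene_id {gid!r} in {path}")
                if gid not in extents:
                    order.append(gid)
                extents[gid] = [chrom, start, end, strand, True]
            elif feature == "exon":
                if gid not in extents:
                    order.append(gid)
                    extents[gid] = [chrom, start, end, strand, False]
                else:
                    rec = extents[gid]
                    rec[1] = min(rec[1], start)
                    rec[2] = max(rec[2], end)
                exons.setdefault(gid, []).append((start, end))
    out = []
    for gid in order:
        chrom, start, end, strand, _explicit = extents[gid]
        ex = tuple(
            GenomicInterval(chrom, s, e, strand)
            for s, e in sorted(exons.get(gid, []))
        )
        out.append(GeneModel(gid, GenomicInterval(chrom, start, end, strand), ex))
    return out


def _read_bed12(path: str) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"expected >=6 BED fields, got {len(f)}", path, lineno)
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
            except (ValueError, IndexError):
                raise ParseError("malformed BED line", path, lineno) from None
            exons: tuple[GenomicInterval, ...] = ()
            if len(f) >= 12:
                try:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                except ValueError:
                    raise ParseError("malformed BED12 block fields", path, lineno) from None
                if len(sizes) != len(offsets):
                    raise ParseError("blockSizes/blockStarts length mismatch", path, lineno)
                exons = tuple(
                    GenomicInterval(chrom, start + o, start + o + s, strand)
                    for o, s in zip(offsets, sizes)
                )
            out.append(GeneModel(name, GenomicInterval(chrom, start, end, strand), exons))
    return out


def write_gtf(genes: Sequence[GeneModel], path: str, source: str = "pausekit") -> None:
    """Write gene (and exon) features, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# coverage I/O
# ---------------------------------------------------------------------------

def read_coverage(path: str, format: str = "bedgraph", strand: str = ".") -> CoverageTrack:
    """Read a coverage track from bedGraph (or bigWig when pyBigWig is present).

    bedGraph intervals must be non-overlapping per chromosome and values
    non-negative; violations raise :class:`ValidationError`.
    """
    if format == "bedgraph":
        return _read_bedgraph(path, strand)
    if format == "bigwig":
        return _read_bigwig(path, strand)
    raise ValueError(f"unknown coverage format {format!r}")


def _read_bedgraph(path: str, strand: str) -> CoverageTrack:
    by_chrom: dict[str, list[list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"expected 4 bedGraph fields, got {len(f)}", path, lineno)
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise ParseError("malformed bedGraph line", path, lineno) from None
            by_chrom.setdefault(f[0], []).append([start, end, value])
    runs = {}
    for chrom, recs in by_chrom.items():
        a = np.array(recs)
        runs[chrom] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
    return CoverageTrack(runs, strand=strand)


def _read_bigwig(path: str, strand: str) -> CoverageTrack:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("bigWig support requires pyBigWig") from exc
    bw = pyBigWig.open(path)
    runs = {}
    try:
        for chrom, length in bw.chroms().items():
            ivs = bw.intervals(chrom, 0, length) or []
            a = np.array(ivs, dtype=np.float64).reshape(-1, 3)
            runs[chrom] = (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64), a[:, 2])
    finally:
        bw.close()
    return CoverageTrack(runs, strand=strand)


def write_bedgraph(track: CoverageTrack, path: str, keep_zeros: bool = False) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                if v == 0 and not keep_zeros:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# peak I/O
# ---------------------------------------------------------------------------

def read_peaks(
    path: str,
    format: str = "narrowpeak",
    fdr_column: int | None = None,
    fdr_is_neglog10: bool | None = None,
) -> list[Peak]:
    """Read peaks from narrowPeak or BED6+ into a (chrom, start)-sorted list.

    ``fdr_column`` is the 0-based column index holding the FDR; for
    narrowPeak it defaults to column 8 (qValue), which is stored as
    -log10 and converted to the linear scale. For BED6+ the values are
    taken as linear unless ``fdr_is_neglog10=True`` is passed. Linear
    values outside [0, 1] raise :class:`ValidationError` (a -log10 column
    read as linear is the classic mistake this catches).
    """
    if format == "narrowpeak":
        fdr_column = 8 if fdr_column is None else fdr_column
        fdr_is_neglog10 = True if fdr_is_neglog10 is None else fdr_is_neglog10
        min_fields = 10
    elif format == "bed6plus":
        if fdr_column is None:
            raise ValueError("bed6plus requires an explicit fdr_column")
        fdr_is_neglog10 = False if fdr_is_neglog10 is None else fdr_is_neglog10
        min_fields = fdr_column + 1
    else:
        raise ValueError(f"unknown peak format {format!r}")

    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < min_fields:
                raise ParseError(
                    f"expected >={min_fields} fields, got {len(f)}", path, lineno
                )
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                strand = f[5] if len(f) > 5 and f[5] in STRANDS else "."
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
                raw = float(f[fdr_column])
            except ValueError:
                raise ParseError("malformed peak line", path, lineno) from None
            if fdr_is_neglog10:
                if raw < 0:
                    raise ParseError(f"negative -log10 FDR {raw}", path, lineno)
                fdr = 10.0 ** (-raw)
            else:
                if not (0.0 <= raw <= 1.0):
                    raise ValidationError(
                        f"{path}:{lineno}: FDR {raw} outside [0, 1] on the linear "
                        "scale; pass fdr_is_neglog10=True for -log10 q-values"
                    )
                fdr = raw
            peaks.append(Peak(GenomicInterval(chrom, start, end, strand), score, fdr))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_peaks_narrowpeak(peaks: Sequence[Peak], path: str) -> None:
    """Write peaks as narrowPeak (qValue column holds -log10 FDR)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            neglog = -np.log10(p.fdr) if p.fdr > 0 else 999.0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t{p.score:g}\t"
                f"{iv.strand}\t{p.score:g}\t-1\t{neglog:.6g}\t-1\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t0\t{iv.strand}\n")
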