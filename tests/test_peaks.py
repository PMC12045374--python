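"""Consensus construction, intersection, annotation, and correlation."""

import numpy as np
import pytest

from pausekit import (
    ConsensusPeakSet,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    Peak,
    ValidationError,
    annotate_peaks,
    consensus,
    intersect_assays,
    signal_fold_change_correlation,
)
from pausekit.peaks import FEATURE_DISTAL, FEATURE_EXON, FEATURE_INTRON, FEATURE_PROMOTER


def pk(start, end, fdr=0.01, chrom="c", score=0.0):
    return Peak(GenomicInterval(chrom, start, end), score, fdr)


# ---------------------------------------------------------------------------
# per-base occupancy oracle
# ---------------------------------------------------------------------------

def consensus_oracle(peak_sets, min_sets, fdr_max, length):
    """Covered-base reference: occupancy >= min_sets forms supported cores;
    every passing peak touching a core contributes its bases; consensus
    regions are the maximal runs of contributed bases."""
    occ = np.zeros(length, dtype=int)
    passing = [[p for p in ps if p.fdr <= fdr_max] for ps in peak_sets]
    for ps in passing:
        cov = np.zeros(length, dtype=bool)
        for p in ps:
            cov[p.interval.start:p.interval.end] = True
        occ += cov
    core = occ >= min_sets
    covered = core.copy()
    for ps in passing:
        for p in ps:
            if core[p.interval.start:p.interval.end].any():
                covered[p.interval.start:p.interval.end] = True
    return _runs_of(covered)


def _runs_of(mask):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


class TestConsensus:
    def test_identical_sets_idempotent(self):
        s = [pk(100, 200), pk(400, 500)]
        cps = consensus([s, s], min_sets=2)
        assert [(p.interval.start, p.interval.end) for p in cps.peaks] == [
            (100, 200), (400, 500)
        ]

    def test_disjoint_sets_empty(self):
        cps = consensus([[pk(0, 100)], [pk(500, 600)]], min_sets=2)
        assert len(cps) == 0

    def test_union_extent_of_linked_pair(self):
        cps = consensus([[pk(100, 200)], [pk(150, 250)]], min_sets=2)
        assert [(p.interval.start, p.interval.end) for p in cps.peaks] == [(100, 250)]

    def test_fdr_filter_applies_before_overlap(self):
        cps = consensus([[pk(100, 200, fdr=0.5)], [pk(150, 250)]], min_sets=2)
        assert len(cps) == 0

    def test_consensus_of_consensus_is_identity(self):
        sets = [
            [pk(0, 50), pk(100, 300)],
            [pk(20, 70), pk(250, 400)],
        ]
        once = consensus(sets, min_sets=2)
        again = consensus([once.peaks], min_sets=1)
        assert [(p.interval.start, p.interval.end) for p in again.peaks] == [
            (p.interval.start, p.interval.end) for p in once.peaks
        ]

    def test_min_fdr_inherited(self):
        cps = consensus([[pk(0, 100, fdr=0.04)], [pk(50, 150, fdr=0.002)]], min_sets=2)
        assert cps.peaks[0].fdr == 0.002

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n_sets = int(rng.integers(1, 5))
            length = int(rng.integers(200, 2000))
            sets = []
            for _ in range(n_sets):
                n = int(rng.integers(0, 15))
                starts = rng.integers(0, length - 20, size=n)
                peaks = [
                    pk(int(s), int(s + rng.integers(5, 100)),
                       fdr=float(rng.uniform(0, 0.2)))
                    for s in starts
                ]
                sets.append(peaks)
            min_sets = int(rng.integers(1, n_sets + 1))
            got = consensus(sets, min_sets=min_sets, fdr_max=0.05)
            expected = consensus_oracle(sets, min_sets, 0.05, length + 200)
            assert [
                (p.interval.start, p.interval.end) for p in got.peaks
            ] == expected


class TestIntersect:
    def _cps(self, *peaks):
        return ConsensusPeakSet(list(peaks))

    def test_self_intersection_identity(self):
        a = self._cps(pk(0, 100), pk(300, 400))
        out = intersect_assays(a, a)
        assert [(p.interval.start, p.interval.end) for p in out.peaks] == [
            (0, 100), (300, 400)
        ]

    def test_empty_intersection(self):
        a = self._cps(pk(0, 100))
        assert len(intersect_assays(a, self._cps())) == 0

    def test_strict_vs_union_extent(self):
        a, b = self._cps(pk(0, 100)), self._cps(pk(50, 150))
        strict = intersect_assays(a, b, extent="strict")
        union = intersect_assays(a, b, extent="union")
        assert [(p.interval.start, p.interval.end) for p in strict.peaks] == [(50, 100)]
        assert [(p.interval.start, p.interval.end) for p in union.peaks] == [(0, 150)]

    def test_strict_matches_per_base_and_commutes(self, rng):
        for _ in range(50):
            length = 800

            def random_merged():
                n = int(rng.integers(1, 10))
                lens = rng.integers(5, 60, size=n)
                gaps = rng.integers(1, 60, size=n)
                starts = np.cumsum(gaps) + np.concatenate(
                    ([0], np.cumsum(lens)[:-1])
                )
                return ConsensusPeakSet(
                    [pk(int(s), int(s + l)) for s, l in zip(starts, lens)]
                )

            a, b = random_merged(), random_merged()
            got = intersect_assays(a, b, extent="strict")
            cov_a = np.zeros(length * 3, dtype=bool)
            cov_b = np.zeros(length * 3, dtype=bool)
            for p in a.peaks:
                cov_a[p.interval.start:p.interval.end] = True
            for p in b.peaks:
                cov_b[p.interval.start:p.interval.end] = True
            expected = _runs_of(cov_a & cov_b)
            assert [
                (p.interval.start, p.interval.end) for p in got.peaks
            ] == expected
            swapped = intersect_assays(b, a, extent="strict")
            assert [(p.interval.start, p.interval.end) for p in swapped.peaks] == expected


class TestAnnotation:
    @pytest.fixture
    def toy_genes(self):
        # gene A spans 10k-20k (+) with exon structure; gene B at 30k (+);
        # gene C on minus strand ending at 50k
        return [
            GeneModel(
                "A",
                GenomicInterval("c", 10_000, 20_000, "+"),
                (
                    GenomicInterval("c", 10_000, 11_000, "+"),
                    GenomicInterval("c", 19_000, 20_000, "+"),
                ),
            ),
            GeneModel("B", GenomicInterval("c", 30_000, 36_000, "+")),
            GeneModel("C", GenomicInterval("c", 44_000, 50_000, "-")),
        ]

    def _annotate(self, peaks, genes, window=2000):
        return annotate_peaks(ConsensusPeakSet(peaks), genes, promoter_window=window)

    def test_peak_on_tss_is_promoter_distance_zero(self, toy_genes):
        (a,) = self._annotate([pk(29_950, 30_050)], toy_genes)
        assert a.feature_class == FEATURE_PROMOTER
        assert a.nearest_gene_id == "B"
        assert a.distance_to_tss == 0

    def test_far_peak_is_distal(self, toy_genes):
        (a,) = self._annotate([pk(130_000, 130_200)], toy_genes)
        assert a.feature_class == FEATURE_DISTAL

    def test_promoter_precedence_over_intron(self, toy_genes):
        # overlaps intron of A (after its 5' exon) and, with a wide window,
        # nothing else: intron; narrow the case onto B's promoter window
        (intron,) = self._annotate([pk(15_000, 15_100)], toy_genes)
        assert intron.feature_class == FEATURE_INTRON
        (prom,) = self._annotate([pk(19_500, 31_000)], toy_genes)
        assert prom.feature_class == FEATURE_PROMOTER

    def test_exon_beats_intron(self, toy_genes):
        (a,) = self._annotate([pk(14_000, 19_500)], toy_genes, window=100)
        assert a.feature_class == FEATURE_EXON

    def test_minus_strand_distance_sign(self, toy_genes):
        # peak just inside gene C (downstream of its TSS at 50k)
        (a,) = self._annotate([pk(49_000, 49_200)], toy_genes)
        assert a.nearest_gene_id == "C"
        assert a.distance_to_tss > 0

    def test_classes_partition_peaks(self, toy_genes, rng):
        peaks = [
            pk(int(s), int(s) + 150)
            for s in sorted(rng.choice(60_000, size=30, replace=False))
            if True
        ]
        merged = ConsensusPeakSet(
            consensus([peaks], min_sets=1, fdr_max=1.0).peaks
        )
        annos = annotate_peaks(merged, toy_genes)
        assert len(annos) == len(merged)
        classes = {a.feature_class for a in annos}
        assert classes <= {
            FEATURE_PROMOTER, FEATURE_EXON, FEATURE_INTRON, FEATURE_DISTAL
        }


def _spearman_oracle(x, y):
    """Rank both vectors (average ranks on ties) and Pearson-correlate."""
    def rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1
            i = j + 1
        return ranks
    rx, ry = rank(x), rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestFoldChangeCorrelation:
    def _tracks_from_densities(self, peaks, dens):
        recs = [
            ("c", p.interval.start, p.interval.end, float(d))
            for p, d in zip(peaks, dens)
        ]
        return CoverageTrack.from_records(recs)

    def test_identical_assays_correlate_perfectly(self, rng):
        peaks = [pk(i * 1000, i * 1000 + 200) for i in range(10)]
        cps = ConsensusPeakSet(peaks)
        ctrl = self._tracks_from_densities(peaks, rng.uniform(1, 10, 10))
        treat = self._tracks_from_densities(peaks, rng.uniform(1, 10, 10))
        rho = signal_fold_change_correlation(cps, (ctrl, treat), (ctrl, treat))
        assert rho == pytest.approx(1.0)

    def test_negated_fold_changes_anticorrelate(self):
        peaks = [pk(i * 1000, i * 1000 + 100) for i in range(8)]
        cps = ConsensusPeakSet(peaks)
        base = np.full(8, 4.0)
        up = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        a = (
            self._tracks_from_densities(peaks, base),
            self._tracks_from_densities(peaks, base * up),
        )
        b = (
            self._tracks_from_densities(peaks, base * up),
            self._tracks_from_densities(peaks, base),
        )
        rho = signal_fold_change_correlation(cps, a, b, pseudocount=1e-9)
        assert rho == pytest.approx(-1.0)

    def test_matches_hand_rank_oracle(self, rng):
        peaks = [pk(i * 500, i * 500 + 100) for i in range(10)]
        cps = ConsensusPeakSet(peaks)
        ctrl_a = rng.uniform(1, 10, 10)
        treat_a = rng.uniform(1, 10, 10)
        ctrl_b = rng.uniform(1, 10, 10)
        treat_b = rng.uniform(1, 10, 10)
        pc = 0.1
        tracks = lambda d: self._tracks_from_densities(peaks, d)
        rho = signal_fold_change_correlation(
            cps, (tracks(ctrl_a), tracks(treat_a)),
            (tracks(ctrl_b), tracks(treat_b)), pseudocount=pc,
        )

        def fc(ctrl, treat):
            tc = sum(c * 100 for c in ctrl)
            tt = sum(t * 100 for t in treat)
            dc = ctrl * 1e6 / tc
            dt = treat * 1e6 / tt
            return np.log2((dt + pc) / (dc + pc))

        expected = _spearman_oracle(fc(ctrl_a, treat_a), fc(ctrl_b, treat_b))
        assert rho == pytest.approx(expected)

    def test_too_few_peaks_rejected(self):
        peaks = [pk(0, 100), pk(500, 600)]
        cps = ConsensusPeakSet(peaks)
        t = self._tracks_from_densities(peaks, [1.0, 2.0])
        with pytest.raises(ValidationError):
            signal_fold_change_correlation(cps, (t, t), (t, t))
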