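"""DamID scoring and LAD calling: trimming/splitting rules, the straddle
counting oracle, pseudocount arithmetic, segmentation against an exhaustive
single-split search, and the LAD merge/length rules."""

import numpy as np
import pytest

from ladkit.damid import (
    AlignedRead,
    BinCounts,
    Segment,
    SegmentSet,
    SequencingRead,
    call_lads,
    compute_damid_scores,
    count_reads_per_fragment,
    segment_scores,
    split_on_adaptor,
    trim_read_5prime,
)
from ladkit.gatc import GatcFragmentMap

from .conftest import make_track


def read_of(quals, bases=None):
    quals = tuple(quals)
    return SequencingRead("r", bases or "A" * len(quals), quals)


class TestTrimming:
    @pytest.mark.parametrize(
        "quals,expected_len",
        [
            ([10, 10, 10, 35, 35, 35], 3),   # trimmed to the passing window
            ([40, 40, 40, 40], 4),           # first window already passes
            ([10, 10, 10, 10], 0),           # no passing window -> empty
        ],
    )
    def test_rule_examples(self, quals, expected_len):
        assert len(trim_read_5prime(read_of(quals))) == expected_len

    def test_short_read_kept_iff_mean_passes(self):
        assert len(trim_read_5prime(read_of([35, 35]))) == 2
        assert len(trim_read_5prime(read_of([10, 20]))) == 0

    def test_trim_keeps_matching_bases(self):
        r = SequencingRead("r", "ACGTAC", (10, 10, 10, 35, 35, 35))
        out = trim_read_5prime(r)
        assert out.bases == "TAC" and out.quals == (35, 35, 35)


class TestAdaptorSplit:
    ADAPTOR = "GGTCGCGGCCGAG"

    def _read(self, *parts):
        bases = self.ADAPTOR.join(parts)
        return SequencingRead("r", bases, tuple([40] * len(bases)))

    def test_short_piece_discarded(self):
        out = split_on_adaptor(self._read("A" * 25, "C" * 10), self.ADAPTOR)
        assert [p.bases for p in out] == ["A" * 25]

    def test_no_adaptor_identity(self):
        r = self._read("A" * 30)
        out = split_on_adaptor(r, self.ADAPTOR)
        assert len(out) == 1 and out[0].bases == r.bases

    def test_both_pieces_kept(self):
        out = split_on_adaptor(self._read("A" * 22, "C" * 22), self.ADAPTOR)
        assert [len(p) for p in out] == [22, 22]
        assert self.ADAPTOR not in "".join(p.bases for p in out)

    def test_boundary_length_20_discarded(self):
        out = split_on_adaptor(self._read("A" * 20, "C" * 21), self.ADAPTOR)
        assert [len(p) for p in out] == [21]  # "greater than 20 bp" only


class TestCounting:
    def test_straddling_read_counts_toward_both(self, toy_fragment_map):
        bc = count_reads_per_fragment([AlignedRead("chrT", 2, 6)], toy_fragment_map)
        assert bc.counts.tolist() == [1, 1, 0]

    def test_contained_read_counts_once(self, toy_fragment_map):
        bc = count_reads_per_fragment([AlignedRead("chrT", 4, 8)], toy_fragment_map)
        assert bc.counts.tolist() == [0, 1, 0]

    def test_out_of_bounds_read_raises(self, toy_fragment_map):
        with pytest.raises(ValueError, match=r"\[10, 20\)"):
            count_reads_per_fragment([AlignedRead("chrT", 10, 20)], toy_fragment_map)

    def test_random_reads_match_bruteforce(self, rng):
        bounds = np.unique(rng.integers(1, 400, size=20))
        bounds = np.concatenate([[0], bounds, [400]])
        frags = np.column_stack([bounds[:-1], bounds[1:]])
        fm = GatcFragmentMap("chrT", 400, bounds[1:-1], frags)
        reads = []
        for _ in range(100):
            s = int(rng.integers(0, 399))
            e = int(rng.integers(s + 1, 401))
            reads.append(AlignedRead("chrT", s, e))
        bc = count_reads_per_fragment(reads, fm)
        brute = np.zeros(fm.n_fragments, dtype=int)
        for r in reads:
            for i, (fs, fe) in enumerate(frags):
                if min(r.end, fe) - max(r.start, fs) >= 1:
                    brute[i] += 1
        assert bc.counts.tolist() == brute.tolist()
        assert bc.library_size == 100


class TestScoring:
    def _counts(self, fm, fusion, control):
        return (
            BinCounts(fm, np.asarray(fusion), int(np.sum(fusion))),
            BinCounts(fm, np.asarray(control), int(np.sum(control))),
        )

    def test_pseudocount_and_symmetry(self, toy_fragment_map):
        f, c = self._counts(toy_fragment_map, [0, 4, 0], [2, 4, 0])
        track = compute_damid_scores(f, c, normalize=False)
        assert track.scores[0] == pytest.approx(np.log2(0.5 / 2))  # -2.0
        assert track.scores[1] == pytest.approx(0.0)
        assert track.missing[2] and np.isnan(track.scores[2])

    def test_scored_plus_missing_conserved(self, toy_fragment_map):
        f, c = self._counts(toy_fragment_map, [0, 4, 0], [2, 4, 0])
        track = compute_damid_scores(f, c, normalize=False)
        assert track.n_scored + int(track.missing.sum()) == toy_fragment_map.n_fragments

    def test_rpm_normalization_shifts_scores(self, toy_fragment_map):
        f, c = self._counts(toy_fragment_map, [8, 8, 8], [4, 4, 4])
        raw = compute_damid_scores(f, c, normalize=False)
        norm = compute_damid_scores(f, c, normalize=True)
        assert np.allclose(raw.scores, 1.0)
        # equal library proportions per bin -> RPM ratio is 1 everywhere
        assert np.allclose(norm.scores, 0.0)

    def test_mask_excludes_fragments(self, toy_fragment_map):
        f, c = self._counts(toy_fragment_map, [4, 4, 4], [4, 4, 4])
        track = compute_damid_scores(f, c, mask=[(0, 5)])
        assert track.missing.tolist() == [True, True, False]

    def test_mismatched_maps_and_empty_library_raise(self, toy_fragment_map):
        f, c = self._counts(toy_fragment_map, [1, 1, 1], [1, 1, 1])
        other = GatcFragmentMap("chrT", 14, np.array([7]), np.array([[0, 7], [7, 14]]))
        with pytest.raises(ValueError, match="share one fragment map"):
            compute_damid_scores(f, BinCounts(other, np.array([1, 1]), 2))
        with pytest.raises(ValueError, match="library"):
            compute_damid_scores(f, BinCounts(toy_fragment_map, np.zeros(3, int), 0))


def exhaustive_single_split(values):
    """Independent oracle: minimise two-segment SSE over all split points."""
    best, best_sse = None, np.inf
    for i in range(1, len(values)):
        l, r = values[:i], values[i:]
        sse = ((l - l.mean()) ** 2).sum() + ((r - r.mean()) ** 2).sum()
        if sse < best_sse:
            best, best_sse = i, sse
    return best


class TestSegmentation:
    def test_noiseless_step_exact_changepoint(self):
        values = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        track = make_track(values)
        segs = segment_scores(track, seed=0)
        assert [(s.start_fragment, s.end_fragment) for s in segs.segments] == [(0, 50), (50, 100)]
        assert exhaustive_single_split(values) == 50

    def test_constant_track_single_segment(self):
        segs = segment_scores(make_track(np.zeros(100)), seed=0)
        assert len(segs.segments) == 1

    def test_noisy_step_within_one_fragment_of_oracle(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        values += rng.normal(0, 0.3, size=100)
        segs = segment_scores(make_track(values), seed=7)
        cps = [s.start_fragment for s in segs.segments[1:]]
        oracle = exhaustive_single_split(values)
        assert any(abs(c - oracle) <= 1 for c in cps)
        assert abs(oracle - 50) <= 1  # oracle itself found the planted step

    def test_missing_fragments_inherit_segment(self):
        values = np.concatenate([np.full(40, -1.0), [np.nan] * 5, np.full(40, 1.0)])
        segs = segment_scores(make_track(values), seed=0)
        assert segs.segments[0].start_fragment == 0
        assert segs.segments[-1].end_fragment == 85
        # the partition tiles all fragments including the missing run
        spans = [(s.start_fragment, s.end_fragment) for s in segs.segments]
        assert spans[0][1] == spans[1][0]

    def test_segment_means_match_member_scores(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(-1, 0.1, 30), rng.normal(2, 0.1, 30)])
        track = make_track(values)
        segs = segment_scores(track, seed=0)
        for s in segs.segments:
            member = values[s.start_fragment:s.end_fragment]
            member = member[np.isfinite(member)]
            assert s.mean == pytest.approx(member.mean())

    def test_all_missing_warns_empty(self):
        with pytest.warns(UserWarning, match="all fragments missing"):
            segs = segment_scores(make_track([np.nan, np.nan]), seed=0)
        assert segs.segments == []

    def test_determinism(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0, 1, 200)
        values[60:140] += 1.5
        a = segment_scores(make_track(values), seed=5)
        b = segment_scores(make_track(values), seed=5)
        assert [(s.start_fragment, s.end_fragment, s.mean) for s in a.segments] == [
            (s.start_fragment, s.end_fragment, s.mean) for s in b.segments
        ]


def uniform_map(n_frag, frag_len=1000, chrom="chrT"):
    bounds = np.arange(n_frag + 1) * frag_len
    return GatcFragmentMap(chrom, int(n_frag * frag_len),
                           bounds[1:-1], np.column_stack([bounds[:-1], bounds[1:]]))


def seg_set(fm, spans_and_means):
    """spans in bp over a uniform 1 kb fragment map."""
    segs = [Segment(s // 1000, e // 1000, m) for s, e, m in spans_and_means]
    return SegmentSet(chrom=fm.chrom, segments=segs)


class TestCallLads:
    def test_small_gap_merged(self):
        fm = uniform_map(150)
        segs = seg_set(fm, [(0, 60_000, 1.0), (60_000, 68_000, -0.5),
                            (68_000, 150_000, 0.8)])
        lads = call_lads(segs, fm)
        assert lads.intervals["chrT"].tolist() == [[0, 150_000]]

    def test_large_gap_splits_and_fails_length(self):
        fm = uniform_map(150)
        segs = seg_set(fm, [(0, 60_000, 1.0), (60_000, 72_000, -0.5),
                            (72_000, 150_000, 0.8)])
        lads = call_lads(segs, fm)
        assert lads.n_lads() == 0  # 60 kb and 78 kb both < 100 kb

    def test_single_positive_segment_passes_length(self):
        fm = uniform_map(150)
        segs = seg_set(fm, [(0, 120_000, 0.9), (120_000, 150_000, -1.0)])
        lads = call_lads(segs, fm)
        assert lads.intervals["chrT"].tolist() == [[0, 120_000]]

    def test_zero_mean_segment_not_positive(self):
        fm = uniform_map(150)
        segs = seg_set(fm, [(0, 120_000, 0.0), (120_000, 150_000, -1.0)])
        assert call_lads(segs, fm).n_lads() == 0

    def test_boundaries_never_inside_gap(self):
        fm = uniform_map(200)
        segs = seg_set(fm, [(0, 110_000, 1.0), (110_000, 118_000, -0.5),
                            (118_000, 130_000, 0.7), (130_000, 200_000, -1.0)])
        lads = call_lads(segs, fm)
        # ends at the outermost positive edge, not inside the negative gap
        assert lads.intervals["chrT"].tolist() == [[0, 130_000]]

    def test_unsegmented_chromosome_yields_no_lads(self):
        fm = uniform_map(150)
        segs = seg_set(fm, [(0, 150_000, 0.01)])
        assert call_lads(segs, fm).n_lads() == 0

    def test_empty_input(self):
        fm = uniform_map(10)
        assert call_lads(SegmentSet(chrom="chrT"), fm).n_lads() == 0

    def test_monotone_in_min_lad_and_max_gap(self):
        fm = uniform_map(400)
        spans = [(0, 110_000, 1.0), (110_000, 118_000, -0.5),
                 (118_000, 250_000, 0.6), (250_000, 290_000, -1.0),
                 (290_000, 395_000, 0.4), (395_000, 400_000, -0.2)]
        segs = seg_set(fm, spans)
        cov = [call_lads(segs, fm, min_lad=m).total_coverage()
               for m in (50_000, 100_000, 150_000, 300_000)]
        assert cov == sorted(cov, reverse=True)
        cov_gap = [call_lads(segs, fm, max_gap=g).total_coverage()
                   for g in (1_000, 10_000, 50_000)]
        assert cov_gap == sorted(cov_gap)
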