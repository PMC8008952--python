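"""DamID-seq scoring and LAD calling.

Pipeline implemented here, in run order:

1. read preprocessing — 5′ sliding-window quality trimming and splitting on
   internal DamID adaptor-primer occurrences (provided for completeness; the
   standard entry point is aligned reads as BED intervals);
2. per-fragment read counting, with reads straddling a fragment boundary
   counted toward every fragment they overlap;
3. pseudocounted log2(Dam-fusion / Dam-only) scores per GATC fragment, with
   optional reads-per-million library normalisation and an optional
   mappability mask;
4. changepoint partitioning of each chromosome's score track by recursive
   binary segmentation with permutation-based split acceptance (the CBS
   procedure);
5. LAD classification: positive-mean segments, merged across negative gaps
   shorter than ``max_gap`` (default 10 kb) and retained when the merged
   region is at least ``min_lad`` (default 100 kb).

Scores are dimensionless log2 ratios. Fragments with zero reads in both
samples, or overlapping the mask, are *missing*, never silently 0: only
non-zero bins carry a defined ratio. A zero count in exactly one sample
receives the 0.5 pseudocount before the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np

from .gatc import GatcFragmentMap

__all__ = [
    "SequencingRead",
    "AlignedRead",
    "BinCounts",
    "DamidScoreTrack",
    "Segment",
    "SegmentSet",
    "LadSet",
    "trim_read_5prime",
    "split_on_adaptor",
    "count_reads_per_fragment",
    "compute_damid_scores",
    "segment_scores",
    "call_lads",
    "read_aligned_bed",
    "write_bedgraph",
    "read_bedgraph_track",
    "write_lads_bed",
    "write_segments_bed",
]

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_LAD = 100_000      # bp; ">100 kb in size of positive signals"
DEFAULT_MAX_GAP = 10_000       # bp; negative gaps "<10 kb" are absorbed
DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 10_000


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequencingRead:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: |bases| != |quals|")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)


def trim_read_5prime(read: SequencingRead, window: int = 3, cutoff: float = 30) -> SequencingRead:
    """Trim the 5′ end until a ``window``-base mean quality reaches ``cutoff``.

    Removes the smallest prefix such that the first ``window`` bases of the
    remainder average at least ``cutoff``. If no position qualifies the read
    is emptied. A read shorter than ``window`` is kept as-is when its
    full-length mean passes, else emptied.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(read.quals, dtype=float)
    n = len(q)
    if n < window:
        if n and q.mean() >= cutoff:
            return read
        return SequencingRead(read.id, "", ())
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    passing = np.nonzero(means >= cutoff)[0]
    if passing.size == 0:
        return SequencingRead(read.id, "", ())
    i = int(passing[0])
    return SequencingRead(read.id, read.bases[i:], read.quals[i:])


def split_on_adaptor(
    read: SequencingRead, adaptor: str, min_len: int = 21
) -> list[SequencingRead]:
    """Split a read at every exact adaptor occurrence, dropping the adaptor.

    Pieces shorter than ``min_len`` (default keeps only reads > 20 bp) are
    discarded. A read without the adaptor is returned as a singleton if long
    enough.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    pieces: list[SequencingRead] = []
    bases, quals = read.bases.upper(), read.quals
    adaptor = adaptor.upper()
    start = 0
    part = 0
    while True:
        i = bases.find(adaptor, start)
        end = i if i >= 0 else len(bases)
        if end - start >= min_len:
            pieces.append(
                SequencingRead(f"{read.id}/{part}" if (i >= 0 or part) else read.id,
                               read.bases[start:end], quals[start:end])
            )
            part += 1
        if i < 0:
            break
        start = i + len(adaptor)
    return pieces


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    start: int
    end: int
    sample: str = "fusion"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid read interval [{self.start}, {self.end})")


@dataclass
class BinCounts:
    """Per-fragment read counts for one sample on one chromosome.

    ``library_size`` is the number of input reads; because straddling reads
    increment every overlapped fragment, column sums may exceed it.
    """

    fragment_map: GatcFragmentMap
    counts: np.ndarray
    library_size: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.fragment_map.n_fragments,):
            raise ValueError("counts must have one entry per fragment")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def count_reads_per_fragment(
    reads: list[AlignedRead], frags: GatcFragmentMap
) -> BinCounts:
    """Assign reads to DpnI fragments; straddling reads count toward both.

    Every fragment a read overlaps by >= 1 bp is incremented.
    """
    counts = np.zeros(frags.n_fragments, dtype=np.int64)
    bounds = frags.boundaries
    for r in reads:
        if r.chrom != frags.chrom:
            raise ValueError(f"read on {r.chrom} not on fragment map chromosome {frags.chrom}")
        if r.start < 0 or r.end > frags.chrom_length:
            raise ValueError(
                f"read [{r.start}, {r.end}) outside chromosome {r.chrom} "
                f"bounds [0, {frags.chrom_length})"
            )
        first = int(np.searchsorted(bounds, r.start, side="right")) - 1
        last = int(np.searchsorted(bounds, r.end - 1, side="right")) - 1
        counts[first : last + 1] += 1
    return BinCounts(fragment_map=frags, counts=counts, library_size=len(reads))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class DamidScoreTrack:
    """Per-fragment log2(fusion/control) with a missing mask.

    ``scores`` is float with NaN at missing fragments (both-zero or masked);
    ``missing`` is the boolean mask of those fragments.
    """

    fragment_map: GatcFragmentMap
    scores: np.ndarray
    missing: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = self.fragment_map.n_fragments
        if self.scores.shape != (n,) or self.missing.shape != (n,):
            raise ValueError("scores/missing must have one entry per fragment")
        if np.any(~np.isfinite(self.scores[~self.missing])):
            raise ValueError("scores must be finite wherever defined")

    @property
    def n_scored(self) -> int:
        return int((~self.missing).sum())


def _mask_to_fragment_bool(frags: GatcFragmentMap, mask_intervals) -> np.ndarray:
    """Boolean per-fragment flag: overlaps any mask interval by >= 1 bp."""
    out = np.zeros(frags.n_fragments, dtype=bool)
    if mask_intervals is None:
        return out
    starts, ends = frags.fragments[:, 0], frags.fragments[:, 1]
    for ms, me in mask_intervals:
        out |= (starts < me) & (ends > ms)
    return out


def compute_damid_scores(
    fusion: BinCounts,
    control: BinCounts,
    normalize: bool = True,
    mask=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DamidScoreTrack:
    """log2 ratio of Dam-fusion over Dam-only per GATC fragment.

    Fragments with zero reads in both samples are missing; a zero in exactly
    one sample takes the pseudocount (0.5) before the ratio. With
    ``normalize`` on (default), counts are first scaled to reads-per-million
    by library size; the pseudocount then substitutes on the raw-zero side
    after scaling, keeping its floor role independent of depth. ``mask`` is
    an optional iterable of (start, end) intervals whose overlapped
    fragments are removed before analysis.
    """
    if fusion.fragment_map is not control.fragment_map and not (
        fusion.fragment_map.chrom == control.fragment_map.chrom
        and np.array_equal(fusion.fragment_map.fragments, control.fragment_map.fragments)
    ):
        raise ValueError("fusion and control must share one fragment map")
    if fusion.library_size <= 0 or control.library_size <= 0:
        raise ValueError("zero library size")

    frags = fusion.fragment_map
    f_raw = fusion.counts.astype(float)
    c_raw = control.counts.astype(float)
    missing = (fusion.counts == 0) & (control.counts == 0)
    missing |= _mask_to_fragment_bool(frags, mask)

    if normalize:
        f = f_raw * 1e6 / fusion.library_size
        c = c_raw * 1e6 / control.library_size
    else:
        f, c = f_raw.copy(), c_raw.copy()
    f[f_raw == 0] = pseudocount
    c[c_raw == 0] = pseudocount

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log2(f / c)
    scores[missing] = np.nan
    return DamidScoreTrack(fragment_map=frags, scores=scores, missing=missing,
                           pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Segmentation (CBS-style recursive binary changepoint partition)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """Half-open fragment-index range with the mean of its member scores."""

    start_fragment: int
    end_fragment: int
    mean: float


@dataclass
class SegmentSet:
    chrom: str
    segments: list[Segment] = field(default_factory=list)


def _max_split_stat(values: np.ndarray) -> tuple[int, float]:
    """Best single split of ``values`` by the mean-difference t-like statistic.

    Returns (split index i in [1, n-1], statistic). The statistic is
    |mean_left - mean_right| / sqrt(1/n_l + 1/n_r); the common variance term
    is permutation-invariant and cancels from the permutation test, so it is
    omitted. Ties break leftmost.
    """
    n = values.size
    cs = np.cumsum(values)
    i = np.arange(1, n)
    mean_l = cs[:-1] / i
    mean_r = (cs[-1] - cs[:-1]) / (n - i)
    stat = np.abs(mean_l - mean_r) / np.sqrt(1.0 / i + 1.0 / (n - i))
    best = int(np.argmax(stat))
    return best + 1, float(stat[best])


@numba.njit(cache=False)
def _perm_exceed_count(
    values: np.ndarray,
    weights: np.ndarray,
    observed: float,
    n_perm: int,
    reject_at: int,
    seed: int,
) -> int:
    """Count permutations whose max split statistic reaches ``observed``.

    Fisher–Yates shuffle and a single left-to-right scan per permutation;
    returns early once ``reject_at`` exceedances make p >= alpha certain.
    The statistic |mean_l - mean_r| / sqrt(1/n_l + 1/n_r) is computed as
    |cumsum_i - i*T/n| * sqrt(n / (i (n-i))) with the weights precomputed.
    """
    n = values.size
    v = values.copy()
    total = v.sum()
    coeff = total / n
    exceed = 0
    # xorshift64* stream for the shuffles; Lemire multiply-shift for the
    # bounded draw (bias < 2**-32, immaterial for a permutation test)
    state = np.uint64(seed * 2654435761 + 1)
    for _p in range(n_perm):
        for j in range(n - 1, 0, -1):
            state ^= state >> np.uint64(12)
            state ^= state << np.uint64(25)
            state ^= state >> np.uint64(27)
            r = (state * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(32)
            k = (r * np.uint64(j + 1)) >> np.uint64(32)
            tmp = v[j]
            v[j] = v[k]
            v[k] = tmp
        cs = 0.0
        mx = 0.0
        for idx in range(n - 1):
            cs += v[idx]
            s = abs(cs - (idx + 1) * coeff) * weights[idx]
            if s > mx:
                mx = s
        if mx >= observed:
            exceed += 1
            if exceed >= reject_at:
                return exceed
    return exceed


def _perm_test_split(
    values: np.ndarray,
    observed: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation acceptance of the best split: p-value < alpha?

    Permutes values within the segment and recomputes the max split
    statistic; p = (1 + #exceedances) / (1 + n_perm). Stops early once the
    exceedance count guarantees p >= alpha.
    """
    n = values.size
    i = np.arange(1, n, dtype=np.float64)
    weights = np.sqrt(n / (i * (n - i)))
    # smallest exceedance count that already implies p >= alpha
    reject_at = int(np.ceil(alpha * (1 + n_perm) - 1 - 1e-12))
    seed = int(rng.integers(0, 2**31 - 1))
    exceed = _perm_exceed_count(
        np.ascontiguousarray(values, dtype=np.float64), weights,
        observed, n_perm, reject_at, seed,
    )
    return (1 + exceed) / (1 + n_perm) < alpha


def _segment_recursive(
    values: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    out: list[tuple[int, int]],
) -> None:
    n = values.size
    if n < 2:
        out.append((offset, offset + n))
        return
    split, stat = _max_split_stat(values)
    if stat > 0 and _perm_test_split(values, stat, alpha, n_perm, rng):
        _segment_recursive(values[:split], offset, alpha, n_perm, rng, out)
        _segment_recursive(values[split:], offset + split, alpha, n_perm, rng, out)
    else:
        out.append((offset, offset + n))


def _refine_boundaries(values: np.ndarray, bounds: list[int], max_iter: int = 10) -> list[int]:
    """Locally re-estimate each interior changepoint, segment count fixed.

    Greedy recursion can misplace a boundary by a few bins when noise makes
    the local shift ambiguous at the node where the split was accepted. With
    the partition fixed, each boundary is moved to the position maximising
    the split statistic (equivalently, minimising the two-segment SSE)
    within its two flanking segments, iterated to a fixpoint.
    """
    bounds = list(bounds)
    for _ in range(max_iter):
        moved = False
        for j in range(1, len(bounds) - 1):
            lo, hi = bounds[j - 1], bounds[j + 1]
            if hi - lo < 2:
                continue
            split, _stat = _max_split_stat(values[lo:hi])
            new = lo + split
            if new != bounds[j]:
                bounds[j] = new
                moved = True
        if not moved:
            break
    return bounds


def segment_scores(
    track: DamidScoreTrack,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> SegmentSet:
    """Partition the score track into constant-mean segments.

    Recursive binary segmentation: at each step the split maximising the
    two-sample t-like statistic is accepted iff its permutation p-value is
    below ``alpha`` (``n_perm`` permutations, seeded); accepted changepoint
    locations are then refined by a local SSE re-fit with the segment count
    fixed. Missing fragments are skipped in the statistics but inherit the
    enclosing segment, so the output segments tile all fragments of the
    chromosome.
    """
    scored_idx = np.nonzero(~track.missing)[0]
    chrom = track.fragment_map.chrom
    if scored_idx.size == 0:
        warnings.warn(f"{chrom}: all fragments missing; empty segment set")
        return SegmentSet(chrom=chrom, segments=[])
    values = track.scores[scored_idx]
    rng = np.random.default_rng(seed)
    ranges: list[tuple[int, int]] = []
    _segment_recursive(values, 0, alpha, n_perm, rng, ranges)
    if len(ranges) > 1:
        bounds = [0] + [b for _a, b in ranges[:-1]] + [values.size]
        bounds = _refine_boundaries(values, bounds)
        ranges = list(zip(bounds[:-1], bounds[1:]))

    # map scored-index ranges back to fragment-index ranges tiling all
    # fragments: each boundary between segments sits just before the first
    # scored fragment of the right segment; leading/trailing missing
    # fragments attach to the first/last segment.
    n_frag = track.fragment_map.n_fragments
    segments: list[Segment] = []
    for k, (a, b) in enumerate(ranges):
        start = 0 if k == 0 else int(scored_idx[a])
        end = n_frag if k == len(ranges) - 1 else int(scored_idx[b])
        segments.append(Segment(start, end, float(values[a:b].mean())))
    return SegmentSet(chrom=chrom, segments=segments)


# ---------------------------------------------------------------------------
# LAD classification
# ---------------------------------------------------------------------------

@dataclass
class LadSet:
    """Sorted, disjoint LAD intervals per chromosome (bp, half-open)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def total_coverage(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def n_lads(self) -> int:
        return int(sum(len(iv) for iv in self.intervals.values()))


def call_lads(
    segments: SegmentSet,
    frags: GatcFragmentMap,
    min_lad: int = DEFAULT_MIN_LAD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> LadSet:
    """Classify LADs from a segment partition.

    Positive segments (mean > 0 strictly) are mapped to genomic intervals at
    their fragment edges; consecutive positive intervals separated by
    negative spans shorter than ``max_gap`` are merged across the gap; merged
    regions of genomic length >= ``min_lad`` are emitted. LAD boundaries
    always lie at outermost positive-segment edges, never inside a gap.

    A chromosome partitioned into a single segment yields no LADs: DamID
    log-ratios are relative, so a track with no significant changepoints
    carries no evidence of domain structure (see the methods note).
    """
    out = LadSet()
    segs = segments.segments
    if not segs or len(segs) < 2:
        return out
    bounds = frags.boundaries
    positives = [
        (int(bounds[s.start_fragment]), int(bounds[s.end_fragment]))
        for s in segs
        if s.mean > 0
    ]
    if not positives:
        return out
    # one left-to-right pass suffices: merging across < max_gap gaps is
    # associative on sorted disjoint intervals
    merged: list[list[int]] = [list(positives[0])]
    for s, e in positives[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_lad]
    if kept:
        out.intervals[segments.chrom] = np.asarray(kept, dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_aligned_bed(path: str, sample: str = "fusion") -> dict[str, list[AlignedRead]]:
    """Read aligned reads from BED3(+); returns per-chromosome lists."""
    out: dict[str, list[AlignedRead]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            out.setdefault(p[0], []).append(AlignedRead(p[0], int(p[1]), int(p[2]), sample))
    return out


def write_bedgraph(track: DamidScoreTrack, path: str) -> None:
    frags = track.fragment_map
    with open(path, "w") as fh:
        for (s, e), v, m in zip(frags.fragments, track.scores, track.missing):
            if not m:
                fh.write(f"{frags.chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph_track(path: str, frags: GatcFragmentMap) -> DamidScoreTrack:
    """Rebuild a score track over ``frags`` from a bedGraph written by us.

    Intervals absent from the file are missing.
    """
    scores = np.full(frags.n_fragments, np.nan)
    starts = frags.fragments[:, 0]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, _e, v = line.split("\t")[:4]
            if chrom != frags.chrom:
                continue
            i = int(np.searchsorted(starts, int(s)))
            if i < frags.n_fragments and starts[i] == int(s):
                scores[i] = float(v)
    missing = ~np.isfinite(scores)
    return DamidScoreTrack(fragment_map=frags, scores=scores, missing=missing)


def write_lads_bed(lads: LadSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lads.intervals):
            for s, e in lads.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_segments_bed(segments: SegmentSet, frags: GatcFragmentMap, path: str) -> None:
    bounds = frags.boundaries
    with open(path, "w") as fh:
        for seg in segments.segments:
            fh.write(
                f"{segments.chrom}\t{bounds[seg.start_fragment]}\t"
                f"{bounds[seg.end_fragment]}\t{seg.mean:.6g}\n"
            )
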