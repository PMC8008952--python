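"""Genomic interval statistics: base-coverage overlap, peak-in-region
fractions, and boundary/anchor-oriented average signal profiles.

These are the validation statistics used to compare ChIP peak sets and
chromatin domains with LADs: what percentage of one set's base pairs fall
inside another ("base coverage" overlap), what fraction of peaks reside
within LADs, and what a signal track looks like on average around LAD
boundaries (oriented outside → inside) or around point anchors.

All features are unstranded half-open intervals; inputs are merged on
construction so self-overlapping BED files cannot inflate coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntervalSet",
    "SignalProfile",
    "base_coverage_overlap",
    "peak_fraction_within",
    "boundary_profile",
    "anchor_profile",
    "read_bed",
    "write_bed",
]


@dataclass
class IntervalSet:
    """Per-chromosome sorted, merged, half-open intervals."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for chrom, iv in self.intervals.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if np.any(iv[:, 0] >= iv[:, 1]) or np.any(iv[:, 0] < 0):
                raise ValueError(f"{chrom}: invalid interval")
            merged[chrom] = _merge(iv)
        self.intervals = merged

    @property
    def total_coverage(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def n_intervals(self) -> int:
        return int(sum(len(iv) for iv in self.intervals.values()))

    def contains_points(self, chrom: str, points: np.ndarray) -> np.ndarray:
        """Boolean membership of each point position in the merged set."""
        iv = self.intervals.get(chrom)
        points = np.asarray(points)
        if iv is None or iv.size == 0:
            return np.zeros(points.shape, dtype=bool)
        edges = iv.ravel()  # starts and ends interleaved, sorted
        return np.searchsorted(edges, points, side="right") % 2 == 1


def _merge(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _intersect_1d(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged sorted interval arrays on one chromosome."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def base_coverage_overlap(A: IntervalSet, B: IntervalSet) -> dict:
    """Shared base pairs and mutual base-coverage percentages.

    pct_A_in_B = 100 · |A ∩ B| / |A| (and symmetrically). An empty set's
    percentage is NA (NaN) with a warning-free explicit result.
    """
    shared = 0
    for chrom in set(A.intervals) & set(B.intervals):
        inter = _intersect_1d(A.intervals[chrom], B.intervals[chrom])
        if inter.size:
            shared += int((inter[:, 1] - inter[:, 0]).sum())
    tot_a, tot_b = A.total_coverage, B.total_coverage
    return {
        "shared_bp": shared,
        "pct_A_in_B": 100.0 * shared / tot_a if tot_a else float("nan"),
        "pct_B_in_A": 100.0 * shared / tot_b if tot_b else float("nan"),
    }


def peak_fraction_within(
    peaks: IntervalSet, regions: IntervalSet, mode: str = "midpoint"
) -> dict:
    """Fraction of peaks residing within the regions.

    ``midpoint`` counts a peak iff its centre base lies in a region;
    ``any_overlap`` counts >= 1 bp of overlap.
    """
    if mode not in ("midpoint", "any_overlap"):
        raise ValueError("mode must be 'midpoint' or 'any_overlap'")
    n_total = peaks.n_intervals()
    if n_total == 0:
        raise ValueError("empty peak set")
    n_in = 0
    for chrom, pk in peaks.intervals.items():
        if mode == "midpoint":
            mids = (pk[:, 0] + pk[:, 1]) // 2
            n_in += int(regions.contains_points(chrom, mids).sum())
        else:
            reg = regions.intervals.get(chrom)
            if reg is None or reg.size == 0:
                continue
            for s, e in pk:
                i = np.searchsorted(reg[:, 1], s, side="right")
                if i < len(reg) and reg[i, 0] < e:
                    n_in += 1
    return {"n_within": n_in, "n_total": n_total, "fraction": n_in / n_total,
            "percent": 100.0 * n_in / n_total}


@dataclass
class SignalProfile:
    """Averaged signal around anchors.

    ``offsets`` are bin-start positions (bp) relative to the anchor,
    negative = outside/left of it; ``mean_values[k]`` averages the track
    over bin [offsets[k], offsets[k]+step) across all anchors with data
    there; ``n_anchors`` counts contributing anchors overall.
    """

    offsets: np.ndarray
    mean_values: np.ndarray
    n_anchors: int
    oriented: bool = False


def _track_bins(track) -> tuple[str, np.ndarray, np.ndarray]:
    """Accept a DamidScoreTrack or (chrom, intervals (n,2), values) tuple."""
    if hasattr(track, "fragment_map"):
        fm = track.fragment_map
        keep = ~track.missing
        return fm.chrom, fm.fragments[keep], track.scores[keep]
    chrom, iv, vals = track
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    return chrom, iv, np.asarray(vals, dtype=float)


def _window_means(
    iv: np.ndarray, vals: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage-weighted mean of a binned track over windows [lo, hi).

    Returns (sums, weights) so callers can average across anchors.
    """
    sums = np.zeros(len(lo))
    wts = np.zeros(len(lo))
    for k in range(len(lo)):
        s, e = lo[k], hi[k]
        if e <= s:
            continue
        ov = np.minimum(iv[:, 1], e) - np.maximum(iv[:, 0], s)
        m = ov > 0
        if m.any():
            sums[k] = float((vals[m] * ov[m]).sum())
            wts[k] = float(ov[m].sum())
    return sums, wts


def _profile(track, anchor_specs, flank: int, step: int,
             chrom_length: int | None, oriented: bool) -> SignalProfile:
    """anchor_specs: list of (position, sign); sign +1 keeps genomic
    orientation, -1 mirrors so positive offsets point leftward."""
    chrom, iv, vals = _track_bins(track)
    offsets = np.arange(-flank, flank, step)
    acc = np.zeros(len(offsets))
    cnt = np.zeros(len(offsets))
    L = chrom_length if chrom_length is not None else int(iv[:, 1].max()) if iv.size else 0
    for pos, sign in anchor_specs:
        if sign > 0:
            lo = pos + offsets
            hi = lo + step
        else:
            hi = pos - offsets
            lo = hi - step
        lo_c = np.clip(lo, 0, L)
        hi_c = np.clip(hi, 0, L)
        sums, wts = _window_means(iv, vals, lo_c, hi_c)
        has = wts > 0
        acc[has] += sums[has] / wts[has]
        cnt[has] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return SignalProfile(offsets=offsets, mean_values=means,
                         n_anchors=len(anchor_specs), oriented=oriented)


def boundary_profile(
    track,
    regions: IntervalSet,
    min_region: int = 100_000,
    flank: int = 100_000,
    step: int = 10_000,
    chrom_length: int | None = None,
) -> SignalProfile:
    """Average signal across all boundaries of regions >= ``min_region``,
    oriented outside (negative offsets) → inside (positive offsets).

    Both boundaries of each retained region contribute; right boundaries are
    mirrored so +offsets always point into the region. Offset bins are
    half-open [o, o+step) with the anchor at offset 0 on the inside edge.
    Windows beyond chromosome bounds contribute only in-bounds bins.
    """
    chrom, _iv, _vals = _track_bins(track)
    reg = regions.intervals.get(chrom)
    if reg is None or reg.size == 0:
        raise ValueError(f"no regions on {chrom}")
    reg = reg[(reg[:, 1] - reg[:, 0]) >= min_region]
    if reg.size == 0:
        raise ValueError(f"no regions >= {min_region} bp on {chrom}")
    anchors = [(int(s), +1) for s, _ in reg] + [(int(e), -1) for _, e in reg]
    return _profile(track, anchors, flank, step, chrom_length, oriented=True)


def anchor_profile(
    track,
    anchors,
    flank: int = 100_000,
    step: int = 10_000,
    chrom_length: int | None = None,
) -> SignalProfile:
    """Average signal in a symmetric window around point anchors (no
    orientation flip)."""
    anchors = list(anchors)
    if not anchors:
        raise ValueError("no anchors")
    specs = [(int(a), +1) for a in anchors]
    return _profile(track, specs, flank, step, chrom_length, oriented=False)


def read_bed(path: str) -> IntervalSet:
    per: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            per.setdefault(p[0], []).append((int(p[1]), int(p[2])))
    return IntervalSet({c: np.asarray(v, dtype=np.int64) for c, v in per.items()})


def write_bed(iset: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(iset.intervals):
            for s, e in iset.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
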