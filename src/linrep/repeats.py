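"""Resolve assembler-collapsed long terminal inverted repeats from read depth.

Linear plasmids of actinomycetes can carry terminal inverted repeats of
100 kb and more: one end of the plasmid is the reverse complement of the
other.  Long-read assemblers represent the two copies as a single contig
(arm + central region), so the assembly is short by one arm and mapped-read
coverage doubles over the collapsed arm relative to the unique central
region.  Given a coverage track this module

1. segments the track into constant-depth pieces (median smoothing followed
   by binary-segmentation change-point detection),
2. calls an end-anchored segment run with ~2x depth as the collapsed arm,
3. reconstructs the full plasmid length ``2R + C`` and, given the contig
   sequence, the full ``arm + central + revcomp(arm)`` sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CoverageTrack, reverse_complement

__all__ = [
    "CoverageSegment",
    "CollapsedRepeatCall",
    "segment_coverage",
    "call_collapsed_repeat",
    "reconstruct_full_length",
    "expand_collapsed_sequence",
]


@dataclass(frozen=True)
class CoverageSegment:
    """A constant-depth piece of a contig, 0-based half-open."""

    start: int
    end: int
    mean_depth: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CollapsedRepeatCall:
    """The inferred duplicated-arm / central-region decomposition.

    ``arm_interval`` (length R) is the collapsed repeat copy touching a
    contig end; ``central_interval`` (length C) is the unique remainder.
    The full plasmid is ``2R + C`` long.  ``depth_ratio`` is arm mean depth
    over central mean depth (about 2 for a true collapse); the baseline is
    the central mean, which reflects actual per-copy sequencing depth.
    """

    contig_id: str
    arm_interval: tuple[int, int]
    central_interval: tuple[int, int]
    baseline_depth: float
    depth_ratio: float
    arm_side: str  # "left" or "right"

    @property
    def arm_length(self) -> int:
        return self.arm_interval[1] - self.arm_interval[0]

    @property
    def central_length(self) -> int:
        return self.central_interval[1] - self.central_interval[0]

    @property
    def reconstructed_length(self) -> int:
        return 2 * self.arm_length + self.central_length


def _best_split(prefix1: np.ndarray, prefix2: np.ndarray, s: int, e: int):
    """Best change point in [s, e) by within-segment squared-deviation cost.

    ``prefix1``/``prefix2`` are cumulative sums of the signal and its square
    (length n+1), so any segment cost is O(1).
    Returns (gain, split) with split in (s, e)."""

    def sse(a: int, b: int) -> np.ndarray:
        n = b - a
        tot = prefix1[b] - prefix1[a]
        tot2 = prefix2[b] - prefix2[a]
        return tot2 - tot * tot / np.maximum(n, 1)

    full = float(sse(s, e))
    t = np.arange(s + 1, e)
    if t.size == 0:
        return 0.0, None
    n1 = t - s
    n2 = e - t
    sum1 = prefix1[t] - prefix1[s]
    sum2 = prefix1[e] - prefix1[t]
    sq1 = prefix2[t] - prefix2[s]
    sq2 = prefix2[e] - prefix2[t]
    cost = (sq1 - sum1 * sum1 / n1) + (sq2 - sum2 * sum2 / n2)
    i = int(np.argmin(cost))
    return full - float(cost[i]), int(t[i])


def segment_coverage(
    track: CoverageTrack,
    min_segment_bp: int = 5000,
    smooth_window_bp: int = 1000,
    max_segments: int = 20,
) -> list[CoverageSegment]:
    """Partition a coverage track into contiguous constant-depth segments.

    The track is median-filtered (centered window, forced odd so a clean
    step stays exactly in place) and then split by recursive binary
    segmentation with a BIC-style penalty scaled to the robust noise level
    of the raw track.  Segments shorter than *min_segment_bp* are merged
    into whichever neighbor has the closer mean.  Deterministic given the
    track; reported means are computed on the raw (unsmoothed) depth.
    """
    depth = track.depth
    n = depth.size
    if n < 2 * min_segment_bp:
        raise ValueError(
            f"track of {n} bp too short to segment (need >= {2 * min_segment_bp})"
        )
    w = min(smooth_window_bp, n)
    w += 1 - w % 2  # odd window keeps a noiseless step edge exact
    smooth = pd.Series(depth).rolling(w, center=True, min_periods=1).median().to_numpy()

    # Robust noise scale from raw first differences (steps contribute only
    # a handful of large diffs, which the median ignores).
    d = np.diff(depth)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    penalty = max(10.0 * sigma * sigma * np.log(n), 1e-9)

    prefix1 = np.concatenate([[0.0], np.cumsum(smooth)])
    prefix2 = np.concatenate([[0.0], np.cumsum(smooth * smooth)])

    boundaries = {0, n}
    stack = [(0, n)]
    while stack and len(boundaries) - 1 < max_segments:
        s, e = stack.pop()
        if e - s < 2:
            continue
        gain, split = _best_split(prefix1, prefix2, s, e)
        if split is None or gain <= penalty:
            continue
        boundaries.add(split)
        stack.append((s, split))
        stack.append((split, e))

    bounds = sorted(boundaries)
    segs = [(a, b) for a, b in zip(bounds, bounds[1:])]

    # Merge short segments into the neighbor with the more similar mean.
    def mean(a: int, b: int) -> float:
        return float(depth[a:b].mean())

    while len(segs) > 1:
        lengths = [b - a for a, b in segs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_segment_bp:
            break
        a, b = segs[i]
        m = mean(a, b)
        left_ok = i > 0
        right_ok = i < len(segs) - 1
        if left_ok and right_ok:
            go_left = abs(mean(*segs[i - 1]) - m) <= abs(mean(*segs[i + 1]) - m)
        else:
            go_left = left_ok
        if go_left:
            segs[i - 1] = (segs[i - 1][0], b)
        else:
            segs[i + 1] = (a, segs[i + 1][1])
        del segs[i]

    return [CoverageSegment(a, b, mean(a, b)) for a, b in segs]


def call_collapsed_repeat(
    segments: Sequence[CoverageSegment],
    ratio_band: tuple[float, float] = (1.6, 2.4),
    contig_id: str = "",
) -> CollapsedRepeatCall | None:
    """Call an end-anchored collapsed repeat, or ``None`` when there is none.

    Considers every run of segments anchored at either contig end as a
    candidate arm; the call requires the (length-weighted) mean depth of the
    arm over that of the remaining region to fall in *ratio_band* (default
    [1.6, 2.4], a tolerant reading of "twice the coverage").  The maximal
    qualifying run wins; a candidate arm covering the whole contig is a
    no-call because there is no unique region to anchor the baseline.
    """
    if not segments:
        raise ValueError("need at least one segment")
    segs = sorted(segments, key=lambda s: s.start)
    lo, hi = ratio_band
    n = len(segs)

    def weighted_mean(run: Sequence[CoverageSegment]) -> float:
        tot = sum(s.length for s in run)
        return sum(s.mean_depth * s.length for s in run) / tot

    best: CollapsedRepeatCall | None = None
    for side in ("left", "right"):
        for k in range(n - 1, 0, -1):  # maximal run first
            arm_run = segs[:k] if side == "left" else segs[n - k:]
            cen_run = segs[k:] if side == "left" else segs[: n - k]
            ratio = weighted_mean(arm_run) / weighted_mean(cen_run)
            if lo <= ratio <= hi:
                arm = (arm_run[0].start, arm_run[-1].end)
                cen = (cen_run[0].start, cen_run[-1].end)
                call = CollapsedRepeatCall(
                    contig_id=contig_id,
                    arm_interval=arm,
                    central_interval=cen,
                    baseline_depth=weighted_mean(cen_run),
                    depth_ratio=ratio,
                    arm_side=side,
                )
                if best is None or call.arm_length > best.arm_length:
                    best = call
                break  # only the maximal run per side
    return best


def reconstruct_full_length(contig_length: int, central_interval: tuple[int, int]) -> int:
    """Full plasmid length ``2R + C`` from the collapsed contig length and C.

    ``R = contig_length - C`` is the collapsed arm; the reconstruction is
    ``2*(contig_length - C) + C``.  Monotone increasing in contig length and
    decreasing in C; with C equal to the whole contig it degenerates to the
    contig length (no repeat).
    """
    c_start, c_end = central_interval
    C = c_end - c_start
    if C < 0:
        raise ValueError("central interval reversed")
    if C > contig_length:
        raise ValueError(
            f"central region ({C} bp) longer than contig ({contig_length} bp)"
        )
    return 2 * (contig_length - C) + C


def expand_collapsed_sequence(
    sequence: str,
    arm_interval: tuple[int, int],
    central_interval: tuple[int, int],
    arm_side: str = "left",
) -> str:
    """Reconstruct the full plasmid sequence from a collapsed contig.

    For a left-anchored arm the full plasmid is
    ``arm + central + reverse_complement(arm)``; for a right-anchored arm it
    is ``reverse_complement(arm) + central + arm``.  Either way the emitted
    sequence's first R bases equal the reverse complement of its last R
    bases, and its length is ``2R + C``.
    """
    L = len(sequence)
    a, c = sorted([arm_interval, central_interval])
    if not (a[0] == 0 and a[1] == c[0] and c[1] == L):
        raise ValueError(
            f"arm {arm_interval} and central {central_interval} do not "
            f"partition the contig [0, {L})"
        )
    if arm_side == "left":
        if arm_interval[0] != 0:
            raise ValueError("left arm must start at position 0")
        arm = sequence[arm_interval[0]: arm_interval[1]]
        central = sequence[central_interval[0]: central_interval[1]]
        return arm + central + reverse_complement(arm)
    if arm_side == "right":
        if arm_interval[1] != L:
            raise ValueError("right arm must end at the contig end")
        arm = sequence[arm_interval[0]: arm_interval[1]]
        central = sequence[central_interval[0]: central_interval[1]]
        return reverse_complement(arm) + central + arm
    raise ValueError(f"arm_side must be 'left' or 'right', got {arm_side!r}")
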