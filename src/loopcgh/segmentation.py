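"""Piecewise-constant least-squares segmentation of log2-ratio profiles.

The segmentation is the exact optimum of the penalized least-squares
objective  sum of within-segment squared deviations + penalty * n_segments,
found by dynamic programming, or the optimal k-segmentation when a segment
budget is given instead. Candidate aberrant segments are then retained by a
magnitude-and-length filter (|mean| >= 0.4, >= 5 probes by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, InvalidArgumentError

DEFAULT_RATIO_THRESHOLD = 0.4
DEFAULT_MIN_PROBES = 5


@dataclass(frozen=True)
class Segment:
    """One constant-mean run of consecutive probes on one array/chromosome."""

    array_id: str
    chrom: str
    start_index: int  # first probe index, inclusive
    end_index: int  # last probe index, inclusive
    start: int  # bp, 0-based
    end: int  # bp, half-open
    mean: float
    n_probes: int

    @property
    def sign(self) -> int:
        return 1 if self.mean > 0 else (-1 if self.mean < 0 else 0)

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateCall(Segment):
    """A threshold-passing aberrant segment annotated with its sign."""


def default_penalty(ratios: np.ndarray) -> float:
    """BIC-style penalty: sigma^2 * log n, sigma from successive differences.

    The robust noise estimate is MAD(diff)/(0.6745*sqrt(2)), immune to the
    level shifts the segmentation is meant to find.
    """
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    if n < 2:
        return 1.0
    diffs = np.diff(ratios)
    sigma = np.median(np.abs(diffs - np.median(diffs))) / (0.6745 * np.sqrt(2.0))
    sigma = max(sigma, 1e-6)
    return float(sigma**2 * np.log(n))


def _check_profile(ratios: np.ndarray) -> np.ndarray:
    values = np.asarray(ratios, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise InvalidArgumentError("profile must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise DataError(f"non-finite log2 ratio at position {bad}")
    return values


def _segment_cost_matrix_row(s1: np.ndarray, s2: np.ndarray, i: int) -> np.ndarray:
    """SSE of segments [j, i) for all j < i, via prefix sums."""
    lengths = i - np.arange(i)
    sums = s1[i] - s1[:i]
    sq = s2[i] - s2[:i]
    return sq - sums * sums / lengths


def _dp_penalized(values: np.ndarray, penalty: float) -> list[int]:
    """Optimal breakpoints (segment start indices, excluding 0) for the
    penalized objective. Ties resolved toward the leftmost breakpoint."""
    n = len(values)
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    best = np.empty(n + 1)
    best[0] = 0.0
    prev = np.zeros(n + 1, dtype=int)
    for i in range(1, n + 1):
        cand = best[:i] + _segment_cost_matrix_row(s1, s2, i) + penalty
        j = int(np.argmin(cand))  # first minimum = leftmost breakpoint
        best[i] = cand[j]
        prev[i] = j
    cuts = []
    i = n
    while i > 0:
        cuts.append(prev[i])
        i = prev[i]
    return sorted(cuts)[1:]  # drop the leading 0


def _dp_k_segments(values: np.ndarray, k: int) -> list[int]:
    """Optimal exactly-k segmentation breakpoints (leftmost on ties)."""
    n = len(values)
    k = min(k, n)
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    inf = np.inf
    best = np.full((k + 1, n + 1), inf)
    prev = np.zeros((k + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for seg in range(1, k + 1):
        for i in range(seg, n + 1):
            cand = best[seg - 1, :i] + _segment_cost_matrix_row(s1, s2, i)
            j = int(np.argmin(cand))
            best[seg, i] = cand[j]
            prev[seg, i] = j
    cuts = []
    i, seg = n, k
    while seg > 0:
        cuts.append(prev[seg, i])
        i = prev[seg, i]
        seg -= 1
    return sorted(cuts)[1:]


def segment_profile(
    ratios,
    penalty: float | None = None,
    max_segments: int | None = None,
    array_id: str = "",
    chrom: str = "",
    starts=None,
    ends=None,
) -> list[Segment]:
    """Segment one ordered log2-ratio profile.

    Exactly one of ``penalty`` / ``max_segments`` drives the objective; with
    neither given a BIC-style default penalty is derived from the data.
    ``starts``/``ends`` (bp per probe) are optional; probe indices are used
    as coordinates when absent.
    """
    values = _check_profile(ratios)
    if penalty is not None and max_segments is not None:
        raise InvalidArgumentError("give either penalty or max_segments, not both")
    if max_segments is not None:
        if max_segments < 1:
            raise InvalidArgumentError("max_segments must be >= 1")
        cuts = _dp_k_segments(values, max_segments)
    else:
        if penalty is None:
            penalty = default_penalty(values)
        if penalty <= 0:
            raise InvalidArgumentError("penalty must be positive")
        cuts = _dp_penalized(values, penalty)

    n = len(values)
    starts = np.arange(n) if starts is None else np.asarray(starts)
    ends = np.arange(1, n + 1) if ends is None else np.asarray(ends)
    bounds = [0] + list(cuts) + [n]
    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        segments.append(
            Segment(
                array_id=array_id,
                chrom=chrom,
                start_index=lo,
                end_index=hi - 1,
                start=int(starts[lo]),
                end=int(ends[hi - 1]),
                mean=float(values[lo:hi].mean()),
                n_probes=hi - lo,
            )
        )
    return segments


def segmentation_cost(
    ratios, segments: list[Segment], penalty: float = 0.0
) -> float:
    """Penalized SSE of a given segmentation (used by optimality checks)."""
    values = np.asarray(ratios, dtype=float)
    total = 0.0
    for seg in segments:
        chunk = values[seg.start_index : seg.end_index + 1]
        total += float(((chunk - chunk.mean()) ** 2).sum())
    return total + penalty * len(segments)


def filter_segments(
    segments: list[Segment],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> list[CandidateCall]:
    """Retain segments with |mean| >= threshold and >= min_probes probes."""
    if ratio_threshold < 0:
        raise InvalidArgumentError("ratio_threshold must be non-negative")
    if min_probes < 1:
        raise InvalidArgumentError("min_probes must be >= 1")
    calls = []
    for seg in segments:
        if abs(seg.mean) >= ratio_threshold and seg.n_probes >= min_probes:
            calls.append(CandidateCall(**vars(seg)))
    return calls


def segment_table(
    table,
    penalty: float | None = None,
    max_segments: int | None = None,
) -> list[Segment]:
    """Segment every chromosome of a :class:`ProbeRatioTable` independently."""
    segments: list[Segment] = []
    frame = table.frame
    for chrom in frame["chrom"].unique():
        sub = frame[frame["chrom"] == chrom]
        segments.extend(
            segment_profile(
                sub["ratio"].to_numpy(),
                penalty=penalty,
                max_segments=max_segments,
                array_id=table.array_id,
                chrom=str(chrom),
                starts=sub["start"].to_numpy(),
                ends=sub["end"].to_numpy(),
            )
        )
    return segments
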