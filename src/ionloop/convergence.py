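"""Replica-exchange sampling diagnostics.

Convergence of an ensemble observable is judged by comparing its
distribution over growing cumulative time windows (e.g. frames 50-100,
50-150, 50-180, 50-200 of a 200-frame trajectory): once successive
windows produce overlapping histograms the estimate has stopped
drifting. Ladder traversal is summarized by the fraction of temperature
rungs a replica visited and its number of bottom-top-bottom round
trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError

__all__ = [
    "WindowedDistributions",
    "windowed_distribution",
    "distribution_overlap",
    "ladder_coverage",
    "longest_dwell",
    "convergence_flag",
]


@dataclass
class WindowedDistributions:
    """Per-window normalized histograms on shared bin edges."""

    name: str
    windows: list          # (start, end) frame pairs
    edges: np.ndarray
    histograms: np.ndarray  # (n_windows, n_bins), each row sums to 1


def windowed_distribution(values: np.ndarray, windows: list,
                          bin_width: float,
                          name: str = "observable") -> WindowedDistributions:
    """Normalized histograms of a series over a list of frame windows.

    Windows are half-open ``[start, end)`` in frame units and share bin
    edges spanning the pooled range of all windows.
    """
    values = np.asarray(values, dtype=float).ravel()
    slices = []
    for start, end in windows:
        if not (0 <= start < end <= len(values)):
            raise AnalysisError(
                f"window ({start}, {end}) outside series of length "
                f"{len(values)}")
        slices.append(values[start:end])
    pooled = np.concatenate(slices)
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.asarray([lo, lo + bin_width])
    hists = []
    for s in slices:
        h = np.histogram(s, bins=edges)[0].astype(float)
        hists.append(h / h.sum())
    return WindowedDistributions(name=name, windows=list(windows),
                                 edges=edges, histograms=np.asarray(hists))


def distribution_overlap(h1: np.ndarray, h2: np.ndarray,
                         edges1: np.ndarray | None = None,
                         edges2: np.ndarray | None = None) -> float:
    """Histogram intersection sum_i min(p_i, q_i), in [0, 1].

    1 iff the normalized histograms are identical, 0 iff their supports
    are disjoint. Requires shared bin edges.
    """
    if edges1 is not None and edges2 is not None:
        if len(edges1) != len(edges2) or not np.allclose(edges1, edges2):
            raise AnalysisError("histograms have mismatched bin edges")
    h1, h2 = np.asarray(h1, dtype=float), np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise AnalysisError("histograms have mismatched shapes")
    return float(np.minimum(h1, h2).sum())


def convergence_flag(wd: WindowedDistributions,
                     threshold: float = 0.9) -> tuple[bool, float]:
    """(converged, overlap): overlap of the last two cumulative windows
    against a configurable threshold. The threshold is this package's
    quantification of the usual visual 'well overlapped' judgement."""
    if len(wd.histograms) < 2:
        raise AnalysisError("need at least two windows")
    ov = distribution_overlap(wd.histograms[-2], wd.histograms[-1])
    return ov >= threshold, ov


def ladder_coverage(visits: np.ndarray, n_rungs: int) -> tuple[float, int]:
    """(fraction of rungs visited, bottom-top-bottom round trips).

    A round trip is one completed excursion rung 0 -> top rung -> rung
    0. The count is invariant under reversing the trace.
    """
    visits = np.asarray(visits, dtype=int)
    if visits.size == 0:
        raise AnalysisError("empty replica trace")
    if visits.min() < 0 or visits.max() >= n_rungs:
        raise AnalysisError("visit index outside [0, n_rungs)")
    fraction = len(np.unique(visits)) / n_rungs
    top = n_rungs - 1
    # count alternations of the subsequence restricted to {0, top}
    marks = visits[(visits == 0) | (visits == top)]
    if marks.size == 0:
        return fraction, 0
    changes = int(np.sum(np.diff(marks) != 0))
    return fraction, changes // 2


def longest_dwell(series: np.ndarray, cutoff: float) -> int:
    """Longest run of consecutive frames with value < cutoff.

    Used as an ion-trapping diagnostic on per-ion minimum-distance
    traces: a dwell spanning the whole series means the ion never
    detached.
    """
    below = np.asarray(series) < cutoff
    best = run = 0
    for b in below:
        run = run + 1 if b else 0
        best = max(best, run)
    return best
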