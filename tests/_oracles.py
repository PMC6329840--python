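"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible — explicit loops, no shared
code with the package implementation — so each serves as an independent
cross-check of the corresponding vectorised routine.
"""

from __future__ import annotations

import itertools

import numpy as np


def run_lengths(exceed: np.ndarray, min_duration: int) -> list[tuple[int, int]]:
    """All (start, end) inclusive runs of True with length >= min_duration."""
    runs = []
    start = None
    for i, flag in enumerate(list(exceed) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_duration:
                runs.append((start, i - 1))
            start = None
    return runs


def hwmid_bruteforce(
    series: np.ndarray,
    thresholds: np.ndarray,
    t25: float,
    t75: float,
    min_duration: int = 3,
) -> float:
    """Straightforward re-implementation of the annual HWMId."""
    best = 0.0
    for start, end in run_lengths(series > thresholds, min_duration):
        magnitude = 0.0
        for d in range(start, end + 1):
            if t75 > t25 and series[d] > t25:
                magnitude += (series[d] - t25) / (t75 - t25)
        best = max(best, magnitude)
    return best


def tx5x_bruteforce(series: np.ndarray, window: int = 5) -> float:
    best = -np.inf
    for i in range(len(series) - window + 1):
        best = max(best, float(np.mean(series[i : i + window])))
    return best


def lmoments_combinatorial(x: np.ndarray) -> tuple[float, float, float]:
    """lambda1, lambda2, tau3 from all pairs / all triples of the sample.

    lambda2 = E|X_i - X_j| / 2 over distinct pairs; lambda3 from the expected
    value of (max - 2 median + min)/3 over distinct triples.
    """
    x = np.asarray(x, dtype=float)
    l1 = float(np.mean(x))
    pair_sum = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(x, 2):
        pair_sum += abs(a - b)
        n_pairs += 1
    l2 = pair_sum / n_pairs / 2.0
    tri_sum = 0.0
    n_tri = 0
    for triple in itertools.combinations(x, 3):
        lo, mid, hi = sorted(triple)
        tri_sum += (hi - 2 * mid + lo) / 3.0
        n_tri += 1
    l3 = tri_sum / n_tri
    return l1, l2, l3 / l2


def aggregate_2x2_sinlat(field: np.ndarray, lat_bounds: np.ndarray, lon_bounds: np.ndarray) -> np.ndarray:
    """Hand-computed conservative 4x4 -> 2x2 aggregation on a sphere.

    Each coarse cell is the area-weighted mean of its 2x2 fine cells, with
    areas proportional to (sin(lat_hi) - sin(lat_lo)) * dlon.
    """
    out = np.empty((2, 2))
    sin_b = np.sin(np.deg2rad(lat_bounds))
    band = np.diff(sin_b)  # per fine row
    dlon = np.diff(lon_bounds)
    for bi in range(2):
        for bj in range(2):
            num = 0.0
            den = 0.0
            for i in range(2 * bi, 2 * bi + 2):
                for j in range(2 * bj, 2 * bj + 2):
                    w = band[i] * dlon[j]
                    num += w * field[i, j]
                    den += w
            out[bi, bj] = num / den
    return out
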