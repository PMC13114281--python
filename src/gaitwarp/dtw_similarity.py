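"""Dynamic time warping with path-length normalisation and a Gaussian-kernel
similarity score.

Given two angle series X (length N) and Y (length M) in degrees, the local
distance is the absolute difference d(x_i, y_j) = |x_i - y_j| and the
cumulative cost obeys

    D(i, j) = d(x_i, y_j) + min(D(i-1, j), D(i, j-1), D(i-1, j-1)),

with D(1, 1) = d(x_1, y_1) and the first row/column accumulating along their
only predecessor.  The DTW distance is D(N, M); the optimal warping path is
recovered by backtracking the argmin chain, breaking ties by preferring the
diagonal predecessor and then (i-1, j).

Because D(N, M) grows with series length, it is divided by the number of
steps on the warping path before scoring; the similarity score is

    similarity = exp(-normalized_dist / sigma),        sigma = 10 deg/step,

mapping 0 distance to 1 and decreasing strictly with distance.  An optional
Sakoe-Chiba band is available but off by default (the protocol uses the
unconstrained recurrence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DEFAULT_SIGMA",
    "WarpingPath",
    "DTWResult",
    "local_distance",
    "dtw",
    "similarity_score",
    "align_pairs",
]

#: Gaussian-kernel width in degrees per path step.
DEFAULT_SIGMA = 10.0


@dataclass(frozen=True)
class WarpingPath:
    """Ordered (i, j) index pairs of the optimal alignment, 1-based.

    The path starts at (1, 1), ends at (N, M), and each step increments i, j
    or both by exactly one (monotone and continuous).
    """

    steps: np.ndarray  # (L, 2) int

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=np.int64))
        if self.steps.ndim != 2 or self.steps.shape[1] != 2:
            raise ValueError("steps must be an (L, 2) array of index pairs")

    def __len__(self) -> int:
        return self.steps.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.steps))

    def validate(self, n: int, m: int) -> None:
        s = self.steps
        if s.shape[0] == 0:
            raise ValueError("empty warping path")
        if tuple(s[0]) != (1, 1) or tuple(s[-1]) != (n, m):
            raise ValueError(f"path must run from (1, 1) to ({n}, {m})")
        d = np.diff(s, axis=0)
        if np.any(d < 0) or np.any(d > 1) or np.any(np.all(d == 0, axis=1)):
            raise ValueError("each path step must increment i, j or both by 1")


@dataclass(frozen=True)
class DTWResult:
    """Alignment summary: raw distance, path, normalised distance, similarity."""

    dtw_dist: float
    path: WarpingPath
    normalized_dist: float
    similarity: float
    sigma: float

    @property
    def path_length(self) -> int:
        return len(self.path)


def local_distance(xi: float, yi: float) -> float:
    """Absolute angular difference |xi - yi| in degrees."""
    return abs(xi - yi)


def similarity_score(normalized_dist: float, sigma: float = DEFAULT_SIGMA) -> float:
    """Gaussian-kernel similarity exp(-normalized_dist / sigma), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if normalized_dist < 0:
        raise ValueError("normalized distance must be non-negative")
    return math.exp(-normalized_dist / sigma)


@njit(cache=True)
def _cost_matrix(x: np.ndarray, y: np.ndarray, band: int) -> np.ndarray:  # pragma: no cover
    n, m = x.size, y.size
    inf = np.inf
    d = np.full((n, m), inf)
    for i in range(n):
        j0, j1 = 0, m
        if band >= 0:
            j0 = max(0, i - band)
            j1 = min(m, i + band + 1)
        for j in range(j0, j1):
            cost = abs(x[i] - y[j])
            if i == 0 and j == 0:
                d[i, j] = cost
            elif i == 0:
                d[i, j] = cost + d[i, j - 1]
            elif j == 0:
                d[i, j] = cost + d[i - 1, j]
            else:
                best = d[i - 1, j - 1]
                if d[i - 1, j] < best:
                    best = d[i - 1, j]
                if d[i, j - 1] < best:
                    best = d[i, j - 1]
                d[i, j] = cost + best
    return d


@njit(cache=True)
def _backtrack(d: np.ndarray) -> np.ndarray:  # pragma: no cover
    n, m = d.shape
    # worst-case path length is n + m - 1
    path = np.empty((n + m - 1, 2), dtype=np.int64)
    i, j = n - 1, m - 1
    k = path.shape[0]
    while True:
        k -= 1
        path[k, 0] = i + 1
        path[k, 1] = j + 1
        if i == 0 and j == 0:
            break
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            # tie-break: diagonal first, then (i-1, j), then (i, j-1)
            diag = d[i - 1, j - 1]
            up = d[i - 1, j]
            left = d[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
    return path[k:]


def dtw(x: np.ndarray, y: np.ndarray, sigma: float = DEFAULT_SIGMA,
        band: int | None = None) -> DTWResult:
    """Full dynamic-time-warping alignment of two 1-D angle series.

    Parameters
    ----------
    x, y
        Finite 1-D series in degrees (clean input; missing values are a
        contract violation — run the cleaning chain first).
    sigma
        Gaussian-kernel width in degrees/step for the similarity score.
    band
        Optional Sakoe-Chiba band half-width (in samples); ``None`` disables
        the constraint.

    Returns
    -------
    DTWResult
        Raw cumulative distance D(N, M), the backtracked warping path,
        the path-length-normalised distance and the similarity score.
    """
    x = np.ascontiguousarray(x, dtype=np.float64).ravel()
    y = np.ascontiguousarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW requires non-empty series")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("DTW input contains missing values; clean first")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if band is not None and band < abs(x.size - y.size):
        raise ValueError("band is narrower than the length difference; "
                         "no monotone path exists")
    d = _cost_matrix(x, y, -1 if band is None else int(band))
    steps = _backtrack(d)
    path = WarpingPath(steps)
    dist = float(d[-1, -1])
    norm = dist / len(path)
    return DTWResult(
        dtw_dist=dist,
        path=path,
        normalized_dist=norm,
        similarity=similarity_score(norm, sigma),
        sigma=sigma,
    )


def align_pairs(x: np.ndarray, y: np.ndarray, path: WarpingPath) -> np.ndarray:
    """Matched sample pairs (x_i, y_j) along a warping path, one per step.

    The pairing preserves path order and feeds the agreement statistics;
    the number of pairs equals the path length.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    path.validate(x.size, y.size)
    idx = path.steps - 1
    return np.column_stack([x[idx[:, 0]], y[idx[:, 1]]])
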