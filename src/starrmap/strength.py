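"""Changepoint-based classification of enhancers into strong/intermediate/weak.

Enhancers are ranked by log2 STARR-seq activity and the ranked curve is
segmented by detecting simultaneous changes in mean and variance under a
Gaussian model: the cost of a segment of length m with MLE variance s2 is
``m * (log(2*pi) + log(s2) + 1)`` (twice the negative log-likelihood), and a
penalty is paid per changepoint (default MBIC-like, ``3 * log(n)``).
The activity value at the highest changepoint becomes the lower threshold
for strong enhancers and the value at the lowest changepoint the upper
threshold for weak ones; everything in between is intermediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrengthThresholds",
    "detect_changepoints",
    "derive_thresholds",
    "classify_strength",
    "CLASS_ORDER",
]

CLASS_ORDER = ("weak", "intermediate", "strong")
_VAR_FLOOR = 1e-8  # keeps log-variance finite on (near-)constant segments


@dataclass
class StrengthThresholds:
    strong_lower_log2: float
    weak_upper_log2: float
    changepoint_indices: list[int] = field(default_factory=list)
    method: str = "manual"
    penalty: float = float("nan")

    def __post_init__(self):
        if self.weak_upper_log2 > self.strong_lower_log2:
            raise ValueError("weak_upper must be <= strong_lower")


def _prefix_sums(x: np.ndarray):
    p1 = np.concatenate([[0.0], np.cumsum(x)])
    p2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return p1, p2


def _segment_costs(p1, p2, s: np.ndarray, t: int) -> np.ndarray:
    """Cost of segments [s_i, t) — twice the Gaussian NLL at the MLE."""
    m = t - s
    mean = (p1[t] - p1[s]) / m
    var = (p2[t] - p2[s]) / m - mean * mean
    var = np.maximum(var, _VAR_FLOOR)
    return m * (math.log(2 * math.pi) + np.log(var) + 1.0)


def detect_changepoints(
    values,
    max_changepoints: int | None = None,
    penalty: float | None = None,
    method: str = "auto",
    min_segment: int = 2,
) -> list[int]:
    """0-based indices of the last element of each segment (excluding the final).

    ``method``: "pelt" (penalised exact search, unconstrained count), "dp"
    (exact dynamic programme honouring ``max_changepoints``), "binseg"
    (greedy binary segmentation), or "auto" which picks "dp" when a
    changepoint budget is given and "pelt" otherwise. Constant input yields
    no changepoints; n < 4 is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if penalty is None:
        penalty = 3.0 * math.log(n)
    if method == "auto":
        method = "pelt" if max_changepoints is None else "dp"

    if method == "pelt":
        cps = _pelt(x, penalty, min_segment)
        if max_changepoints is not None and len(cps) > max_changepoints:
            cps = _dp(x, max_changepoints, penalty, min_segment)
    elif method == "dp":
        k = max_changepoints if max_changepoints is not None else (n // min_segment - 1)
        cps = _dp(x, k, penalty, min_segment)
    elif method == "binseg":
        k = max_changepoints if max_changepoints is not None else (n // min_segment - 1)
        cps = _binseg(x, k, penalty, min_segment)
    else:
        raise ValueError(f"unknown method {method!r}")
    return sorted(int(c) for c in cps)


def _pelt(x: np.ndarray, penalty: float, minseg: int) -> list[int]:
    n = x.size
    p1, p2 = _prefix_sums(x)
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=np.int64)
    cands = [0]
    for t in range(minseg, n + 1):
        s = np.array([c for c in cands if t - c >= minseg], dtype=np.int64)
        if s.size == 0:
            continue
        tot = F[s] + _segment_costs(p1, p2, s, t) + penalty
        j = int(np.argmin(tot))
        F[t] = tot[j]
        last[t] = s[j]
        # PELT pruning (cost is subadditive, so pruned points stay suboptimal)
        keep = tot - penalty <= F[t]
        cands = [int(c) for c, k in zip(s, keep) if k]
        cands.append(t - minseg + 1 if t - minseg + 1 > 0 else 0)
        cands = sorted(set(c for c in cands if c <= t))
    # backtrack
    cps = []
    t = n
    while t > 0:
        s = int(last[t])
        if s == 0:
            break
        cps.append(s - 1)  # last element of the preceding segment
        t = s
    return cps[::-1]


def _dp(x: np.ndarray, max_cp: int, penalty: float, minseg: int) -> list[int]:
    """Exact minimisation over segmentations with <= max_cp changepoints."""
    n = x.size
    p1, p2 = _prefix_sums(x)
    max_cp = max(0, min(max_cp, n // minseg - 1))
    # F[k, t]: best cost of [0, t) with exactly k changepoints (k+1 segments)
    F = np.full((max_cp + 1, n + 1), np.inf)
    back = np.zeros((max_cp + 1, n + 1), dtype=np.int64)
    for t in range(minseg, n + 1):
        F[0, t] = _segment_costs(p1, p2, np.array([0]), t)[0]
    for k in range(1, max_cp + 1):
        for t in range((k + 1) * minseg, n + 1):
            s = np.arange(k * minseg, t - minseg + 1)
            tot = F[k - 1, s] + _segment_costs(p1, p2, s, t)
            j = int(np.argmin(tot))
            F[k, t] = tot[j]
            back[k, t] = s[j]
    totals = F[:, n] + penalty * np.arange(max_cp + 1)
    k_best = int(np.argmin(totals))
    cps = []
    t, k = n, k_best
    while k > 0:
        s = int(back[k, t])
        cps.append(s - 1)
        t, k = s, k - 1
    return cps[::-1]


def _binseg(x: np.ndarray, max_cp: int, penalty: float, minseg: int) -> list[int]:
    """Greedy binary segmentation; splits while the gain exceeds the penalty."""
    p1, p2 = _prefix_sums(x)

    def seg_cost(a, b):
        return _segment_costs(p1, p2, np.array([a]), b)[0]

    segments = [(0, x.size)]
    cps: list[int] = []
    for _ in range(max_cp):
        best = None
        for a, b in segments:
            for s in range(a + minseg, b - minseg + 1):
                gain = seg_cost(a, b) - seg_cost(a, s) - seg_cost(s, b)
                if best is None or gain > best[0]:
                    best = (gain, a, s, b)
        if best is None or best[0] <= penalty:
            break
        _, a, s, b = best
        segments.remove((a, b))
        segments += [(a, s), (s, b)]
        cps.append(s - 1)
    return cps


def derive_thresholds(
    ranked_activities,
    max_changepoints: int | None = None,
    penalty: float | None = None,
    method: str = "auto",
) -> StrengthThresholds:
    """Thresholds from the changepoints of the ascending-ranked activity curve.

    The changepoint at the largest activity value sets ``strong_lower`` and
    the one at the smallest sets ``weak_upper`` (on ascending-ranked input
    these are the last and first changepoints). With a single changepoint
    both thresholds coincide and the intermediate class is empty.
    """
    x = np.asarray(ranked_activities, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("activities must be ranked ascending")
    if penalty is None:
        penalty = 3.0 * math.log(x.size)
    cps = detect_changepoints(x, max_changepoints=max_changepoints,
                              penalty=penalty, method=method)
    if not cps:
        raise ValueError(
            "no changepoints detected; supply manual thresholds "
            "(strong_lower, weak_upper) instead"
        )
    return StrengthThresholds(
        strong_lower_log2=float(x[cps[-1]]),
        weak_upper_log2=float(x[cps[0]]),
        changepoint_indices=list(cps),
        method="gaussian-meanvar",
        penalty=float(penalty),
    )


def classify_strength(
    activities_log2, thresholds: StrengthThresholds, boundary: str = "outer"
) -> np.ndarray:
    """Label each enhancer weak/intermediate/strong.

    ``boundary="outer"`` (default) assigns values exactly at a threshold to
    the outer class (weak/strong); ``"inner"`` assigns them to intermediate.
    """
    a = np.asarray(activities_log2, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("activities must be finite")
    out = np.full(a.shape, "intermediate", dtype=object)
    if boundary == "outer":
        out[a <= thresholds.weak_upper_log2] = "weak"
        out[a >= thresholds.strong_lower_log2] = "strong"
    elif boundary == "inner":
        out[a < thresholds.weak_upper_log2] = "weak"
        out[a > thresholds.strong_lower_log2] = "strong"
    else:
        raise ValueError(f"unknown boundary rule {boundary!r}")
    return out
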