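"""Correlation and goodness-of-fit kernel.

Pearson's r with its two-tailed significance from the exact t transform
t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; Spearman's rs as the
Pearson correlation of mean ranks, with either the same t approximation
(matching common online calculators) or, for small n, an exact permutation
p-value; and the coefficient of determination R^2 = 1 - SS_res/SS_tot,
always evaluated in the original (untransformed) response space.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError

Method = Literal["pearson", "spearman"]


@dataclass(frozen=True)
class CorrelationResult:
    method: Method
    r: float
    n: int
    p: float

    def to_tsv_row(self) -> str:
        return f"{self.method}\t{self.r:.4f}\t{self.n}\t{self.p:.4f}"


def _as_arrays(x: Sequence[float], y: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise ParameterError("x and y must be one-dimensional and of equal length")
    if xa.size < min_n:
        raise ParameterError(f"need at least {min_n} points, got {xa.size}")
    return xa, ya

def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise DegenerateInputError("zero variance in x or y")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def t_approx_p(r: float, n: int) -> float:
    """Two-tailed p for a correlation coefficient via the t transform."""
    if n < 3:
        raise ParameterError(f"p undefined for n < 3, got n={n}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed t-based p."""
    xa, ya = _as_arrays(x, y, min_n=3)
    r = _pearson_r(xa, ya)
    return CorrelationResult("pearson", r, int(xa.size), t_approx_p(r, int(xa.size)))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, observed_r: float) -> float:
    """Exact two-tailed permutation p: share of rank permutations with |rs| >= |observed|."""
    n = rx.size
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(range(n)):
        rs = _pearson_r(rx, ry[list(perm)])
        if abs(rs) >= abs(observed_r) - tol:
            count += 1
        total += 1
    return count / total


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    p_mode: Literal["t", "exact"] = "t",
) -> CorrelationResult:
    """Spearman rank correlation (mean ranks for ties), two-tailed p.

    ``p_mode="exact"`` enumerates all rank permutations (allowed for n <= 10).
    """
    xa, ya = _as_arrays(x, y, min_n=3)
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise DegenerateInputError("all-tied series: Spearman undefined")
    r = _pearson_r(rx, ry)
    n = int(xa.size)
    if p_mode == "t":
        p = t_approx_p(r, n)
    elif p_mode == "exact":
        if n > 10:
            raise ParameterError("exact permutation p limited to n <= 10")
        p = _exact_spearman_p(rx, ry, r)
    else:
        raise ParameterError(f"unknown p_mode {p_mode!r}")
    return CorrelationResult("spearman", r, n, p)


def r_squared(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (original response space).

    Negative values are legal for nonlinear fits worse than the mean.
    """
    obs, fit = _as_arrays(observed, fitted, min_n=2)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise DegenerateInputError("observed series has zero variance")
    ss_res = float(((obs - fit) ** 2).sum())
    return 1.0 - ss_res / ss_tot
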