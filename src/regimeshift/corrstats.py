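"""Parameter-correlation matrices and dependent-correlation tests.

Two correlations that share a variable (e.g. one behavioral measure
correlated with two different neural measures from the same subjects)
are themselves dependent; comparing them needs either the parametric
z test of Meng, Rosenthal & Rubin (Fisher-transformed correlations with
a dependence correction) or a subject-wise bootstrap of the difference.
Both are provided; the package's default tail convention for the
difference test is one-tailed, with two-tailed available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrPair",
    "parameter_correlation_matrix",
    "meng_z",
    "BootstrapResult",
    "bootstrap_corr_diff",
]

_R_GUARD = 1.0 - 1e-12


@dataclass(frozen=True)
class CorrPair:
    """Two dependent Pearson correlations sharing one variable.

    ``r1`` and ``r2`` each correlate the shared variable with one of two
    non-shared variables; ``r_x`` is the correlation between the two
    non-shared variables; ``N`` is the number of subjects.
    """

    r1: float
    r2: float
    r_x: float
    N: int

    def __post_init__(self) -> None:
        for name, r in (("r1", self.r1), ("r2", self.r2), ("r_x", self.r_x)):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {r}")
        if self.N < 4:
            raise ValueError("N must be >= 4 (the test uses N - 3)")


def parameter_correlation_matrix(
    alpha: np.ndarray, beta: np.ndarray
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations of subject-level parameters.

    ``alpha`` and ``beta`` are (n_subjects, 3) arrays of per-level
    estimates. Returns 3x3 matrices (with matching p-value frames) for
    the cross-family (alpha_i vs beta_j), within-alpha and within-beta
    comparisons. A constant column yields NaN entries (flagged, not
    silently zeroed).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha.ndim != 2 or alpha.shape[1] != 3 or alpha.shape != beta.shape:
        raise ValueError("alpha and beta must both be (n_subjects, 3)")
    if alpha.shape[0] < 4:
        raise ValueError("need >= 4 subjects with complete parameter sets")

    def matrix(x, y, xl, yl):
        r = np.full((3, 3), np.nan)
        p = np.full((3, 3), np.nan)
        for i in range(3):
            for j in range(3):
                if np.ptp(x[:, i]) == 0 or np.ptp(y[:, j]) == 0:
                    continue  # constant column: correlation undefined
                r[i, j], p[i, j] = stats.pearsonr(x[:, i], y[:, j])
        rows = [f"{xl}{i+1}" for i in range(3)]
        cols = [f"{yl}{j+1}" for j in range(3)]
        return (pd.DataFrame(r, index=rows, columns=cols),
                pd.DataFrame(p, index=rows, columns=cols))

    ab_r, ab_p = matrix(alpha, beta, "alpha_", "beta_")
    aa_r, aa_p = matrix(alpha, alpha, "alpha_", "alpha_")
    bb_r, bb_p = matrix(beta, beta, "beta_", "beta_")
    return {
        "cross_r": ab_r, "cross_p": ab_p,
        "within_alpha_r": aa_r, "within_alpha_p": aa_p,
        "within_beta_r": bb_r, "within_beta_p": bb_p,
    }


def meng_z(pair: CorrPair) -> tuple[float, float, float]:
    """Dependent-correlation z test (Meng-Rosenthal-Rubin).

    z = (z_r1 - z_r2) * sqrt((N - 3) / (2 (1 - r_x) h)) with
    r2bar = (r1^2 + r2^2) / 2, f = (1 - r_x) / (2 (1 - r2bar)) capped at
    1, and h = 1 + r2bar / (1 - r2bar) * (1 - f). Returns
    (z, one_tailed_p, two_tailed_p); the one-tailed p is the upper-tail
    probability of the observed z.
    """
    if abs(pair.r1) >= 1.0 or abs(pair.r2) >= 1.0:
        raise ValueError("|r1| and |r2| must be < 1")
    z1 = np.arctanh(np.clip(pair.r1, -_R_GUARD, _R_GUARD))
    z2 = np.arctanh(np.clip(pair.r2, -_R_GUARD, _R_GUARD))
    r2bar = (pair.r1**2 + pair.r2**2) / 2.0
    f = min((1.0 - pair.r_x) / (2.0 * (1.0 - r2bar)), 1.0)
    h = 1.0 + r2bar / (1.0 - r2bar) * (1.0 - f)
    z = (z1 - z2) * np.sqrt((pair.N - 3) / (2.0 * (1.0 - pair.r_x) * h))
    one_p = float(stats.norm.sf(z))
    two_p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), one_p, two_p


@dataclass
class BootstrapResult:
    """Subject-wise bootstrap of a dependent-correlation difference."""

    observed_diff: float
    p_value: float
    tail: str
    n_boot: int
    n_redrawn: int
    seed: Optional[int]
    diff_mean: float
    diff_sd: float
    ci_2_5: float
    ci_97_5: float


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (m, n) matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_corr_diff(
    x: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    n_boot: int = 100_000,
    rng: np.random.Generator | None = None,
    seed: Optional[int] = None,
    tail: str = "one",
) -> BootstrapResult:
    """Bootstrap test for corr(x, y1) - corr(x, y2).

    Subjects (joint rows of x, y1, y2) are resampled with replacement;
    the difference in correlations is recomputed per resample. The
    one-tailed p-value is the (+1-corrected) proportion of resamples
    whose difference falls on the opposite side of 0 from the observed
    difference; ``tail='two'`` doubles it (capped at 1). Degenerate
    resamples (a constant column) are redrawn and counted.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = x.size
    if not (y1.size == n and y2.size == n and n >= 4):
        raise ValueError("x, y1, y2 must have equal length >= 4")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if rng is None:
        rng = np.random.default_rng(seed)

    obs = float(np.corrcoef(x, y1)[0, 1] - np.corrcoef(x, y2)[0, 1])

    diffs = np.empty(n_boot)
    filled = 0
    n_redrawn = 0
    while filled < n_boot:
        m = n_boot - filled
        idx = rng.integers(0, n, size=(m, n))
        xr, y1r, y2r = x[idx], y1[idx], y2[idx]
        d = _pearson_rows(xr, y1r) - _pearson_rows(xr, y2r)
        ok = np.isfinite(d)
        k = int(ok.sum())
        diffs[filled : filled + k] = d[ok]
        filled += k
        n_redrawn += m - k

    if obs >= 0:
        extreme = int(np.sum(diffs <= 0.0))
    else:
        extreme = int(np.sum(diffs >= 0.0))
    p = (extreme + 1.0) / (n_boot + 1.0)
    if tail == "two":
        p = min(2.0 * p, 1.0)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(
        obs, float(p), tail, n_boot, n_redrawn, seed,
        float(diffs.mean()), float(diffs.std(ddof=1)), float(lo), float(hi),
    )
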