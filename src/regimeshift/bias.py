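"""Under/overreaction metrics and behavioral sensitivity slopes.

The Index of Overreaction compares a responder's belief revision with
the normative Bayesian revision on the same signal sequence:
``IO = dP_t - dP_t^B`` for ``t = 2..T``; positive means the responder
revised more than the Bayesian (overreaction), negative less
(underreaction).

The behavioral slope ``gamma`` summarizes sensitivity to a system
parameter: regress the subjectively weighted parameter value on its
objective level across the three levels. A Bayesian responder has
``gamma = 1``; a responder who reacts identically across systems
(complete neglect) has ``gamma = 0``. For diagnosticity the weighted
value is ``beta_j * ln(d_j)`` regressed on ``ln(d_j)``; for transition
probability it is ``alpha_i * q_i`` (the effective transition
probability) regressed on ``q_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import task
from .observers import SubjectParams, bayesian_posterior, prior_log_odds

__all__ = [
    "index_of_overreaction",
    "io_summary",
    "SlopeResult",
    "behavioral_slope",
    "neglect_position_tests",
    "exclude_outlier_slopes",
    "design_regressors",
    "handedness_code",
    "REGRESSOR_COLUMNS",
]


def index_of_overreaction(
    observed: np.ndarray, bayes: np.ndarray, t_min: int = 2
) -> np.ndarray:
    """Per-period IO for one trial: (P_t - P_{t-1}) - (P^B_t - P^B_{t-1}).

    Returned for t = ``t_min``..T (default 2..T, length T - 1). Setting
    ``t_min = 1`` prepends the first-period revision against the implied
    P_0 = 0 (the trial starts in the red regime with certainty).
    """
    observed = np.asarray(observed, dtype=float)
    bayes = np.asarray(bayes, dtype=float)
    if observed.shape != bayes.shape:
        raise ValueError("observed and Bayesian series must align")
    if t_min not in (1, 2):
        raise ValueError("t_min must be 1 or 2")
    if t_min == 1:
        observed = np.concatenate([[0.0], observed])
        bayes = np.concatenate([[0.0], bayes])
    return np.diff(observed) - np.diff(bayes)


def io_summary(estimates: pd.DataFrame, t_min: int = 2) -> pd.DataFrame:
    """Mean IO per subject and condition from a long estimates table.

    ``estimates`` follows the estimates.csv schema (subject_id, block,
    trial, q, d, period, signal, P, optionally missing). The Bayesian
    posterior is recomputed from each trial's signals. Periods are
    weighted equally within condition, then averaged per subject; group
    means are equal-weight means of subject means.
    """
    df = estimates.copy()
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)]
    recs = []
    for (sid, blk, trl), g in df.groupby(["subject_id", "block", "trial"], sort=True):
        g = g.sort_values("period")
        if len(g) < 2 or not np.array_equal(
            g["period"].to_numpy(), np.arange(1, len(g) + 1)
        ):
            continue  # incomplete trial: deltas undefined
        q, d = float(g["q"].iloc[0]), float(g["d"].iloc[0])
        pb = bayesian_posterior(g["signal"].to_numpy(), q, d)
        io = index_of_overreaction(g["P"].to_numpy(), pb, t_min=t_min)
        recs.append((sid, q, d, float(io.mean())))
    per_trial = pd.DataFrame(recs, columns=["subject_id", "q", "d", "mean_IO"])
    return (
        per_trial.groupby(["subject_id", "q", "d"], as_index=False)["mean_IO"]
        .mean()
    )


@dataclass
class SlopeResult:
    """Fitted sensitivity slope for one subject and parameter family."""

    subject_id: int
    family: str  # "q" or "d"
    gamma: float
    intercept: float
    included: bool = True


def behavioral_slope(
    params: SubjectParams,
    family: str,
    subject_id: int = 0,
    signal_class: int = 0,
) -> SlopeResult:
    """OLS slope of the subjectively weighted parameter on its level.

    family "d": regress beta_j ln(d_j) on ln(d_j). family "q": regress
    alpha_i q_i on q_i. Three points, intercept included.
    """
    if family == "d":
        w = params.beta[signal_class] if params.beta.ndim == 2 else params.beta
        x = np.log(np.asarray(params.d_levels, dtype=float))
        y = w * x
    elif family == "q":
        w = params.alpha[signal_class] if params.alpha.ndim == 2 else params.alpha
        x = np.asarray(params.q_levels, dtype=float)
        y = w * x
    else:
        raise ValueError("family must be 'q' or 'd'")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite weighted parameter values")
    slope, intercept = np.polyfit(x, y, 1)
    return SlopeResult(subject_id, family, float(slope), float(intercept))


def exclude_outlier_slopes(
    slopes: Sequence[SlopeResult], bounds: tuple[float, float] = (-0.5, 1.5)
) -> list[SlopeResult]:
    """Flag slopes outside ``bounds`` as excluded (never silently drop)."""
    lo, hi = bounds
    out = []
    for s in slopes:
        out.append(
            SlopeResult(s.subject_id, s.family, s.gamma, s.intercept,
                        included=bool(lo <= s.gamma <= hi))
        )
    return out


def neglect_position_tests(slopes: Sequence[SlopeResult]) -> pd.DataFrame:
    """One-sample two-tailed t-tests of gamma against 0, 1 and 0.5.

    0 is the complete-neglect boundary, 1 the Bayesian boundary, 0.5 the
    midpoint (negative midpoint t means closer to complete neglect).
    Only included slopes enter; requires at least two of them.
    """
    g = np.array([s.gamma for s in slopes if s.included])
    if g.size < 2:
        raise ValueError("need at least 2 included subjects")
    rows = []
    for name, ref in (("complete_neglect", 0.0), ("bayesian", 1.0), ("midpoint", 0.5)):
        if np.std(g) == 0.0:
            # degenerate cohort: t is 0 when the common value equals the
            # reference, infinite (p = 0) otherwise
            t = 0.0 if np.isclose(g[0], ref) else math.inf * np.sign(g[0] - ref)
            p = 1.0 if np.isclose(g[0], ref) else 0.0
        else:
            t, p = stats.ttest_1samp(g, ref)
        rows.append((name, ref, float(g.mean()), float(t), g.size - 1, float(p)))
    return pd.DataFrame(
        rows, columns=["reference", "value", "mean_gamma", "t", "df", "p"]
    )


_LEFT_DIGITS = {1, 2, 3, 4, 5}  # left-hand buttons; 6-9 and 0 are right


def handedness_code(P: float) -> int:
    """Action-handedness of the two-digit entry of ``P``.

    ``P`` must be expressible as a two-digit percentage (hundredths in
    [0, 0.99]). Both digits left-hand -> -1, mixed -> 0, both right -> +1.
    """
    cents = round(float(P) * 100)
    if not (0 <= cents <= 99) or abs(P * 100 - cents) > 1e-6:
        raise ValueError(
            f"estimate {P} not expressible as a two-digit entry (00-99)"
        )
    tens, ones = divmod(cents, 10)
    left = (tens in _LEFT_DIGITS) + (ones in _LEFT_DIGITS)
    return {2: -1, 1: 0, 0: 1}[left]


REGRESSOR_COLUMNS = [
    "subject_id",
    "block",
    "trial",
    "period",
    "P",
    "dP",
    "certainty",
    "signal_code",
    "evidence_strength",
    "intertemporal_prior",
    "handedness",
]


def design_regressors(
    estimates: pd.DataFrame, with_handedness: bool = False
) -> pd.DataFrame:
    """Per-period design-matrix quantities used in the neural analyses.

    Emits, aligned to the estimates table: the estimate ``P``; belief
    revision ``dP`` (NaN at t = 1); certainty ``|P - 0.5|``; the signal
    code s (+1 blue / change-consistent, -1 red); strength of change
    evidence ``s * ln(d)``; the intertemporal prior ``ln((1-(1-q)^t) /
    (1-q)^t)``; and optionally the action-handedness code of the
    two-digit entry.
    """
    recs = []
    for (sid, blk, trl), g in estimates.groupby(
        ["subject_id", "block", "trial"], sort=True
    ):
        g = g.sort_values("period")
        P = g["P"].to_numpy(dtype=float)
        q = float(g["q"].iloc[0])
        d = float(g["d"].iloc[0])
        t = g["period"].to_numpy(dtype=int)
        s = 1 - 2 * g["signal"].to_numpy(dtype=int)  # blue (0) -> +1, red (1) -> -1
        dP = np.concatenate([[np.nan], np.diff(P)])
        for i in range(len(g)):
            hand = handedness_code(P[i]) if with_handedness else pd.NA
            recs.append(
                (
                    sid, blk, trl, t[i], P[i], dP[i], abs(P[i] - 0.5),
                    int(s[i]), s[i] * np.log(d), prior_log_odds(q, int(t[i])), hand,
                )
            )
    return pd.DataFrame(recs, columns=REGRESSOR_COLUMNS)
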