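"""Bayesian and quasi-Bayesian (system-neglect) change-point observers.

The normative observer reports, after each period ``t`` of a trial, the
posterior probability that the latent regime has shifted to the absorbing
blue state. Its posterior odds factor into a prior-odds term driven only
by the transition probability ``q`` and a likelihood ratio that mixes,
over all disjoint possible shift times ``j = 1..t``, the diagnosticity
term ``d ** (t + 1 - j - 2 * sum(r_j..r_t))`` weighted by the conditional
shift-time probabilities ``q (1-q)**(j-1) / (1 - (1-q)**t)``. Here
``r_k`` is 1 for a red signal (evidence against a shift) and 0 for blue.

The system-neglect observer distorts this computation with per-level
weighting parameters: ``alpha`` multiplies ``q`` inside the prior odds
and ``beta`` multiplies the diagnosticity exponent. ``alpha = beta = 1``
recovers the Bayesian observer; ``alpha, beta`` falling with the level of
their system parameter is the behavioral signature of system neglect.
Signal-dependent variants select the (alpha, beta) pair by the current
period's signal class (blue = change-consistent, red = change-inconsistent).

The shift-time mixture weights always use the undistorted ``q``; only the
prior odds are distorted. ``distort_mixture_weights=True`` applies
``alpha * q`` inside the weights as well, as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import special

from .task import D_LEVELS, Q_LEVELS

__all__ = [
    "VARIANTS",
    "SubjectParams",
    "bayesian_posterior",
    "system_neglect_posterior",
    "signal_dependent_posterior",
    "posterior",
    "posterior_oracle",
    "prior_log_odds",
    "delta",
]

VARIANTS = (
    "bayes",
    "sn_original",
    "sn_sigdep_beta",
    "sn_sigdep_alpha",
    "sn_sigdep_alphabeta",
)

#: Which parameter families are doubled into (consistent, inconsistent)
#: sets under each variant.
_DOUBLED = {
    "bayes": (False, False),
    "sn_original": (False, False),
    "sn_sigdep_beta": (False, True),
    "sn_sigdep_alpha": (True, False),
    "sn_sigdep_alphabeta": (True, True),
}


@dataclass
class SubjectParams:
    """Weighting parameters of one (real or synthetic) subject.

    ``alpha`` holds the transition-probability weights keyed to the three
    q-levels and ``beta`` the diagnosticity weights keyed to the three
    d-levels. Shared families have shape ``(3,)``; families that are
    signal-dependent under ``variant`` have shape ``(2, 3)`` with row 0
    the change-consistent (blue-signal) set and row 1 the
    change-inconsistent (red-signal) set.
    """

    variant: str
    alpha: np.ndarray
    beta: np.ndarray
    sigma_noise: Optional[float] = None
    q_levels: tuple[float, ...] = Q_LEVELS
    d_levels: tuple[float, ...] = D_LEVELS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        a_dbl, b_dbl = _DOUBLED[self.variant]
        self.alpha = self._coerce(self.alpha, a_dbl, "alpha")
        self.beta = self._coerce(self.beta, b_dbl, "beta")
        if self.variant == "bayes":
            if not (np.all(self.alpha == 1.0) and np.all(self.beta == 1.0)):
                raise ValueError("bayes variant requires alpha = beta = 1")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be nonnegative")
        aq = self.alpha * np.asarray(self.q_levels)
        if np.any(aq >= 1.0):
            raise ValueError("alpha * q must be < 1 at every level")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    def _coerce(self, arr, doubled: bool, name: str) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(arr, dtype=float))
        n = len(self.q_levels) if name == "alpha" else len(self.d_levels)
        want = (2, n) if doubled else (n,)
        if arr.shape == (n,) and doubled:
            arr = np.vstack([arr, arr])  # degenerate doubling: one shared set
        if arr.shape != want:
            raise ValueError(
                f"{name} must have shape {want} for variant {self.variant!r}, "
                f"got {arr.shape}"
            )
        return arr

    @property
    def n_params(self) -> int:
        """Number of free weighting parameters (6, 9 or 12)."""
        if self.variant == "bayes":
            return 0
        return self.alpha.size + self.beta.size

    def alpha_at(self, q: float, signal: int = 0) -> float:
        """Alpha for q-level ``q``; ``signal`` selects the sigdep set."""
        i = _level_index(q, self.q_levels, "q")
        return float(self.alpha[signal, i] if self.alpha.ndim == 2 else self.alpha[i])

    def beta_at(self, d: float, signal: int = 0) -> float:
        i = _level_index(d, self.d_levels, "d")
        return float(self.beta[signal, i] if self.beta.ndim == 2 else self.beta[i])

    @classmethod
    def bayes(cls) -> "SubjectParams":
        return cls("bayes", np.ones(3), np.ones(3))


def _level_index(value: float, levels: tuple[float, ...], name: str) -> int:
    for i, lv in enumerate(levels):
        if np.isclose(value, lv):
            return i
    raise KeyError(f"no {name}-level matching {value} among {levels}")


def _check_qd(q: float, d: float) -> None:
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be in [0, 1], got {q}")
    if d < 1.0:
        raise ValueError(f"d must be >= 1, got {d}")


def _posterior_core(
    r: np.ndarray,
    q: float,
    d: float,
    alpha_t: np.ndarray,
    beta_t: np.ndarray,
    distort_mixture_weights: bool = False,
) -> np.ndarray:
    """Evaluate the (possibly distorted) posterior for all t of one trial.

    ``alpha_t``/``beta_t`` give the weighting applied when computing the
    period-``t`` estimate (length-T vectors; constant for non-sigdep use).
    Works on odds in linear space: with |beta| <= 10 and T = 10 the
    diagnosticity term stays within float64 range (9**100 ~ 2.7e95).
    """
    r = np.asarray(r, dtype=float)
    T = r.size
    t_idx = np.arange(1, T + 1, dtype=float)

    if q == 0.0:
        return np.zeros(T)

    aq = np.clip(alpha_t * q, None, 1.0 - 1e-12)
    # log prior odds: log((1-aq)^-t - 1) = log(expm1(x)), x = -t log1p(-aq),
    # computed stably for both tiny and near-one aq
    x = -t_idx * np.log1p(-aq)
    with np.errstate(divide="ignore"):
        log_prior_odds = np.where(
            x < 30.0,
            np.log(np.expm1(np.minimum(x, 30.0))),
            x + np.log1p(-np.exp(-np.maximum(x, 1.0))),
        )

    # exponent matrix e[t-1, j-1] = t + 1 - j - 2 * sum_{k=j..t} r_k, j <= t
    S = np.concatenate([[0.0], np.cumsum(r)])  # S[k] = r_1 + ... + r_k
    tt = t_idx[:, None]
    jj = t_idx[None, :]
    tail = S[1:, None] - S[None, :-1]  # tail[t-1, j-1] = sum r_j..r_t
    expo = tt + 1.0 - jj - 2.0 * tail
    mask = jj <= tt

    qw = aq if distort_mixture_weights else np.full(T, q)
    # log weights: log qw + (j-1) log1p(-qw) - log(1 - (1-qw)^t), all in
    # log space so tiny qw keeps full precision
    qw_col = qw[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = tt * np.log1p(-qw_col)  # <= 0
        log_norm = np.log(-np.expm1(y))
        geo = (jj - 1.0) * np.log1p(-qw_col)
        geo = np.where(jj == 1.0, 0.0, geo)  # avoid 0 * -inf at qw = 1
        log_w = np.log(qw_col) + geo - log_norm

    # mixture via logsumexp: beta * expo * ln d can exceed the float64
    # exponent range for extreme (d, beta)
    with np.errstate(invalid="ignore"):
        log_terms = np.where(mask, log_w + beta_t[:, None] * expo * np.log(d), -np.inf)
        log_mix = special.logsumexp(log_terms, axis=1)
    return special.expit(log_prior_odds + log_mix)


def bayesian_posterior(r: np.ndarray, q: float, d: float) -> np.ndarray:
    """Normative posterior probability of a shift, P_t^B, for t = 1..T."""
    _check_qd(q, d)
    r = np.asarray(r, dtype=float)
    ones = np.ones(r.size)
    return _posterior_core(r, q, d, ones, ones)


def system_neglect_posterior(
    r: np.ndarray,
    q: float,
    d: float,
    params: SubjectParams,
    distort_mixture_weights: bool = False,
) -> np.ndarray:
    """System-neglect posterior with level-selected alpha, beta weights."""
    _check_qd(q, d)
    r = np.asarray(r, dtype=float)
    if params.alpha.ndim == 2 or params.beta.ndim == 2:
        return signal_dependent_posterior(
            r, q, d, params, distort_mixture_weights=distort_mixture_weights
        )
    a = params.alpha_at(q)
    b = params.beta_at(d)
    T = r.size
    return _posterior_core(
        r, q, d, np.full(T, a), np.full(T, b), distort_mixture_weights
    )


def signal_dependent_posterior(
    r: np.ndarray,
    q: float,
    d: float,
    params: SubjectParams,
    distort_mixture_weights: bool = False,
) -> np.ndarray:
    """Posterior with (alpha, beta) selected by the current period's signal.

    Blue (r_t = 0) selects the change-consistent set, red (r_t = 1) the
    change-inconsistent set; the whole period-t computation then uses
    that pair.
    """
    _check_qd(q, d)
    r = np.asarray(r, dtype=float)
    sig = r.astype(int)  # 0 = blue -> consistent row, 1 = red -> inconsistent row
    a2 = params.alpha if params.alpha.ndim == 2 else np.vstack([params.alpha] * 2)
    b2 = params.beta if params.beta.ndim == 2 else np.vstack([params.beta] * 2)
    ai = _level_index(q, params.q_levels, "q")
    bi = _level_index(d, params.d_levels, "d")
    alpha_t = a2[sig, ai]
    beta_t = b2[sig, bi]
    return _posterior_core(r, q, d, alpha_t, beta_t, distort_mixture_weights)


def posterior(
    r: np.ndarray, q: float, d: float, params: SubjectParams, **kw
) -> np.ndarray:
    """Dispatch on ``params.variant``."""
    if params.variant == "bayes":
        return bayesian_posterior(r, q, d)
    return system_neglect_posterior(r, q, d, params, **kw)


# ---------------------------------------------------------------------------
# independent verification oracle

def _enumeration_posterior(r: np.ndarray, q: float, d: float) -> np.ndarray:
    """Posterior by explicit enumeration over shift times.

    For each t, sums the exact joint probability of the observed history
    under every disjoint hypothesis (shift at j = 1..t, or no shift yet)
    and normalizes. Independent of the closed-form mixture algebra.
    """
    r = np.asarray(r, dtype=int)
    T = r.size
    p_dom = d / (d + 1.0)
    # emission prob of signal r_k under red regime / blue regime
    p_red = np.where(r == 1, p_dom, 1.0 - p_dom)
    p_blue = np.where(r == 0, p_dom, 1.0 - p_dom)
    out = np.empty(T)
    for t in range(1, T + 1):
        num = 0.0
        for j in range(1, t + 1):  # shift immediately before period j
            pj = q * (1.0 - q) ** (j - 1)
            lik = np.prod(p_red[: j - 1]) * np.prod(p_blue[j - 1 : t])
            num += pj * lik
        p_no = (1.0 - q) ** t * np.prod(p_red[:t])
        out[t - 1] = num / (num + p_no) if (num + p_no) > 0 else 0.0
    return out


def _filter_posterior(r: np.ndarray, q: float, d: float) -> np.ndarray:
    """Posterior by a recursive two-state filter with absorbing blue state."""
    r = np.asarray(r, dtype=int)
    p_dom = d / (d + 1.0)
    post = 0.0
    out = np.empty(r.size)
    for t, rt in enumerate(r):
        prior = post + (1.0 - post) * q
        l_blue = p_dom if rt == 0 else 1.0 - p_dom
        l_red = p_dom if rt == 1 else 1.0 - p_dom
        num = prior * l_blue
        den = num + (1.0 - prior) * l_red
        post = num / den if den > 0 else 0.0
        out[t] = post
    return out


def posterior_oracle(
    r: np.ndarray, q: float, d: float, atol: float = 1e-10
) -> np.ndarray:
    """Posterior via two independent routes, cross-checked against the
    closed form; raises if any pair disagrees beyond ``atol``."""
    _check_qd(q, d)
    enum = _enumeration_posterior(r, q, d)
    filt = _filter_posterior(r, q, d)
    closed = bayesian_posterior(r, q, d)
    for name, other in (("filter", filt), ("closed-form", closed)):
        err = np.max(np.abs(enum - other))
        if err > atol:
            raise AssertionError(
                f"oracle disagreement enumeration vs {name}: max|diff| = {err:.3g}"
            )
    return enum


# ---------------------------------------------------------------------------
# derived regressor quantities

def prior_log_odds(q: float, t: int | np.ndarray) -> float | np.ndarray:
    """Intertemporal prior ln((1 - (1-q)^t) / (1-q)^t); increasing in t."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in the open interval (0, 1), got {q}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("t must be >= 1")
    surv = (1.0 - q) ** t
    out = np.log((1.0 - surv) / surv)
    return float(out) if out.ndim == 0 else out


def delta(P: np.ndarray) -> np.ndarray:
    """Belief revision dP_t = P_t - P_{t-1} for t = 2..T (length T-1)."""
    P = np.asarray(P, dtype=float)
    return np.diff(P)
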