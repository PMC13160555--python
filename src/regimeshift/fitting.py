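"""Per-subject estimation of the observer-model family.

Fits are nonlinear least squares on the probability estimates: the
fitted parameters minimize ``sum_t (P_t_obs - P_t_model)**2`` over all
non-missing periods of all trials, with box constraints
``alpha_i in [0, (1 - eps) / q_i]`` and ``beta_j in [-10, 10]`` and a
multi-start policy (all-ones, the group means of the human cohort, and
three random draws; best RSS wins, ties broken by start order).

The Gaussian maximum-likelihood path reuses the same optimum: for
homoscedastic Gaussian noise the RSS minimizer is exactly the MLE of
the model parameters and ``sigma_hat = sqrt(RSS / n)`` is the MLE of
the noise SD (profile likelihood), so no second optimization is run.

AIC uses ``k = n_model_params + 1`` (the +1 for the noise SD) in both
paths; with the Gaussian constant ``n (1 + ln 2pi)`` included the two
paths give identical numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import task
from .observers import VARIANTS, SubjectParams, _DOUBLED
from .population import (
    ALPHA_GROUP_MEANS,
    BETA_GROUP_MEANS,
    HET_BIN_SDS,
    NoiseModel,
    PopulationSpec,
    sample_subject_params,
    simulate_estimates,
)

__all__ = [
    "FitResult",
    "RecoveryReport",
    "fit_nls",
    "fit_mle_noise",
    "fit_cohort",
    "aic",
    "compare_models",
    "parameter_recovery",
    "residual_sd_by_probability_bin",
    "DEFAULT_NOISE_LEVELS",
]

DEFAULT_NOISE_LEVELS: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.3)
_BETA_BOUNDS = (-10.0, 10.0)
_ALPHA_EPS = 1e-6


@dataclass
class FitResult:
    """Outcome of one subject-level fit."""

    variant: str
    params: Optional[SubjectParams]
    rss: float
    n_obs: int
    residuals: np.ndarray
    log_likelihood: Optional[float] = None
    sigma_noise_hat: Optional[float] = None
    aic: Optional[float] = None
    converged: bool = True
    path: str = "nls"
    n_starts: int = 0
    best_start: int = -1
    message: str = ""
    aic_convention: str = "k = n_model_params + 1 (noise SD); Gaussian constant included"

    @property
    def theta(self) -> np.ndarray:
        return _pack(self.params)


class _PredictCache:
    """Flattened per-observation structures for fast model evaluation.

    One row per non-missing period; one term per (row, candidate shift
    time j <= t). Model evaluation is then a handful of vectorized
    operations regardless of the number of trials.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        q_levels: Sequence[float] = task.Q_LEVELS,
        d_levels: Sequence[float] = task.D_LEVELS,
    ):
        need = {"block", "trial", "q", "d", "period", "signal", "P"}
        missing_cols = need - set(data.columns)
        if missing_cols:
            raise ValueError(f"fit data missing columns {sorted(missing_cols)}")
        df = data.copy()
        if "missing" not in df.columns:
            df["missing"] = False
        df = df.sort_values(["block", "trial", "period"], kind="stable")

        self.q_levels = np.asarray(q_levels, dtype=float)
        self.d_levels = np.asarray(d_levels, dtype=float)

        rows_t, rows_q, rows_d, rows_qi, rows_di, rows_sig, rows_obs = (
            [] for _ in range(7)
        )
        term_row, term_w, term_e = [], [], []
        for (_, _), g in df.groupby(["block", "trial"], sort=True):
            g = g.sort_values("period")
            q = float(g["q"].iloc[0])
            d = float(g["d"].iloc[0])
            qi = int(np.argmin(np.abs(self.q_levels - q)))
            di = int(np.argmin(np.abs(self.d_levels - d)))
            if not (
                np.isclose(self.q_levels[qi], q) and np.isclose(self.d_levels[di], d)
            ):
                raise ValueError(f"condition (q={q}, d={d}) not on the level grid")
            r = g["signal"].to_numpy(dtype=float)
            S = np.concatenate([[0.0], np.cumsum(r)])
            keep = ~g["missing"].to_numpy(dtype=bool)
            periods = g["period"].to_numpy(dtype=int)
            obs = g["P"].to_numpy(dtype=float)
            for pos, t in enumerate(periods):
                if not keep[pos]:
                    continue
                row = len(rows_t)
                rows_t.append(float(t))
                rows_q.append(q)
                rows_d.append(d)
                rows_qi.append(qi)
                rows_di.append(di)
                rows_sig.append(int(r[pos]))
                rows_obs.append(obs[pos])
                j = np.arange(1, t + 1, dtype=float)
                w = q * (1.0 - q) ** (j - 1.0)
                w /= 1.0 - (1.0 - q) ** t if q > 0 else 1.0
                e = t + 1.0 - j - 2.0 * (S[t] - S[j.astype(int) - 1])
                term_row.extend([row] * len(j))
                term_w.extend(w)
                term_e.extend(e)

        self.t = np.asarray(rows_t)
        self.q = np.asarray(rows_q)
        self.qi = np.asarray(rows_qi, dtype=int)
        self.di = np.asarray(rows_di, dtype=int)
        self.sig = np.asarray(rows_sig, dtype=int)
        self.obs = np.asarray(rows_obs)
        self.n_obs = len(self.obs)
        self.term_row = np.asarray(term_row, dtype=int)
        self.term_w = np.asarray(term_w)
        self.term_logd_e = np.asarray(term_e) * np.log(np.asarray(rows_d))[self.term_row]

    def predict(self, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
        a2 = np.atleast_2d(alpha)
        b2 = np.atleast_2d(beta)
        a_cls = self.sig if a2.shape[0] == 2 else np.zeros(self.n_obs, dtype=int)
        b_cls = self.sig if b2.shape[0] == 2 else np.zeros(self.n_obs, dtype=int)
        a_row = a2[a_cls, self.qi]
        b_row = b2[b_cls, self.di]
        aq = np.clip(a_row * self.q, None, 1.0 - 1e-12)
        prior = (1.0 - aq) ** (-self.t) - 1.0
        term_val = self.term_w * np.exp(b_row[self.term_row] * self.term_logd_e)
        lik = np.bincount(self.term_row, weights=term_val, minlength=self.n_obs)
        odds = prior * lik
        return odds / (1.0 + odds)


def _shapes(variant: str) -> tuple[tuple[int, ...], tuple[int, ...]]:
    a_dbl, b_dbl = _DOUBLED[variant]
    return ((2, 3) if a_dbl else (3,)), ((2, 3) if b_dbl else (3,))


def _pack(params: SubjectParams) -> np.ndarray:
    return np.concatenate([params.alpha.ravel(), params.beta.ravel()])


def _unpack(theta: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    a_shape, b_shape = _shapes(variant)
    na = int(np.prod(a_shape))
    return theta[:na].reshape(a_shape), theta[na:].reshape(b_shape)


def _bounds(variant: str, q_levels: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a_shape, b_shape = _shapes(variant)
    a_ub = np.broadcast_to((1.0 - _ALPHA_EPS) / np.asarray(q_levels), a_shape).ravel()
    lo = np.concatenate([np.zeros(a_ub.size), np.full(int(np.prod(b_shape)), _BETA_BOUNDS[0])])
    hi = np.concatenate([a_ub, np.full(int(np.prod(b_shape)), _BETA_BOUNDS[1])])
    return lo, hi


def _starts(
    variant: str, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator,
    n_random: int = 3,
) -> list[np.ndarray]:
    a_shape, b_shape = _shapes(variant)
    na = int(np.prod(a_shape))
    ones = np.ones(na + int(np.prod(b_shape)))
    means = np.concatenate(
        [
            np.broadcast_to(ALPHA_GROUP_MEANS, a_shape).ravel(),
            np.broadcast_to(BETA_GROUP_MEANS, b_shape).ravel(),
        ]
    )
    starts = [ones, np.clip(means, lo, hi)]
    for _ in range(n_random):
        a = rng.uniform(0.1, np.minimum(5.0, 0.95 * hi[:na]))
        b = rng.uniform(0.0, 2.5, size=len(ones) - na)
        starts.append(np.concatenate([a, b]))
    return starts


def fit_nls(
    data: pd.DataFrame,
    variant: str = "sn_original",
    q_levels: Sequence[float] = task.Q_LEVELS,
    d_levels: Sequence[float] = task.D_LEVELS,
    rng: np.random.Generator | None = None,
    n_random_starts: int = 3,
    ftol: float = 1e-10,
) -> FitResult:
    """Nonlinear least-squares fit of one subject's estimates.

    ``data`` is a long-format frame with columns block, trial, q, d,
    period, signal (1 = red), P and optionally missing. Rows flagged
    missing are dropped; ``n_obs`` counts the rest.
    """
    if variant not in VARIANTS or variant == "bayes":
        raise ValueError(f"variant must be a fittable model, got {variant!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    cache = _PredictCache(data, q_levels, d_levels)
    if cache.n_obs < 1:
        raise ValueError("no non-missing observations to fit")
    lo, hi = _bounds(variant, q_levels)

    def resid(theta: np.ndarray) -> np.ndarray:
        a, b = _unpack(theta, variant)
        return cache.predict(a, b) - cache.obs

    best: Optional[optimize.OptimizeResult] = None
    best_start = -1
    starts = _starts(variant, lo, hi, rng, n_random_starts)
    messages = []
    for i, x0 in enumerate(starts):
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), method="trf", ftol=ftol, xtol=1e-12
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            messages.append(f"start {i}: {exc}")
            continue
        if not sol.success:
            messages.append(f"start {i}: {sol.message}")
            continue
        if best is None or 2.0 * sol.cost < best_rss - 1e-14:
            best, best_start, best_rss = sol, i, 2.0 * sol.cost

    if best is None:
        return FitResult(
            variant, None, math.inf, cache.n_obs, np.array([]),
            converged=False, n_starts=len(starts), message="; ".join(messages),
        )
    a, b = _unpack(best.x, variant)
    params = SubjectParams(
        variant, a, b, q_levels=tuple(q_levels), d_levels=tuple(d_levels)
    )
    rss = float(2.0 * best.cost)
    res = FitResult(
        variant, params, rss, cache.n_obs, best.fun.copy(),
        converged=True, n_starts=len(starts), best_start=best_start,
    )
    res.aic = aic(res)
    return res


def fit_mle_noise(
    data: pd.DataFrame, variant: str = "sn_original", **kw
) -> FitResult:
    """Gaussian MLE of model parameters and the noise SD.

    Exact via the profile likelihood: the RSS minimizer maximizes the
    Gaussian likelihood and ``sigma_hat = max(sqrt(RSS/n), 1e-4)``.
    """
    res = fit_nls(data, variant, **kw)
    if not res.converged:
        return res
    n = res.n_obs
    sigma = max(math.sqrt(res.rss / n), 1e-4)
    res.path = "mle"
    res.sigma_noise_hat = sigma
    res.log_likelihood = float(
        -0.5 * n * math.log(2.0 * math.pi * sigma**2) - res.rss / (2.0 * sigma**2)
    )
    if res.params is not None:
        res.params.sigma_noise = sigma
    res.aic = aic(res)
    return res


def aic(fit: FitResult) -> float:
    """Akaike information criterion; lower is better.

    MLE path: ``2 k - 2 logL``. NLS path: Gaussian profile form
    ``n ln(RSS/n) + n (1 + ln 2pi) + 2 k``. Both use
    ``k = n_model_params + 1`` and agree numerically.
    """
    if not fit.converged or fit.params is None:
        raise ValueError("AIC undefined for an unconverged fit")
    k = fit.params.n_params + 1
    if fit.log_likelihood is not None:
        return 2.0 * k - 2.0 * fit.log_likelihood
    n = fit.n_obs
    return n * math.log(fit.rss / n) + n * (1.0 + math.log(2.0 * math.pi)) + 2.0 * k


def compare_models(
    fits: dict[str, Sequence[FitResult]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level AIC comparison across model variants.

    ``fits`` maps variant -> per-subject FitResults (same subjects, same
    order, across variants). Returns (summary, pairwise): group-mean AIC
    per variant, and paired two-tailed t-tests on per-subject AIC between
    every variant pair. Identical AICs give t = 0, p = 1 ("no
    difference").
    """
    n_sub = {v: len(f) for v, f in fits.items()}
    if len(set(n_sub.values())) != 1:
        raise ValueError(f"mismatched subject counts across variants: {n_sub}")
    aics = {v: np.array([aic(f) for f in fs]) for v, fs in fits.items()}
    summary = pd.DataFrame(
        {
            "variant": list(aics),
            "mean_aic": [a.mean() for a in aics.values()],
            "sem_aic": [a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan
                        for a in aics.values()],
            "n_subjects": [len(a) for a in aics.values()],
        }
    ).sort_values("mean_aic", ignore_index=True)
    rows = []
    variants = list(aics)
    for i, v1 in enumerate(variants):
        for v2 in variants[i + 1 :]:
            diff = aics[v1] - aics[v2]
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(aics[v1], aics[v2])
            rows.append((v1, v2, float(diff.mean()), float(t), float(p)))
    pairwise = pd.DataFrame(
        rows, columns=["variant_1", "variant_2", "mean_delta_aic", "t", "p"]
    )
    return summary, pairwise


def fit_cohort(
    estimates: pd.DataFrame,
    variant: str = "sn_original",
    rng: np.random.Generator | None = None,
    **kw,
) -> dict[int, FitResult]:
    """Fit every subject in a long-format estimates table (estimates.csv
    schema); returns subject_id -> FitResult."""
    rng = np.random.default_rng(0) if rng is None else rng
    out = {}
    for sid, g in estimates.groupby("subject_id", sort=True):
        out[int(sid)] = fit_nls(g, variant, rng=rng, **kw)
    return out


def fits_to_frame(fits: dict[int, FitResult]) -> pd.DataFrame:
    """Tidy fits table (fits.csv schema)."""
    recs = []
    for sid, f in fits.items():
        if f.params is None:
            continue
        for fam, arr in (("alpha", f.params.alpha), ("beta", f.params.beta)):
            arr2 = np.atleast_2d(arr)
            classes = ["shared"] if arr2.shape[0] == 1 else ["consistent", "inconsistent"]
            for ci, cname in enumerate(classes):
                for lv in range(arr2.shape[1]):
                    recs.append((sid, f.variant, fam, lv + 1, cname, arr2[ci, lv]))
    return pd.DataFrame(
        recs,
        columns=["subject_id", "variant", "parameter", "level", "signal_class", "estimate"],
    )


# ---------------------------------------------------------------------------
# parameter recovery

@dataclass
class RecoveryReport:
    """Truth-vs-estimate correlations per noise level.

    ``r_alpha`` / ``r_beta`` pool truth-estimate pairs across subjects
    and the three levels of the family (3 * n_subjects pairs);
    ``r_per_level`` keeps the per-level breakdown. ``scatter`` stores the
    pooled (true, estimated) arrays per noise level for plotting.
    """

    noise_levels: tuple[float, ...]
    r_alpha: dict[float, float]
    r_beta: dict[float, float]
    r_per_level: dict[float, dict[str, list[float]]]
    scatter: dict[float, dict[str, np.ndarray]]
    n_subjects: int
    n_blocks: int
    seed: Optional[int]
    noise_kind: str
    excluded: list = field(default_factory=list)

    @property
    def min_r_alpha(self) -> float:
        return min(self.r_alpha.values())

    @property
    def min_r_beta(self) -> float:
        return min(self.r_beta.values())

    def to_dict(self) -> dict:
        return {
            "noise_levels": list(self.noise_levels),
            "r_alpha": {str(k): v for k, v in self.r_alpha.items()},
            "r_beta": {str(k): v for k, v in self.r_beta.items()},
            "r_per_level": {str(k): v for k, v in self.r_per_level.items()},
            "min_r_alpha": self.min_r_alpha,
            "min_r_beta": self.min_r_beta,
            "n_subjects": self.n_subjects,
            "n_blocks": self.n_blocks,
            "seed": self.seed,
            "noise_kind": self.noise_kind,
            "excluded": self.excluded,
        }


def parameter_recovery(
    spec: PopulationSpec,
    noise_levels: Sequence[float] = DEFAULT_NOISE_LEVELS,
    rng: np.random.Generator | None = None,
    seed: Optional[int] = None,
    n_blocks: int = 11,
    T: int = 10,
    heteroscedastic: bool = False,
    bin_sds: Sequence[float] = HET_BIN_SDS,
    n_random_starts: int = 3,
) -> RecoveryReport:
    """Simulate-and-refit parameter recovery for the system-neglect model.

    For each synthetic subject: draw true (alpha, beta) from ``spec``,
    generate a fresh ``n_blocks``-block design and signal sequences,
    compute the model posteriors, then for each noise level add Gaussian
    noise (homoscedastic sigma, or the bin-SD profile rescaled so its
    mean equals sigma when ``heteroscedastic``), refit, and correlate
    truth with estimates pooled across subjects and levels.
    """
    if not all(0.0 < s < 1.0 for s in noise_levels):
        raise ValueError("noise levels must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)

    subjects = []
    for sid in range(1, spec.n_subjects + 1):
        p = sample_subject_params(spec, rng)
        des = task.generate_design(n_blocks, rng=rng)
        seqs = task.generate_trials(des, T=T, rng=rng)
        base = simulate_estimates(
            p, des, seqs, NoiseModel.homoscedastic(0.0), rng, subject_id=sid
        )
        subjects.append((sid, p, base))

    profile = NoiseModel.heteroscedastic(bin_sds) if heteroscedastic else None
    r_alpha, r_beta, r_lvl, scatter = {}, {}, {}, {}
    excluded = []
    for sig in noise_levels:
        noise = (
            profile.scaled_to(sig) if profile is not None
            else NoiseModel.homoscedastic(sig)
        )
        ta, ea, tb, eb = [], [], [], []
        for sid, p, base in subjects:
            data = base.copy()
            sd = noise.sigma_for(data["P_model"].to_numpy())
            data["P"] = np.clip(
                data["P_model"].to_numpy()
                + rng.standard_normal(len(data)) * sd,
                0.0, 1.0,
            )
            fit = fit_nls(
                data, "sn_original",
                q_levels=spec.q_levels, d_levels=spec.d_levels,
                rng=rng, n_random_starts=n_random_starts,
            )
            if not fit.converged:
                excluded.append({"sigma": sig, "subject": sid, "reason": fit.message})
                continue
            ta.append(p.alpha)
            ea.append(fit.params.alpha)
            tb.append(p.beta)
            eb.append(fit.params.beta)
        ta, ea = np.concatenate(ta).reshape(-1, 3), np.concatenate(ea).reshape(-1, 3)
        tb, eb = np.concatenate(tb).reshape(-1, 3), np.concatenate(eb).reshape(-1, 3)
        r_alpha[sig] = float(stats.pearsonr(ta.ravel(), ea.ravel())[0])
        r_beta[sig] = float(stats.pearsonr(tb.ravel(), eb.ravel())[0])
        r_lvl[sig] = {
            "alpha": [float(stats.pearsonr(ta[:, i], ea[:, i])[0]) for i in range(3)],
            "beta": [float(stats.pearsonr(tb[:, i], eb[:, i])[0]) for i in range(3)],
        }
        scatter[sig] = {
            "alpha_true": ta.ravel(), "alpha_est": ea.ravel(),
            "beta_true": tb.ravel(), "beta_est": eb.ravel(),
        }
    return RecoveryReport(
        tuple(noise_levels), r_alpha, r_beta, r_lvl, scatter,
        spec.n_subjects, n_blocks, seed,
        "heteroscedastic" if heteroscedastic else "homoscedastic", excluded,
    )


def residual_sd_by_probability_bin(
    observed: np.ndarray,
    model: np.ndarray,
    index_by: str = "model",
) -> tuple[np.ndarray, np.ndarray]:
    """Residual SD in five probability bins [0,.2), ..., [.8,1].

    Bins are indexed by the model probability by default (``index_by =
    'observed'`` switches). Returns (sds, counts); empty bins give NaN.
    """
    observed = np.asarray(observed, dtype=float)
    model = np.asarray(model, dtype=float)
    if observed.shape != model.shape:
        raise ValueError("observed and model must align")
    key = model if index_by == "model" else observed
    if index_by not in ("model", "observed"):
        raise ValueError("index_by must be 'model' or 'observed'")
    idx = np.clip((key * 5).astype(int), 0, 4)
    resid = observed - model
    sds = np.full(5, np.nan)
    counts = np.zeros(5, dtype=int)
    for b in range(5):
        sel = resid[idx == b]
        counts[b] = sel.size
        if sel.size >= 2:
            sds[b] = sel.std(ddof=1)
    return sds, counts
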