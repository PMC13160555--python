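"""Synthetic subject populations for the regime-shift task.

Generates cohorts of simulated subjects whose probability estimates have
the statistical structure the downstream analyses assume: per-subject
system-neglect weighting parameters drawn from a log-normal population
centered on the group means reported for the human cohort, model-implied
posteriors on freshly generated stimulus sequences, and additive Gaussian
response noise (optionally heteroscedastic by probability bin, optionally
quantized to the two-digit button-entry grid).

The population distribution is a modeling choice of this package: values
are log-normal with the *mean* anchored at the group-level parameter
means, a shared subject-level log-scale factor inducing positive
within-family correlation across levels, and independence between the
alpha and beta families (the human data showed within-family but not
cross-family correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import task
from .observers import SubjectParams, posterior
from .task import TrialCondition, TrialSequence

__all__ = [
    "ALPHA_GROUP_MEANS",
    "BETA_GROUP_MEANS",
    "HET_BIN_SDS",
    "NoiseModel",
    "PopulationSpec",
    "SyntheticDataset",
    "sample_subject_params",
    "simulate_estimates",
    "simulate_missing",
    "simulate_population",
]

#: Group-mean transition-probability weights for q = (0.01, 0.05, 0.1).
ALPHA_GROUP_MEANS: tuple[float, ...] = (3.69, 1.04, 0.65)
#: Group-mean diagnosticity weights for d = (1.5, 3, 9).
BETA_GROUP_MEANS: tuple[float, ...] = (1.69, 0.77, 0.57)
#: Empirical residual SDs in the five probability bins [0,.2),...,[.8,1].
HET_BIN_SDS: tuple[float, ...] = (0.1015, 0.1296, 0.1987, 0.1929, 0.2061)

ESTIMATES_COLUMNS = [
    "subject_id",
    "block",
    "trial",
    "q",
    "d",
    "period",
    "signal",
    "P_model",
    "P",
    "missing",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian response noise, constant or probability-binned.

    ``homoscedastic``: one SD for every period. ``heteroscedastic``: the
    SD of a period is taken from ``bin_sds`` indexed by the noiseless
    model probability (five bins of width 0.2 over [0, 1]).
    """

    kind: str
    sigma: float = 0.0
    bin_sds: tuple[float, ...] = HET_BIN_SDS

    def __post_init__(self) -> None:
        if self.kind not in ("homoscedastic", "heteroscedastic"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "heteroscedastic" and len(self.bin_sds) != 5:
            raise ValueError("heteroscedastic noise needs exactly 5 bin SDs")

    @classmethod
    def homoscedastic(cls, sigma: float) -> "NoiseModel":
        return cls("homoscedastic", sigma=float(sigma))

    @classmethod
    def heteroscedastic(cls, bin_sds: Sequence[float] = HET_BIN_SDS) -> "NoiseModel":
        return cls("heteroscedastic", bin_sds=tuple(float(s) for s in bin_sds))

    def scaled_to(self, mean_sigma: float) -> "NoiseModel":
        """Rescale the bin-SD profile so its mean equals ``mean_sigma``."""
        if self.kind == "homoscedastic":
            return NoiseModel.homoscedastic(mean_sigma)
        f = mean_sigma / np.mean(self.bin_sds)
        return NoiseModel.heteroscedastic(tuple(f * s for s in self.bin_sds))

    def sigma_for(self, p_model: np.ndarray) -> np.ndarray:
        p_model = np.asarray(p_model, dtype=float)
        if self.kind == "homoscedastic":
            return np.full(p_model.shape, self.sigma)
        idx = np.clip((p_model * 5).astype(int), 0, 4)
        return np.asarray(self.bin_sds)[idx]


@dataclass
class PopulationSpec:
    """Between-subject distribution and response-noise settings."""

    alpha_mean: tuple[float, ...] = ALPHA_GROUP_MEANS
    beta_mean: tuple[float, ...] = BETA_GROUP_MEANS
    log_sd: float = 0.35
    within_family_corr: float = 0.5
    noise: NoiseModel = field(default_factory=lambda: NoiseModel.homoscedastic(0.1))
    quantize: bool = False
    n_subjects: int = 30
    q_levels: tuple[float, ...] = task.Q_LEVELS
    d_levels: tuple[float, ...] = task.D_LEVELS

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd (dispersion) must be >= 0")
        if not (0.0 <= self.within_family_corr <= 1.0):
            raise ValueError("within_family_corr must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _draw_family(
    means: np.ndarray, s: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """One subject's log-normal level values with shared-factor correlation.

    log value_i = log mean_i - s^2/2 + sqrt(rho) u + sqrt(1-rho) eps_i,
    so E[value_i] = mean_i and corr(log v_i, log v_j) = rho.
    """
    u = rng.standard_normal()
    eps = rng.standard_normal(means.size)
    z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps
    return means * np.exp(s * z - s * s / 2.0)


def sample_subject_params(
    spec: PopulationSpec, rng: np.random.Generator, max_tries: int = 1000
) -> SubjectParams:
    """Draw one subject's (alpha, beta); redrawn until alpha * q < 1."""
    a_mean = np.asarray(spec.alpha_mean, dtype=float)
    b_mean = np.asarray(spec.beta_mean, dtype=float)
    q = np.asarray(spec.q_levels)
    for _ in range(max_tries):
        alpha = _draw_family(a_mean, spec.log_sd, spec.within_family_corr, rng)
        if np.all(alpha * q < 1.0):
            break
    else:
        raise ValueError("could not satisfy alpha * q < 1; infeasible population spec")
    beta = _draw_family(b_mean, spec.log_sd, spec.within_family_corr, rng)
    return SubjectParams(
        "sn_original",
        alpha,
        beta,
        q_levels=spec.q_levels,
        d_levels=spec.d_levels,
    )


def simulate_estimates(
    params: SubjectParams,
    design: pd.DataFrame,
    trials: Sequence[TrialSequence],
    noise: NoiseModel,
    rng: np.random.Generator,
    quantize: bool = False,
    subject_id: int = 1,
    clip: bool = True,
) -> pd.DataFrame:
    """Model posterior plus response noise for one subject, long format.

    Noise is added in probability space and the result clipped to [0, 1]
    (``clip=False`` keeps the raw noisy value, exposing the untruncated
    noise for diagnostics); ``quantize`` rounds to hundredths (two-digit
    entry). Returns one row per period with both the noiseless model
    probability (``P_model``) and the noisy observation (``P``).
    """
    if len(design) != len(trials):
        raise ValueError("design and trials length mismatch")
    recs = []
    for row, tr in zip(design.itertuples(), trials):
        p_model = posterior(tr.signals, row.q, row.d, params)
        sd = noise.sigma_for(p_model)
        p_obs = p_model + rng.standard_normal(p_model.size) * sd
        if clip:
            p_obs = np.clip(p_obs, 0.0, 1.0)
        if quantize:
            # two-digit button entry: the realizable grid is 0.00-0.99
            p_obs = np.minimum(np.round(p_obs, 2), 0.99)
        for t in range(tr.T):
            recs.append(
                (
                    subject_id,
                    row.block,
                    row.trial,
                    row.q,
                    row.d,
                    t + 1,
                    int(tr.signals[t]),
                    p_model[t],
                    p_obs[t],
                    False,
                )
            )
    return pd.DataFrame(recs, columns=ESTIMATES_COLUMNS)


def simulate_missing(
    estimates: pd.DataFrame, p_missing: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Flag periods missing at random (timed-out responses). Returns a copy."""
    if not (0.0 <= p_missing < 1.0):
        raise ValueError("p_missing must be in [0, 1)")
    out = estimates.copy()
    out["missing"] = out["missing"] | (rng.random(len(out)) < p_missing)
    return out


@dataclass
class SyntheticDataset:
    """A full synthetic cohort: stimuli, true parameters and estimates."""

    design: pd.DataFrame  # columns subject_id, block, trial, q, d
    trials: dict  # (subject_id, block, trial) -> TrialSequence
    params_true: dict  # subject_id -> SubjectParams
    estimates: pd.DataFrame  # ESTIMATES_COLUMNS
    meta: dict

    def params_frame(self) -> pd.DataFrame:
        """Tidy per-subject true parameters (params_true.csv schema)."""
        recs = []
        for sid, p in self.params_true.items():
            for fam, arr in (("alpha", p.alpha), ("beta", p.beta)):
                arr2 = np.atleast_2d(arr)
                classes = (
                    ["shared"] if arr2.shape[0] == 1 else ["consistent", "inconsistent"]
                )
                for ci, cname in enumerate(classes):
                    for lv in range(arr2.shape[1]):
                        recs.append((sid, fam, lv + 1, cname, arr2[ci, lv]))
        return pd.DataFrame(
            recs, columns=["subject_id", "parameter", "level", "signal_class", "value"]
        )

    def write(self, outdir) -> None:
        """Write trials.csv, estimates.csv, params_true.csv, dataset_meta.json."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trial_frames = []
        for sid in sorted(self.params_true):
            sub = self.design[self.design.subject_id == sid]
            seqs = [
                self.trials[(sid, r.block, r.trial)] for r in sub.itertuples()
            ]
            trial_frames.append(
                task.trials_to_frame(sub, seqs, subject_id=sid)
            )
        pd.concat(trial_frames).to_csv(outdir / "trials.csv", index=False)
        self.estimates.to_csv(outdir / "estimates.csv", index=False)
        self.params_frame().to_csv(outdir / "params_true.csv", index=False)
        (outdir / "dataset_meta.json").write_text(json.dumps(self.meta, indent=2))


def simulate_population(
    spec: PopulationSpec,
    n_blocks: int = 11,
    T: int = 10,
    rng: np.random.Generator | None = None,
    seed: Optional[int] = None,
    p_missing: float = 0.0,
) -> SyntheticDataset:
    """Simulate a cohort: params, per-subject stimuli and noisy estimates.

    Each subject gets an independent randomized block design and fresh
    signal sequences, mirroring per-subject stimulus generation in the
    task. ``n_blocks = 11`` reproduces the full design (8 behavioral + 3
    scanner blocks, 99 trials, 990 periods per subject).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    designs, trials, params_true, est_frames = [], {}, {}, []
    clipped = 0
    total = 0
    for sid in range(1, spec.n_subjects + 1):
        p = sample_subject_params(spec, rng)
        params_true[sid] = p
        des = task.generate_design(n_blocks, rng=rng)
        seqs = task.generate_trials(des, T=T, rng=rng)
        for row, tr in zip(des.itertuples(), seqs):
            trials[(sid, row.block, row.trial)] = tr
        est = simulate_estimates(
            p, des, seqs, spec.noise, rng, quantize=spec.quantize, subject_id=sid
        )
        raw = est["P_model"]
        clipped += int(((est["P"] == 0) & (raw > 0)).sum() + ((est["P"] == 1) & (raw < 1)).sum())
        total += len(est)
        if p_missing > 0:
            est = simulate_missing(est, p_missing, rng)
        des = des.copy()
        des.insert(0, "subject_id", sid)
        designs.append(des)
        est_frames.append(est)
    meta = {
        "seed": seed,
        "n_subjects": spec.n_subjects,
        "n_blocks": n_blocks,
        "T": T,
        "noise": {
            "kind": spec.noise.kind,
            "sigma": spec.noise.sigma,
            "bin_sds": list(spec.noise.bin_sds),
        },
        "quantize": spec.quantize,
        "p_missing": p_missing,
        "log_sd": spec.log_sd,
        "within_family_corr": spec.within_family_corr,
        "boundary_handling": "clip",
        "fraction_clipped": clipped / total if total else 0.0,
    }
    return SyntheticDataset(
        pd.concat(designs, ignore_index=True), trials, params_true,
        pd.concat(est_frames, ignore_index=True), meta,
    )
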