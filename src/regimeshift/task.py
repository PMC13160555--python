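"""Generative model of the regime-shift detection task.

A trial consists of ``T`` periods (default 10). The latent regime starts
red and, before each period's signal, may shift to blue with per-period
transition probability ``q``; blue is absorbing, so a trial contains at
most one shift. Each period's signal (a red or blue ball) is drawn from
the current regime's urn, whose dominant-color probability is
``d / (d + 1)`` where ``d`` is the signal diagnosticity.

Signals are coded as integers with 1 = red and 0 = blue, matching the
indicator convention used by the observer models (a red signal is
evidence *against* a shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Q_LEVELS",
    "D_LEVELS",
    "TrialCondition",
    "TrialSequence",
    "generate_trial",
    "generate_design",
    "generate_trials",
    "bonus",
    "TRIALS_CSV_COLUMNS",
    "trials_to_frame",
]

#: Transition-probability levels of the 3x3 factorial design.
Q_LEVELS: tuple[float, ...] = (0.01, 0.05, 0.1)
#: Signal-diagnosticity levels of the 3x3 factorial design.
D_LEVELS: tuple[float, ...] = (1.5, 3.0, 9.0)

RED, BLUE = 1, 0


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the 3x3 design: volatility ``q`` and diagnosticity ``d``."""

    q: float
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"transition probability q must be in [0, 1], got {self.q}")
        if self.d < 1.0:
            raise ValueError(f"signal diagnosticity d must be >= 1, got {self.d}")

    @property
    def dominant_fraction(self) -> float:
        """Probability that a regime emits its own dominant color, d/(d+1)."""
        return self.d / (self.d + 1.0)


@dataclass(frozen=True)
class TrialSequence:
    """A realized trial: signals, latent regime path and change period.

    ``signals`` and ``regime_path`` are length-``T`` integer vectors with
    1 = red, 0 = blue. ``change_period`` is the 1-based first blue period,
    or ``None`` if the regime never shifted.
    """

    condition: TrialCondition
    signals: np.ndarray
    regime_path: np.ndarray
    change_period: Optional[int]

    @property
    def T(self) -> int:
        return len(self.signals)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=np.int8)
        reg = np.asarray(self.regime_path, dtype=np.int8)
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "regime_path", reg)
        if sig.shape != reg.shape:
            raise ValueError("signals and regime_path must have equal length")
        blue = reg == BLUE
        if blue.any():
            first = int(np.argmax(blue)) + 1
            if not blue[first - 1 :].all():
                raise ValueError("regime_path must be absorbing: once blue, always blue")
            if self.change_period != first:
                raise ValueError("change_period inconsistent with regime_path")
        elif self.change_period is not None:
            raise ValueError("change_period given but regime_path never blue")


def generate_trial(
    condition: TrialCondition, T: int = 10, rng: np.random.Generator | None = None
) -> TrialSequence:
    """Generate one trial under ``condition``.

    Per period a Bernoulli(q) transition draw precedes the signal draw, so
    a shift can occur before the first signal; after a shift the remaining
    signals all come from the blue urn.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    q, p_dom = condition.q, condition.dominant_fraction

    regime = np.full(T, RED, dtype=np.int8)
    change_period: Optional[int] = None
    for t in range(T):
        if rng.random() < q:
            regime[t:] = BLUE
            change_period = t + 1
            break
    # signal = dominant color of current regime with prob d/(d+1)
    dom = rng.random(T) < p_dom
    signals = np.where(dom, regime, 1 - regime).astype(np.int8)
    return TrialSequence(condition, signals, regime, change_period)


def generate_design(
    n_blocks: int,
    conditions: Sequence[TrialCondition] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build a randomized block design table.

    Each block presents every condition exactly once in a freshly
    permuted order. The default condition set is the full 3x3 grid.
    Returns a DataFrame with columns ``block``, ``trial``, ``q``, ``d``
    (block and trial are 1-based; ``trial`` runs within block).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if conditions is None:
        conditions = [TrialCondition(q, d) for q in Q_LEVELS for d in D_LEVELS]
    if not conditions:
        raise ValueError("conditions must be nonempty")
    rng = np.random.default_rng() if rng is None else rng

    rows = []
    for b in range(1, n_blocks + 1):
        order = rng.permutation(len(conditions))
        for i, k in enumerate(order, start=1):
            c = conditions[k]
            rows.append((b, i, c.q, c.d))
    return pd.DataFrame(rows, columns=["block", "trial", "q", "d"])


def generate_trials(
    design: pd.DataFrame, T: int = 10, rng: np.random.Generator | None = None
) -> list[TrialSequence]:
    """Realize signal sequences for every row of a design table."""
    rng = np.random.default_rng() if rng is None else rng
    return [
        generate_trial(TrialCondition(row.q, row.d), T=T, rng=rng)
        for row in design.itertuples()
    ]


def bonus(P_t: float, B_t: int) -> float:
    """Quadratic payoff (in TWD) for one probability estimate.

    ``Bonus = 30 * (0.1 - 0.2 * (P_t - B_t)**2)`` where ``B_t`` is the
    regime indicator (1 = blue). Ranges from +3 (estimate equals the
    regime indicator) down to -3.
    """
    P_t = float(P_t)
    if not (0.0 <= P_t <= 1.0):
        raise ValueError(f"probability estimate must be in [0, 1], got {P_t}")
    if B_t not in (0, 1):
        raise ValueError(f"regime indicator must be 0 or 1, got {B_t}")
    return 30.0 * (0.1 - 0.2 * (P_t - B_t) ** 2)


TRIALS_CSV_COLUMNS = [
    "subject_id",
    "block",
    "trial",
    "q",
    "d",
    "period",
    "signal",
    "regime",
    "change_period",
]

_COLOR = {RED: "red", BLUE: "blue"}


def trials_to_frame(
    design: pd.DataFrame, trials: Sequence[TrialSequence], subject_id: int = 1
) -> pd.DataFrame:
    """Long-format (one row per period) table of realized trials.

    Matches the flat ``trials.csv`` schema: signal/regime as color names,
    1-based periods, empty change_period when no shift occurred.
    """
    if len(design) != len(trials):
        raise ValueError("design and trials length mismatch")
    recs = []
    for row, tr in zip(design.itertuples(), trials):
        for t in range(tr.T):
            recs.append(
                (
                    subject_id,
                    row.block,
                    row.trial,
                    row.q,
                    row.d,
                    t + 1,
                    _COLOR[int(tr.signals[t])],
                    _COLOR[int(tr.regime_path[t])],
                    tr.change_period if tr.change_period is not None else pd.NA,
                )
            )
    return pd.DataFrame(recs, columns=TRIALS_CSV_COLUMNS)
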