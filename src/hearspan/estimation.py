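"""Non-parametric transition estimation from person-year panels.

Age-specific transition probabilities are obtained by tabulating observed
year-to-year movements: every pair of consecutive records within a person is
one observed transition from the state at age x to the state at age x+1, and
``p_ij(x)`` is the row proportion ``count(x, i->j) / exposure(x, i)``.  No
smoothing or parametric modeling is applied.  Starting-distribution weights
are the shares of living-state person-years near the reference age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import StatePanel
from .states import (
    AGES,
    AGE_MIN,
    ALL_STRATA,
    LIVING_STATES,
    N_AGES,
    N_LIVING,
    N_STATES,
    STATES,
    Stratum,
    X,
)
from .surface import TransitionSurface

logger = logging.getLogger(__name__)

#: Origin ages for observed pairs: 60..98 (a pair ends at age 99 at most).
N_PAIR_AGES = N_AGES - 1


class EstimationError(ValueError):
    """Raised for empty windows or zero-exposure rows under the strict rule."""


@dataclass
class TransitionCounts:
    """Observed transition counts per origin age (60-98) and state pair."""

    stratum: Stratum
    counts: np.ndarray  # (39, 5, 5) int64
    exposures: np.ndarray = field(init=False)  # (39, 5)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_PAIR_AGES, N_STATES, N_STATES):
            raise EstimationError(
                f"counts must have shape {(N_PAIR_AGES, N_STATES, N_STATES)}"
            )
        self.exposures = self.counts.sum(axis=2)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        """True when the stratum contributed no person-year pairs."""
        return self.n_pairs == 0


def tabulate_transitions(panel: StatePanel, stratum: Stratum = ALL_STRATA) -> TransitionCounts:
    """Count age-specific origin->destination moves within the stratum.

    A censored final record contributes exposure to no pair.  An empty
    stratum yields zero counts (flagged on the result), not an exception.
    """
    counts = np.zeros((N_PAIR_AGES, N_STATES, N_STATES), dtype=np.int64)
    if panel.n_records:
        origin = ~panel.last_of_block()
        origin &= stratum.record_mask(panel.sex_code, panel.edu_code)
        idx = np.flatnonzero(origin)
        if idx.size:
            a = panel.age[idx] - AGE_MIN
            key = (a * N_STATES + panel.state_code[idx]) * N_STATES + panel.state_code[idx + 1]
            flat = np.bincount(key, minlength=N_PAIR_AGES * N_STATES * N_STATES)
            counts = flat.reshape(N_PAIR_AGES, N_STATES, N_STATES).astype(np.int64)
    return TransitionCounts(stratum=stratum, counts=counts)


def estimate_surface(
    counts: TransitionCounts, zero_exposure_rule: str = "carry_identity"
) -> TransitionSurface:
    """Row-proportion transition probabilities from tabulated counts.

    Living-state rows with zero exposure are handled per
    ``zero_exposure_rule``: ``"carry_identity"`` assigns stay probability 1
    (with a logged warning), ``"fail"`` raises naming the age and state.
    The age-99 row is forced to death (closure of the truncated age range);
    the death row is always the unit vector on death.
    """
    if zero_exposure_rule not in ("carry_identity", "fail"):
        raise EstimationError(f"unknown zero_exposure_rule {zero_exposure_rule!r}")
    probs = np.zeros((N_AGES, N_STATES, N_STATES))
    c = counts.counts[:, :N_LIVING, :].astype(np.float64)
    expo = counts.exposures[:, :N_LIVING].astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        rows = c / expo[:, :, None]
    empty = expo == 0
    if empty.any():
        if zero_exposure_rule == "fail":
            a, i = np.argwhere(empty)[0]
            raise EstimationError(
                f"zero exposure at age {AGES[a]}, state {STATES[i]} "
                f"(stratum {counts.stratum.label})"
            )
        logger.warning(
            "carry_identity applied to %d zero-exposure row(s) (stratum %s)",
            int(empty.sum()),
            counts.stratum.label,
        )
        rows[empty] = 0.0
        for a, i in np.argwhere(empty):
            rows[a, i, i] = 1.0
    probs[:N_PAIR_AGES, :N_LIVING, :] = rows
    probs[N_PAIR_AGES, :N_LIVING, X] = 1.0  # age-99 closure
    probs[:, X, X] = 1.0
    surface = TransitionSurface(probs, counts.stratum, provenance="estimated")
    surface.validate()
    return surface


@dataclass
class StartingDistribution:
    """Living-state shares near the reference age, used as mixing weights."""

    stratum: Stratum
    weights: np.ndarray  # (4,) over H, L, D, C
    window: tuple[int, int]
    n_person_years: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (N_LIVING,):
            raise EstimationError("weights must cover the four living states")
        if (self.weights < 0).any() or not np.isclose(self.weights.sum(), 1.0):
            raise EstimationError("weights must be a distribution")

    def weight(self, state: str) -> float:
        return float(self.weights[LIVING_STATES.index(state)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.stratum.sex,
                "education": self.stratum.education,
                "state": list(LIVING_STATES),
                "w": self.weights,
            }
        )


def starting_distribution(
    panel: StatePanel,
    stratum: Stratum = ALL_STRATA,
    window: tuple[int, int] = (60, 65),
) -> StartingDistribution:
    """Share of living-state person-years in the half-open age ``window``.

    The default [60, 65) pools ages 60-64, trading a little age resolution
    for stability of the weights.  Weights use person-years, not persons,
    consistent with period tabulation.
    """
    lo, hi = window
    if hi <= lo:
        raise EstimationError(f"empty age window {window}")
    mask = (
        (panel.age >= lo)
        & (panel.age < hi)
        & (panel.state_code != X)
        & stratum.record_mask(panel.sex_code, panel.edu_code)
    )
    codes = panel.state_code[mask]
    if codes.size == 0:
        raise EstimationError(
            f"no living person-years in window {window} for stratum {stratum.label}"
        )
    tallies = np.bincount(codes, minlength=N_STATES)[:N_LIVING].astype(np.float64)
    return StartingDistribution(
        stratum=stratum,
        weights=tallies / tallies.sum(),
        window=(lo, hi),
        n_person_years=int(tallies.sum()),
    )
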