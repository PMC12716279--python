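"""Multistate engine: occupancy, fundamental matrices, state expectancies.

Two independent code paths turn a transition surface into occupancy
probabilities.  The reference path is the forward recursion of
:func:`occupancy_profile` — the distribution at age x+1 is the distribution
at age x propagated through P(x).  The second path builds the transient
block supermatrix of the absorbing chain over the (age, living-state) space
and inverts I - U; the row of the fundamental matrix N = (I - U)^{-1} at
(60, origin) holds exactly the same occupancy probabilities.  Their equality
is a standing invariant.

State expectancies sum occupancy probabilities over ages 60-99 and subtract
a half-year correction of 0.5 from the origin state's occupancy — the
mid-interval convention, applied at the conditional level before the
starting-distribution weights.  The chain is truncated after the age-99
occupancy; remaining years beyond 99 are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import StartingDistribution
from .states import (
    AGES,
    LIVING_STATES,
    N_AGES,
    N_LIVING,
    N_STATES,
    STATE_INDEX,
    STATES,
    Stratum,
    X,
)
from .surface import TransitionSurface

#: Default mid-interval correction, in years.
HALF_YEAR_CORRECTION = 0.5


class EngineError(ValueError):
    """Raised when the chain is not absorbing-bound (singular system)."""


@dataclass
class OccupancyProfile:
    """State distribution at each age 60-99 given the origin state at 60."""

    origin: str
    dist: np.ndarray  # (40, 5)

    @property
    def ages(self) -> np.ndarray:
        return AGES

    def occupancy_sums(self) -> np.ndarray:
        """Expected person-years per state over ages 60-99 (no correction)."""
        return self.dist.sum(axis=0)

    def survival(self) -> np.ndarray:
        """P(alive at age x | origin at 60) for each age."""
        return 1.0 - self.dist[:, X]


def occupancy_profile(surface: TransitionSurface, origin: str) -> OccupancyProfile:
    """Forward recursion of the discrete-time chain from a point mass at 60."""
    if origin not in LIVING_STATES:
        raise EngineError(f"origin must be a living state, got {origin!r}")
    dist = np.zeros((N_AGES, N_STATES))
    dist[0, STATE_INDEX[origin]] = 1.0
    for k in range(N_AGES - 1):
        dist[k + 1] = dist[k] @ surface.probs[k]
    return OccupancyProfile(origin=origin, dist=dist)


def build_transient_supermatrix(surface: TransitionSurface) -> np.ndarray:
    """Transient part U of the absorbing chain over (age, living state).

    Index k = (age - 60) * 4 + living-state; shape (160, 160).  The only
    nonzero blocks map age x to age x+1 with the transient entries of P(x).
    Age-99 rows are zero — their mass moves to death or beyond the truncated
    age range — so U is nilpotent and I - U invertible.
    """
    n = N_AGES * N_LIVING
    U = np.zeros((n, n))
    for k in range(N_AGES - 1):
        U[
            k * N_LIVING : (k + 1) * N_LIVING,
            (k + 1) * N_LIVING : (k + 2) * N_LIVING,
        ] = surface.probs[k, :N_LIVING, :N_LIVING]
    return U


def fundamental_matrix(U: np.ndarray) -> np.ndarray:
    """N = (I - U)^{-1} of the transient supermatrix.

    ``N[(60, i), (x, j)]`` is the probability of occupying state j at age x
    given origin i at 60.  Solved as a linear system; a singular system
    signals a surface that is not absorbing-bound.
    """
    n = U.shape[0]
    try:
        return np.linalg.solve(np.eye(n) - U, np.eye(n))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise EngineError("I - U is singular: surface is not absorbing-bound") from exc


def occupancy_from_fundamental(N: np.ndarray, origin: str) -> np.ndarray:
    """Occupancy probabilities (40, 4) read off a fundamental-matrix row."""
    row = N[STATE_INDEX[origin], :]
    return row.reshape(N_AGES, N_LIVING)


@dataclass
class ExpectancyTable:
    """Years expected in each state from age 60, by origin and weighted.

    ``conditional[i, j]`` is e_j(60 | origin i) for living states i, j.
    Conditional totals are exact row sums.  Unconditional values are the
    starting-weight mixture of the conditional ones and are populated by
    :func:`unconditional_expectancies`.
    """

    stratum: Stratum
    conditional: np.ndarray  # (4, 4): origin x state
    correction: float = HALF_YEAR_CORRECTION
    weights: StartingDistribution | None = None
    unconditional: np.ndarray | None = None  # (4,)

    def conditional_le(self, origin: str) -> float:
        """Total life expectancy at 60 given the origin state."""
        return float(self.conditional[LIVING_STATES.index(origin)].sum())

    def expectancy(self, origin: str, state: str) -> float:
        return float(
            self.conditional[LIVING_STATES.index(origin), LIVING_STATES.index(state)]
        )

    @property
    def overall_le(self) -> float:
        """Population life expectancy at 60 (requires weights)."""
        if self.unconditional is None:
            raise EngineError("unconditional expectancies not computed yet")
        return float(self.unconditional.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy rows (sex, education, origin, state, years).

        Conditional origins are the four living states; the ``"weighted"``
        origin level carries the unconditional rows.  ``state == "total"``
        rows hold the life-expectancy sums.
        """
        rows = []
        for i, origin in enumerate(LIVING_STATES):
            for j, state in enumerate(LIVING_STATES):
                rows.append((origin, state, self.conditional[i, j]))
            rows.append((origin, "total", float(self.conditional[i].sum())))
        if self.unconditional is not None:
            for j, state in enumerate(LIVING_STATES):
                rows.append(("weighted", state, float(self.unconditional[j])))
            rows.append(("weighted", "total", self.overall_le))
        df = pd.DataFrame(rows, columns=["origin", "state", "years"])
        df.insert(0, "education", self.stratum.education)
        df.insert(0, "sex", self.stratum.sex)
        return df


def conditional_expectancies(
    surface: TransitionSurface, correction: float = HALF_YEAR_CORRECTION
) -> ExpectancyTable:
    """State expectancies at 60 conditional on each living origin state.

    Raw occupancy o_j(i) sums P(state at x = j | origin i) over ages 60-99;
    the half-year correction is subtracted from the origin state's own
    occupancy, so LE(60 | i) = sum_j o_j(i) - correction exactly.
    """
    cond = np.zeros((N_LIVING, N_LIVING))
    for i, origin in enumerate(LIVING_STATES):
        occ = occupancy_profile(surface, origin).occupancy_sums()[:N_LIVING]
        occ[i] -= correction
        cond[i] = occ
    return ExpectancyTable(
        stratum=surface.stratum, conditional=cond, correction=correction
    )


def unconditional_expectancies(
    table: ExpectancyTable, weights: StartingDistribution
) -> ExpectancyTable:
    """Populate the starting-weight mixture: e_j(60) = sum_i w_i e_j(60|i)."""
    return ExpectancyTable(
        stratum=table.stratum,
        conditional=table.conditional,
        correction=table.correction,
        weights=weights,
        unconditional=weights.weights @ table.conditional,
    )
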