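"""Age-specific transition probability surfaces.

A surface holds one row-stochastic 5x5 matrix ``P(x)`` per single year of
age x in 60-99, where ``P(x)[i, j]`` is the probability of occupying state j
at age x+1 given state i at age x.  Entries outside the irreversibility mask
are zero, and the death row is the unit vector on death.  Surfaces are either
``"estimated"`` (tabulated from a panel) or ``"truth"`` (evaluated from a
parametric synthetic model) — everything downstream consumes them the same
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .states import (
    AGES,
    ALLOWED,
    ALL_STRATA,
    N_AGES,
    N_STATES,
    STATE_INDEX,
    STATES,
    Stratum,
    X,
)


class SurfaceError(ValueError):
    """Raised when a surface breaks row-stochasticity or the transition mask."""


@dataclass
class TransitionSurface:
    """Per-stratum stack of 40 row-stochastic 5x5 matrices, ages 60-99."""

    probs: np.ndarray
    stratum: Stratum = field(default_factory=lambda: ALL_STRATA)
    provenance: str = "estimated"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (N_AGES, N_STATES, N_STATES):
            raise SurfaceError(
                f"surface must have shape {(N_AGES, N_STATES, N_STATES)}, "
                f"got {self.probs.shape}"
            )

    @property
    def ages(self) -> np.ndarray:
        return AGES

    def matrix(self, age: int) -> np.ndarray:
        """The 5x5 matrix governing the move from ``age`` to ``age + 1``."""
        return self.probs[age - AGES[0]]

    def validate(self, atol: float = 1e-9) -> None:
        """Raise :class:`SurfaceError` on the first broken invariant."""
        p = self.probs
        if np.any(p < -atol) or np.any(p > 1 + atol):
            raise SurfaceError("probabilities outside [0, 1]")
        rowsums = p.sum(axis=2)
        bad = np.abs(rowsums - 1.0) > atol
        if bad.any():
            a, i = np.argwhere(bad)[0]
            raise SurfaceError(
                f"row not stochastic at age {AGES[a]}, state {STATES[i]} "
                f"(sum {rowsums[a, i]:.12f})"
            )
        if np.any(p[:, ~ALLOWED] > atol):
            a = np.argwhere(np.abs(p) * ~ALLOWED > atol)[0]
            raise SurfaceError(
                f"nonzero probability outside the transition mask at age "
                f"{AGES[a[0]]}: {STATES[a[1]]} -> {STATES[a[2]]}"
            )
        expected_x = np.zeros(N_STATES)
        expected_x[X] = 1.0
        if np.any(np.abs(p[:, X, :] - expected_x) > atol):
            raise SurfaceError("death row must be the unit vector on X")

    def copy(self) -> "TransitionSurface":
        return replace(self, probs=self.probs.copy())

    # ------------------------------------------------------------------ io

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: sex, education, age, from_state, to_state, p.

        Only mask-allowed cells are emitted.
        """
        rows_i, rows_j = np.nonzero(ALLOWED)
        n_cells = rows_i.size
        return pd.DataFrame(
            {
                "sex": self.stratum.sex,
                "education": self.stratum.education,
                "age": np.repeat(AGES, n_cells),
                "from_state": np.tile(np.asarray(STATES, object)[rows_i], N_AGES),
                "to_state": np.tile(np.asarray(STATES, object)[rows_j], N_AGES),
                "p": self.probs[:, rows_i, rows_j].ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "estimated") -> "TransitionSurface":
        """Rebuild a surface from :meth:`to_frame` output (one stratum)."""
        sexes = df["sex"].unique()
        edus = df["education"].unique()
        if len(sexes) != 1 or len(edus) != 1:
            raise SurfaceError("from_frame expects a single stratum")
        probs = np.zeros((N_AGES, N_STATES, N_STATES))
        a = df["age"].to_numpy(dtype=int) - AGES[0]
        i = np.array([STATE_INDEX[s] for s in df["from_state"]])
        j = np.array([STATE_INDEX[s] for s in df["to_state"]])
        probs[a, i, j] = df["p"].to_numpy(dtype=float)
        surf = cls(probs, Stratum(str(sexes[0]), str(edus[0])), provenance)
        surf.validate(atol=1e-6)
        return surf


def random_surface(rng: np.random.Generator, stratum: Stratum = ALL_STRATA) -> TransitionSurface:
    """A random mask-respecting surface (Dirichlet rows); test/demo helper."""
    probs = np.zeros((N_AGES, N_STATES, N_STATES))
    for i in range(N_STATES):
        dests = np.flatnonzero(ALLOWED[i])
        probs[:, i, dests] = rng.dirichlet(np.ones(dests.size), size=N_AGES)
    probs[:, X, :] = 0.0
    probs[:, X, X] = 1.0
    return TransitionSurface(probs, stratum, provenance="truth")
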