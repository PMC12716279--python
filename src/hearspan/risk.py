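"""Lifetime and partial first-passage risks via target-state absorption.

The probability of ever occupying a destination state by a horizon age is
computed with the standard first-passage construction: replace the target
state's rows with self-loops at every age, propagate a point mass on the
origin from age 60, and read the mass on the target at the horizon.  "Ever
transitioning into state j" means first entry into exactly state j — moving
from healthy straight to comorbidity does not count toward the dementia
risk.  A variant accepting a set of target states (e.g. dementia or
comorbidity, "any dementia") absorbs them all and sums their mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import occupancy_profile
from .states import (
    AGES,
    AGE_MIN,
    LIVING_STATES,
    N_STATES,
    STATE_INDEX,
    Stratum,
)
from .surface import TransitionSurface

#: Destinations with a defined first-passage risk (death and healthy excluded).
RISK_TARGETS: tuple[str, ...] = ("L", "D", "C")
DEFAULT_HORIZONS: tuple[int, ...] = (80, 99)


class RiskError(ValueError):
    """Raised for undefined origin/target/horizon combinations."""


def make_absorbing(surface: TransitionSurface, target: str) -> TransitionSurface:
    """Replace the target state's rows with self-loops at every age.

    Death is already absorbing and healthy cannot be re-entered under
    irreversibility, so only L, D, C are admissible targets.  Idempotent.
    """
    if target not in RISK_TARGETS:
        raise RiskError(
            f"target must be one of {RISK_TARGETS} (X is already absorbing, "
            f"H is undefined under irreversibility); got {target!r}"
        )
    t = STATE_INDEX[target]
    modified = surface.copy()
    modified.probs[:, t, :] = 0.0
    modified.probs[:, t, t] = 1.0
    return modified


def _absorb_all(surface: TransitionSurface, targets: Sequence[str]) -> TransitionSurface:
    out = surface
    for t in targets:
        out = make_absorbing(out, t)
    return out


def cumulative_risk(
    surface: TransitionSurface,
    origin: str,
    target: str | Iterable[str],
    horizon: int = 99,
) -> float:
    """P(ever occupying the target state(s) at an age in (60, horizon]).

    ``target`` may be a single state or an iterable of states; with several
    targets the result is the probability of ever entering any of them.
    Unreachable targets yield exactly 0.
    """
    targets = (target,) if isinstance(target, str) else tuple(target)
    if origin not in LIVING_STATES:
        raise RiskError(f"origin must be a living state, got {origin!r}")
    if origin in targets:
        raise RiskError(f"origin {origin!r} cannot be its own target")
    if not (AGE_MIN + 1 <= horizon <= AGES[-1]):
        raise RiskError(f"horizon must be in [{AGE_MIN + 1}, {AGES[-1]}], got {horizon}")
    absorbed = _absorb_all(surface, targets)
    dist = occupancy_profile(absorbed, origin).dist
    return float(sum(dist[horizon - AGE_MIN, STATE_INDEX[t]] for t in targets))


@dataclass
class RiskTable:
    """First-passage probabilities for all origin/destination/horizon cells."""

    stratum: Stratum
    horizons: tuple[int, ...]
    values: dict[tuple[str, str, int], float]

    def risk(self, origin: str, target: str, horizon: int) -> float:
        return self.values[(origin, target, horizon)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy rows (sex, education, origin, destination, horizon, risk,
        risk_percent) — the percent column rounded to one decimal."""
        rows = [
            (o, t, h, v, round(100.0 * v, 1))
            for (o, t, h), v in sorted(self.values.items(), key=lambda kv: kv[0])
        ]
        df = pd.DataFrame(
            rows, columns=["origin", "destination", "horizon", "risk", "risk_percent"]
        )
        df.insert(0, "education", self.stratum.education)
        df.insert(0, "sex", self.stratum.sex)
        return df


def risk_table(
    surface: TransitionSurface,
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    origins: Sequence[str] = LIVING_STATES,
    targets: Sequence[str] = RISK_TARGETS,
) -> RiskTable:
    """All origin/destination/horizon first-passage probabilities.

    One absorption and one forward propagation per (target, origin) pair;
    every horizon is read off the same occupancy profile.  Cells whose
    destination is unreachable from the origin are exactly 0.
    """
    values: dict[tuple[str, str, int], float] = {}
    for t in targets:
        absorbed = make_absorbing(surface, t)
        ti = STATE_INDEX[t]
        for o in origins:
            if o == t:
                continue
            dist = occupancy_profile(absorbed, o).dist
            for h in horizons:
                values[(o, t, h)] = float(dist[h - AGE_MIN, ti])
    return RiskTable(stratum=surface.stratum, horizons=tuple(horizons), values=values)


def first_entry_distribution(
    surface: TransitionSurface, origin: str, target: str
) -> np.ndarray:
    """P(first entry into the target at each age 61-99); bookkeeping check.

    Propagates the chain restricted to never-entered trajectories (target
    column removed) and records the mass flowing into the target each year.
    Its cumulative sums must match :func:`cumulative_risk` at every horizon.
    """
    if target not in RISK_TARGETS:
        raise RiskError(f"target must be one of {RISK_TARGETS}, got {target!r}")
    ti = STATE_INDEX[target]
    d = np.zeros(N_STATES)
    d[STATE_INDEX[origin]] = 1.0
    entries = np.zeros(AGES.size - 1)
    for k in range(AGES.size - 1):
        moved = d @ surface.probs[k]
        entries[k] = moved[ti]
        moved[ti] = 0.0  # restrict to trajectories that have not entered
        d = moved
    return entries
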