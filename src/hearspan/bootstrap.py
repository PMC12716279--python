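"""Trajectory bootstrap with the subsample-then-rescale shortcut.

Whole person trajectories are the resampling unit: all of a person's
records move together.  To keep full-population runs affordable the
interval length can be estimated on an f-fraction random subsample and
rescaled by sqrt(f) — with the default f = 0.05 that is the 1/sqrt(20)
factor relating a 5% subsample to a population 20 times its size.  The
2.5th-97.5th percentile spread of the B resample values defines the raw
length, and the interval is placed symmetrically around the full-panel
point estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .panel import StatePanel

logger = logging.getLogger(__name__)

DEFAULT_B = 200
DEFAULT_FRACTION = 0.05


class BootstrapError(ValueError):
    """Raised for invalid resampling settings."""


def scale_ci(raw_length: float, f: float) -> float:
    """Scale a subsample interval length to the full population: raw * sqrt(f)."""
    if not 0.0 < f <= 1.0:
        raise BootstrapError(f"subsample fraction must be in (0, 1], got {f}")
    if raw_length < 0:
        raise BootstrapError(f"interval length must be nonnegative, got {raw_length}")
    return raw_length * math.sqrt(f)


@dataclass
class BootstrapCI:
    """A symmetric confidence interval for one tracked statistic."""

    name: str
    point: float
    B: int
    f: float
    raw_length: float
    scaled_length: float
    lo: float
    hi: float
    seed: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            assert self.scaled_length >= 0
            assert self.lo - 1e-12 <= self.point <= self.hi + 1e-12


def _as_series(value, fallback_name: str) -> pd.Series:
    if isinstance(value, pd.Series):
        return value.astype(float)
    return pd.Series([float(value)], index=[fallback_name])


def bootstrap_table(
    panel: StatePanel,
    statistic: Callable[[StatePanel], "pd.Series | float"],
    B: int = DEFAULT_B,
    f: float = DEFAULT_FRACTION,
    seed: int = 0,
    name: str = "statistic",
) -> pd.DataFrame:
    """Bootstrap a scalar- or Series-valued statistic of a panel.

    Draws one f-fraction simple random subsample of persons, then B
    with-replacement person-level resamples of that subsample, recomputing
    the statistic end-to-end on each resampled panel.  Returns a frame
    indexed like the statistic with columns ``point``, ``lo``, ``hi``,
    ``raw_length``, ``scaled_length``, ``missing``.

    A resample on which the statistic cannot be evaluated (it raises or
    returns NaN — e.g. an empty stratum in a tiny subsample) marks the
    affected entries missing, with a warning, rather than failing globally.
    """
    if not 0.0 < f <= 1.0:
        raise BootstrapError(f"subsample fraction must be in (0, 1], got {f}")
    if B < 1:
        raise BootstrapError(f"B must be at least 1, got {B}")
    rng = np.random.default_rng(seed)
    point = _as_series(statistic(panel), name)
    k_index = point.index

    n_persons = panel.n_persons
    if f >= 1.0:
        sub = np.arange(n_persons)
    else:
        k = max(1, int(round(f * n_persons)))
        sub = rng.choice(n_persons, size=k, replace=False)
    k = sub.size

    values = np.empty((B, k_index.size))
    for b in range(B):
        draw = sub[rng.integers(0, k, size=k)]
        resampled = panel.take_persons(draw, relabel=True)
        try:
            v = _as_series(statistic(resampled), name)
            values[b] = v.reindex(k_index).to_numpy()
        except Exception as exc:  # noqa: BLE001 - per-resample failures are data-driven
            logger.warning("statistic failed on resample %d: %s", b, exc)
            values[b] = np.nan

    missing = np.isnan(values).any(axis=0)
    if missing.any():
        logger.warning(
            "%d statistic(s) missing on some resamples; intervals flagged",
            int(missing.sum()),
        )
    with np.errstate(invalid="ignore"):
        lo_p, hi_p = np.nanpercentile(values, [2.5, 97.5], axis=0)
    raw = hi_p - lo_p
    scaled = raw * math.sqrt(f)
    pt = point.to_numpy()
    out = pd.DataFrame(
        {
            "point": pt,
            "lo": pt - scaled / 2.0,
            "hi": pt + scaled / 2.0,
            "raw_length": raw,
            "scaled_length": scaled,
            "missing": missing,
        },
        index=k_index,
    )
    out.loc[missing, ["lo", "hi", "raw_length", "scaled_length"]] = np.nan
    return out


def bootstrap_statistics(
    panel: StatePanel,
    statistics: Mapping[str, Callable[[StatePanel], float]],
    B: int = DEFAULT_B,
    f: float = DEFAULT_FRACTION,
    seed: int = 0,
) -> dict[str, BootstrapCI]:
    """Bootstrap several scalar statistics on one shared subsample.

    All statistics are evaluated on the same subsample and the same B
    resamples, so cross-statistic comparisons share their resampling noise.
    """

    def combined(p: StatePanel) -> pd.Series:
        return pd.Series({nm: float(fn(p)) for nm, fn in statistics.items()})

    table = bootstrap_table(panel, combined, B=B, f=f, seed=seed)
    return {
        nm: BootstrapCI(
            name=nm,
            point=row["point"],
            B=B,
            f=f,
            raw_length=row["raw_length"],
            scaled_length=row["scaled_length"],
            lo=row["lo"],
            hi=row["hi"],
            seed=seed,
            missing=bool(row["missing"]),
        )
        for nm, row in table.iterrows()
    }
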