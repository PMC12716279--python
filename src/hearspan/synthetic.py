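"""Synthetic register generator and microsimulation oracle.

Real inputs to this kind of analysis are administrative registers with no
public access.  This module emulates their statistical structure from a fully
known parametric model — a Gompertz mortality baseline with state, sex, and
education multipliers, plus logistic-in-age incidence curves for each
admissible morbidity move — so that estimation and the matrix engine can be
tested against ground truth.

Two simulators are provided:

* :func:`simulate_panel` produces a register-like person-year panel with
  staggered entry over a calendar window, left truncation, and right
  censoring — the raw material of the estimation pipeline.
* :func:`microsimulate_summaries` simulates closed cohorts from exact age 60
  under the same truth surface, with no truncation or censoring.  It shares
  the discrete-time semantics of the matrix engine (one multinomial draw per
  year over the full destination row) and serves as an independent oracle
  for expectancies and lifetime risks.

Default parameter values are calibrated qualitatively — orderings and rough
magnitudes, not fits: hearing loss carries no excess mortality, dementia and
comorbidity do; incidence into comorbidity from hearing loss exceeds both
healthy-to-dementia and dementia-to-comorbidity incidence at every age.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit, logit

from .panel import StatePanel
from .states import (
    AGES,
    AGE_MIN,
    EDUCATIONS,
    LIVING_STATES,
    N_AGES,
    N_LIVING,
    N_STATES,
    SEXES,
    STATE_INDEX,
    STATES,
    Stratum,
    X,
)
from .surface import TransitionSurface

#: Admissible morbidity moves with their own incidence curve.
TRANSITION_KEYS: tuple[str, ...] = ("H>L", "H>D", "H>C", "L>C", "D>C")

_EXITED = -2  # simulation sentinel: dead or censored
_NOT_ENTERED = -1


class SpecError(ValueError):
    """Raised for an inconsistent synthetic model specification."""


def _unit_multipliers() -> dict[str, float]:
    return {"male": 1.0, "female": 1.0, "none": 1.0, "secondary": 1.0, "tertiary": 1.0}


def _lookup(multipliers: dict[str, float], key: str) -> float:
    """Multiplier for a stratum level; ``"all"`` means the baseline (1.0)."""
    return 1.0 if key == "all" else float(multipliers.get(key, 1.0))


@dataclass
class IncidenceCurve:
    """Logistic-in-age annual onset probability.

    The curve is logistic on the logit scale: ``p(x) = expit(logit(level60)
    + slope * (x - 60))``, then multiplied by the stratum factors.  ``slope``
    is per year of age.  Multiplied values may exceed 1 in pathological
    configurations; the surface constructor's cap rule deals with that.
    """

    level60: float
    slope: float
    sex_multipliers: dict[str, float] = field(default_factory=_unit_multipliers)
    education_multipliers: dict[str, float] = field(default_factory=_unit_multipliers)

    def probability(self, ages: np.ndarray, sex: str = "all", education: str = "all") -> np.ndarray:
        base = expit(logit(self.level60) + self.slope * (np.asarray(ages) - AGE_MIN))
        return base * _lookup(self.sex_multipliers, sex) * _lookup(
            self.education_multipliers, education
        )


@dataclass
class GompertzMortality:
    """Gompertz annual death probability with state and stratum multipliers.

    ``a`` is the baseline probability at age 60, ``b`` the log-slope per year
    of age: ``q(x) = a * exp(b * (x - 60)) * r_state * m_sex * m_education``.
    """

    a: float
    b: float
    state_multipliers: dict[str, float]
    sex_multipliers: dict[str, float] = field(default_factory=_unit_multipliers)
    education_multipliers: dict[str, float] = field(default_factory=_unit_multipliers)

    def probability(self, ages: np.ndarray, state: str, sex: str = "all", education: str = "all") -> np.ndarray:
        return (
            self.a
            * np.exp(self.b * (np.asarray(ages) - AGE_MIN))
            * float(self.state_multipliers[state])
            * _lookup(self.sex_multipliers, sex)
            * _lookup(self.education_multipliers, education)
        )


@dataclass
class SyntheticModelSpec:
    """Full parametric description of the synthetic register.

    Fields
    ------
    n_individuals, seed
        Cohort size and the seed controlling every draw.
    period
        (first_year, last_year) calendar window; entry is staggered across
        it and observation is right-censored at its end.
    sex_weights, education_weights
        Population composition; education is sex-specific.
    entry_year_weights
        Distribution over calendar years of entry (length = window length).
        The default front-loads the first year (the prevalent pool) and
        spreads the rest uniformly.
    entry_age_weights
        Distribution over ages 60-99 at entry (length 40).
    start_state_weights
        Per-sex distribution over living states at entry.
    mortality, incidence
        The truth surface parameters.
    cap
        Row-overflow rule when candidate off-diagonal mass exceeds 1:
        ``"error"`` (default — keeps truth surfaces honest) or
        ``"rescale"`` (proportional renormalization, stay mass 0).
    """

    n_individuals: int
    seed: int
    period: tuple[int, int]
    sex_weights: dict[str, float]
    education_weights: dict[str, dict[str, float]]
    entry_year_weights: list[float]
    entry_age_weights: list[float]
    start_state_weights: dict[str, dict[str, float]]
    mortality: GompertzMortality
    incidence: dict[str, IncidenceCurve]
    cap: str = "error"

    # ------------------------------------------------------------ validation

    def validate(self) -> None:
        """Raise :class:`SpecError` on the first inconsistency found."""
        if self.n_individuals <= 0:
            raise SpecError("n_individuals must be positive")
        first, last = self.period
        if last < first:
            raise SpecError("period must be (first_year, last_year) with first <= last")
        if self.cap not in ("error", "rescale"):
            raise SpecError(f"unknown cap rule {self.cap!r}")
        n_years = last - first + 1
        for name, w, n in (
            ("entry_year_weights", self.entry_year_weights, n_years),
            ("entry_age_weights", self.entry_age_weights, N_AGES),
        ):
            arr = np.asarray(w, dtype=float)
            if arr.size != n:
                raise SpecError(f"{name} must have length {n}, got {arr.size}")
            if (arr < 0).any() or not np.isclose(arr.sum(), 1.0):
                raise SpecError(f"{name} must be a distribution")
        _check_distribution("sex_weights", self.sex_weights, SEXES)
        for sex in SEXES:
            _check_distribution(
                f"education_weights[{sex}]", self.education_weights[sex], EDUCATIONS
            )
            _check_distribution(
                f"start_state_weights[{sex}]", self.start_state_weights[sex], LIVING_STATES
            )
        unknown = set(self.incidence) - set(TRANSITION_KEYS)
        if unknown:
            raise SpecError(f"unknown incidence transition(s): {sorted(unknown)}")
        # every concrete stratum must yield a valid surface under the cap rule
        for sex in SEXES:
            for edu in EDUCATIONS:
                surface_from_spec(self, Stratum(sex, edu)).validate()

    # -------------------------------------------------------------- yaml io

    def to_dict(self) -> dict:
        d = asdict(self)
        d["period"] = list(self.period)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticModelSpec":
        d = dict(d)
        d["period"] = tuple(d["period"])
        d["mortality"] = GompertzMortality(**d["mortality"])
        d["incidence"] = {k: IncidenceCurve(**v) for k, v in d["incidence"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _check_distribution(name: str, weights: dict[str, float], keys: tuple[str, ...]) -> None:
    missing = set(keys) - set(weights)
    if missing:
        raise SpecError(f"{name} missing keys {sorted(missing)}")
    vals = np.array([weights[k] for k in keys], dtype=float)
    if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
        raise SpecError(f"{name} must be a nonnegative distribution summing to 1")


# ------------------------------------------------------------------ defaults


def build_default_spec(n_individuals: int = 100_000, seed: int = 2009) -> SyntheticModelSpec:
    """The default synthetic register: study-condition parameter values.

    Start-state weights at entry reproduce the observed near-age-60 shares
    (men 92.5% healthy / 5.8% hearing loss, women 93.2% / 5.7%), with the
    remainder split between dementia and comorbidity in proportion to the
    register's entry composition.  Mortality multipliers encode that hearing
    loss adds no mortality while dementia and comorbidity do; incidence into
    comorbidity from hearing loss dominates healthy-to-dementia and
    dementia-to-comorbidity incidence at every age.
    """
    entry_age = np.exp(-0.06 * (AGES - AGE_MIN))
    entry_age /= entry_age.sum()
    n_years = 2019 - 2009 + 1
    entry_year = np.full(n_years, 0.65 / (n_years - 1))
    entry_year[0] = 0.35

    male_dc = 1.0 - 0.925 - 0.058   # split D:C as 2.4 : 0.5 (entry shares)
    female_dc = 1.0 - 0.932 - 0.057  # split D:C as 4.1 : 0.7
    start = {
        "male": {
            "H": 0.925,
            "L": 0.058,
            "D": male_dc * 2.4 / 2.9,
            "C": male_dc * 0.5 / 2.9,
        },
        "female": {
            "H": 0.932,
            "L": 0.057,
            "D": female_dc * 4.1 / 4.8,
            "C": female_dc * 0.7 / 4.8,
        },
    }

    mortality = GompertzMortality(
        a=0.009,
        b=0.085,
        state_multipliers={"H": 1.0, "L": 1.0, "D": 2.2, "C": 2.2},
        sex_multipliers={"male": 1.25, "female": 0.8},
        education_multipliers={"none": 1.15, "secondary": 1.0, "tertiary": 0.85},
    )
    incidence = {
        "H>L": IncidenceCurve(0.004, 0.075, sex_multipliers={"male": 1.2, "female": 0.85}),
        "H>D": IncidenceCurve(0.0015, 0.13, sex_multipliers={"male": 0.85, "female": 1.2}),
        "H>C": IncidenceCurve(0.0002, 0.11, sex_multipliers={"male": 0.9, "female": 1.1}),
        "L>C": IncidenceCurve(0.004, 0.13, sex_multipliers={"male": 0.9, "female": 1.15}),
        "D>C": IncidenceCurve(0.003, 0.10, sex_multipliers={"male": 1.15, "female": 0.9}),
    }

    return SyntheticModelSpec(
        n_individuals=n_individuals,
        seed=seed,
        period=(2009, 2019),
        sex_weights={"male": 0.46, "female": 0.54},
        education_weights={
            "male": {"none": 0.424, "secondary": 0.318, "tertiary": 0.258},
            "female": {"none": 0.457, "secondary": 0.309, "tertiary": 0.234},
        },
        entry_year_weights=entry_year.tolist(),
        entry_age_weights=entry_age.tolist(),
        start_state_weights=start,
        mortality=mortality,
        incidence=incidence,
        cap="error",
    )


# ------------------------------------------------------------ truth surface


def surface_from_spec(spec: SyntheticModelSpec, stratum: Stratum) -> TransitionSurface:
    """Evaluate the parametric truth surface for one stratum.

    ``"all"`` on either stratum dimension uses the baseline curves
    (multiplier 1.0).  Each origin row receives its death probability and
    incidence probabilities; the stay probability is the residual mass.
    Candidate off-diagonal mass above 1 triggers the spec's cap rule.
    """
    sex, edu = stratum.sex, stratum.education
    probs = np.zeros((N_AGES, N_STATES, N_STATES))
    for i, origin in enumerate(LIVING_STATES):
        off = np.zeros((N_AGES, N_STATES))
        off[:, X] = spec.mortality.probability(AGES, origin, sex, edu)
        for key in TRANSITION_KEYS:
            src, dest = key.split(">")
            if src != origin or key not in spec.incidence:
                continue
            off[:, STATE_INDEX[dest]] = spec.incidence[key].probability(AGES, sex, edu)
        total = off.sum(axis=1)
        over = total > 1.0
        if over.any():
            if spec.cap == "error":
                age = int(AGES[np.flatnonzero(over)[0]])
                raise SpecError(
                    f"candidate off-diagonal mass exceeds 1 at age {age}, "
                    f"origin state {origin} (stratum {stratum.label})"
                )
            off[over] /= total[over, None]
            total = np.minimum(total, 1.0)
        probs[:, i, :] = off
        probs[:, i, i] = 1.0 - total
    probs[:, X, X] = 1.0
    return TransitionSurface(probs, stratum, provenance="truth")


def _cumulative_rows(surface: TransitionSurface) -> np.ndarray:
    """Cumulative destination probabilities, shape (40, 5, 5)."""
    return np.cumsum(surface.probs, axis=2)


def _draw_destinations(
    rng: np.random.Generator, cum_rows: np.ndarray
) -> np.ndarray:
    """One multinomial draw per row of ``cum_rows`` (k, 5) -> states (k,)."""
    u = rng.random(cum_rows.shape[0])
    return (cum_rows[:, :-1] < u[:, None]).sum(axis=1).astype(np.int8)


# ------------------------------------------------------------------- panel


def simulate_panel(spec: SyntheticModelSpec) -> StatePanel:
    """Simulate a register-like person-year panel (seeded, reproducible).

    Each person draws sex, education, entry year, entry age, and entry
    state; thereafter one destination per year from the truth surface row
    for their stratum and age.  Simulation stops at death, at period end,
    or after the age-99 record (survivors past 99 are right-censored — the
    panel never contains an age above 99).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    first, last = spec.period
    n_years = last - first + 1

    sex = _draw_coded(rng, n, [spec.sex_weights[s] for s in SEXES])
    edu = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    for si in range(2):
        cum = np.cumsum([spec.education_weights[SEXES[si]][e] for e in EDUCATIONS])
        m = sex == si
        edu[m] = np.searchsorted(cum, u[m], side="right").astype(np.int8)
        np.clip(edu, 0, len(EDUCATIONS) - 1, out=edu)
    entry_year_idx = rng.choice(n_years, size=n, p=np.asarray(spec.entry_year_weights))
    entry_age = rng.choice(AGES, size=n, p=np.asarray(spec.entry_age_weights)).astype(np.int16)
    state0 = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    for si in range(2):
        cum = np.cumsum([spec.start_state_weights[SEXES[si]][s] for s in LIVING_STATES])
        m = sex == si
        state0[m] = np.searchsorted(cum, u[m], side="right").astype(np.int8)
        np.clip(state0, 0, N_LIVING - 1, out=state0)

    cum_surf = {
        (si, ei): _cumulative_rows(surface_from_spec(spec, Stratum(SEXES[si], EDUCATIONS[ei])))
        for si in range(2)
        for ei in range(3)
    }

    state = np.full(n, _NOT_ENTERED, dtype=np.int8)
    rec_pid: list[np.ndarray] = []
    rec_year: list[np.ndarray] = []
    rec_age: list[np.ndarray] = []
    rec_state: list[np.ndarray] = []

    for yi in range(n_years):
        year = first + yi
        if yi > 0:
            act = np.flatnonzero(state >= 0)
            if act.size:
                age_prev = entry_age[act] + (yi - 1) - entry_year_idx[act]
                past99 = age_prev >= AGES[-1]
                state[act[past99]] = _EXITED  # censor after the age-99 record
                act = act[~past99]
                age_prev = age_prev[~past99]
            if act.size:
                ai = (age_prev - AGE_MIN).astype(np.int64)
                new_state = np.empty(act.size, dtype=np.int8)
                for si in range(2):
                    for ei in range(3):
                        stratum_mask = (sex[act] == si) & (edu[act] == ei)
                        for origin in range(N_LIVING):
                            m = stratum_mask & (state[act] == origin)
                            k = int(m.sum())
                            if k == 0:
                                continue
                            rows = cum_surf[(si, ei)][ai[m], origin, :]
                            new_state[m] = _draw_destinations(rng, rows)
                state[act] = new_state
                rec_pid.append(act)
                rec_year.append(np.full(act.size, year, dtype=np.int64))
                rec_age.append((age_prev + 1).astype(np.int64))
                rec_state.append(new_state.copy())
                state[act[new_state == X]] = _EXITED
        ent = np.flatnonzero((entry_year_idx == yi) & (state == _NOT_ENTERED))
        if ent.size:
            state[ent] = state0[ent]
            rec_pid.append(ent)
            rec_year.append(np.full(ent.size, year, dtype=np.int64))
            rec_age.append(entry_age[ent].astype(np.int64))
            rec_state.append(state0[ent].copy())

    pid = np.concatenate(rec_pid) if rec_pid else np.empty(0, dtype=np.int64)
    year_arr = np.concatenate(rec_year) if rec_year else np.empty(0, dtype=np.int64)
    age_arr = np.concatenate(rec_age) if rec_age else np.empty(0, dtype=np.int64)
    state_arr = np.concatenate(rec_state) if rec_state else np.empty(0, dtype=np.int8)

    order = np.lexsort((year_arr, pid))
    pid, year_arr = pid[order], year_arr[order]
    age_arr, state_arr = age_arr[order], state_arr[order]

    boundary = np.flatnonzero(pid[1:] != pid[:-1]) + 1
    starts = np.concatenate(([0], boundary)).astype(np.int64)
    ends = np.concatenate((boundary, [pid.size]))
    counts = (ends - starts).astype(np.int64)
    person_idx = pid[starts]
    width = len(str(max(n - 1, 1)))
    person_ids = np.array([f"p{i:0{width}d}" for i in person_idx], dtype=object)

    return StatePanel._from_packed(
        year_arr,
        age_arr.astype(np.int64),
        sex[pid],
        edu[pid],
        state_arr,
        starts,
        counts,
        person_ids,
    )


def _draw_coded(rng: np.random.Generator, n: int, weights: list[float]) -> np.ndarray:
    cum = np.cumsum(weights)
    codes = np.searchsorted(cum, rng.random(n), side="right").astype(np.int8)
    return np.clip(codes, 0, len(weights) - 1)


# ------------------------------------------------------------------- oracle


@dataclass
class MicrosimSummary:
    """Closed-cohort microsimulation results from exact age 60.

    ``mean_years`` carries the engine's half-year convention: the occupied
    person-years in the origin state are reduced by 0.5.  ``ever_entered``
    maps each horizon age to the share of trajectories that occupied each
    state at some age in (60, horizon].
    """

    origin: str
    stratum: Stratum
    n: int
    mean_years: dict[str, float]
    ever_entered: dict[int, dict[str, float]]


def microsimulate_summaries(
    spec: SyntheticModelSpec,
    stratum: Stratum,
    origin: str,
    n: int,
    seed: int,
    horizons: tuple[int, ...] = (80, 99),
) -> MicrosimSummary:
    """Simulate ``n`` closed trajectories from age 60 under the truth surface.

    Independent oracle for the matrix engine: no left truncation, no
    censoring; competing risks within a year are resolved by a single
    multinomial draw over the full destination row, exactly as in
    :func:`simulate_panel` and in the discrete-time chain itself.
    """
    if origin not in LIVING_STATES:
        raise SpecError(f"origin must be a living state, got {origin!r}")
    cum_rows = _cumulative_rows(surface_from_spec(spec, stratum))
    rng = np.random.default_rng(seed)

    state = np.full(n, STATE_INDEX[origin], dtype=np.int8)
    years = np.zeros(N_STATES, dtype=np.float64)
    ever = np.zeros((n, N_STATES), dtype=bool)
    snapshots: dict[int, dict[str, float]] = {}
    arange_n = np.arange(n)

    for step in range(N_AGES - 1):  # transitions 60->61 ... 98->99
        years += np.bincount(state, minlength=N_STATES)
        alive = np.flatnonzero(state != X)
        if alive.size:
            new_state = np.empty(alive.size, dtype=np.int8)
            for origin_code in range(N_LIVING):
                m = state[alive] == origin_code
                k = int(m.sum())
                if k == 0:
                    continue
                rows = np.broadcast_to(
                    cum_rows[step, origin_code, :], (k, N_STATES)
                )
                new_state[m] = _draw_destinations(rng, rows)
            state[alive] = new_state
        ever[arange_n, state] = True
        age_now = AGE_MIN + step + 1
        if age_now in horizons:
            snapshots[age_now] = {
                s: float(ever[:, STATE_INDEX[s]].mean()) for s in LIVING_STATES
            }
    years += np.bincount(state, minlength=N_STATES)  # age-99 occupancy
    if AGES[-1] in horizons and AGES[-1] not in snapshots:  # pragma: no cover
        snapshots[int(AGES[-1])] = {
            s: float(ever[:, STATE_INDEX[s]].mean()) for s in LIVING_STATES
        }

    mean_years = {s: years[STATE_INDEX[s]] / n for s in LIVING_STATES}
    mean_years[origin] -= 0.5
    return MicrosimSummary(
        origin=origin,
        stratum=stratum,
        n=n,
        mean_years=mean_years,
        ever_entered=snapshots,
    )


def with_overrides(spec: SyntheticModelSpec, **kwargs) -> SyntheticModelSpec:
    """A copy of ``spec`` with top-level fields replaced (e.g. n, seed)."""
    return replace(spec, **kwargs)
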