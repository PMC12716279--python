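"""Person-year state panels: data model, CSV round trip, validation, inclusion.

A panel is long format: one record per individual per calendar year, carrying
age (completed years, 60-99), sex, education, and the health state on record
at the end of that year.  Within a person, years are consecutive, age
advances by one per year, sex and education are constant, the state sequence
respects irreversibility, and death (``X``) is a single terminal record.
Individuals may enter the observation window at any age (left truncation)
and disappear without an ``X`` record (right censoring at period end).

Internally a :class:`StatePanel` stores packed, person-block-sorted integer
arrays; the pandas DataFrame view is materialized lazily.  This keeps the
trajectory bootstrap — which rebuilds panels thousands of times — cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import (
    AGE_MAX,
    AGE_MIN,
    ALLOWED,
    EDUCATIONS,
    SEXES,
    STATES,
    X,
)

CSV_COLUMNS: tuple[str, ...] = ("person_id", "year", "age", "sex", "education", "state")


class PanelError(ValueError):
    """Base class for panel problems."""


class PanelFormatError(PanelError):
    """A file or frame does not conform to the panel CSV schema."""


@dataclass(frozen=True)
class Violation:
    """One broken panel invariant, attributable to a person and rule."""

    person_id: str
    year: int | None
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" (year {self.year})" if self.year is not None else ""
        return f"person {self.person_id}{where}: [{self.rule}] {self.message}"


class PanelValidationError(PanelError):
    """Raised when a panel that must be valid is not."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        head = "; ".join(str(v) for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"{len(self.violations)} panel violation(s): {head}{more}")


def _block_gather(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Record indices for a sequence of person blocks (vectorized concat)."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    out[0] = starts[0]
    pos = np.cumsum(counts)[:-1]
    out[pos] = starts[1:] - (starts[:-1] + counts[:-1]) + 1
    return np.cumsum(out)


class StatePanel:
    """An immutable person-year panel sorted by (person_id, year).

    Construct from a DataFrame via :meth:`from_frame`, from disk via
    :func:`read_panel`, or let :func:`hearspan.synthetic.simulate_panel`
    build one.  Equality (:meth:`equals`) compares record content.
    """

    __slots__ = (
        "year",
        "age",
        "sex_code",
        "edu_code",
        "state_code",
        "starts",
        "counts",
        "person_ids",
        "_df",
    )

    def __init__(self, *args, **kwargs):
        raise TypeError("use StatePanel.from_frame(df) or read_panel(path)")

    # ------------------------------------------------------------------ build

    @classmethod
    def _from_packed(
        cls,
        year: np.ndarray,
        age: np.ndarray,
        sex_code: np.ndarray,
        edu_code: np.ndarray,
        state_code: np.ndarray,
        starts: np.ndarray,
        counts: np.ndarray,
        person_ids: np.ndarray,
    ) -> "StatePanel":
        self = object.__new__(cls)
        self.year = year
        self.age = age
        self.sex_code = sex_code
        self.edu_code = edu_code
        self.state_code = state_code
        self.starts = starts
        self.counts = counts
        self.person_ids = person_ids
        self._df = None
        return self

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "StatePanel":
        """Pack a schema-conformant DataFrame into a panel.

        Raises :class:`PanelFormatError` for schema problems (missing
        columns, non-integer years, unknown categorical values) and, when
        ``validate`` is true, :class:`PanelValidationError` if any panel
        invariant is broken.
        """
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"missing column(s): {', '.join(missing)}")

        pid = df["person_id"].astype(str).to_numpy()
        year = _int_column(df, "year")
        age = _int_column(df, "age")
        sex_code = _coded_column(df, "sex", SEXES)
        edu_code = _coded_column(df, "education", EDUCATIONS)
        state_code = _coded_column(df, "state", STATES)

        order = np.lexsort((year, pid))
        pid = pid[order]
        year = year[order]
        age = age[order]
        sex_code = sex_code[order]
        edu_code = edu_code[order]
        state_code = state_code[order]

        if pid.size:
            boundary = np.flatnonzero(pid[1:] != pid[:-1]) + 1
            starts = np.concatenate(([0], boundary)).astype(np.int64)
            ends = np.concatenate((boundary, [pid.size]))
            counts = (ends - starts).astype(np.int64)
            person_ids = pid[starts]
        else:
            starts = np.empty(0, dtype=np.int64)
            counts = np.empty(0, dtype=np.int64)
            person_ids = np.empty(0, dtype=pid.dtype)

        panel = cls._from_packed(
            year, age, sex_code, edu_code, state_code, starts, counts, person_ids
        )
        if validate:
            violations = validate_panel(panel)
            if violations:
                raise PanelValidationError(violations)
        return panel

    @classmethod
    def empty(cls) -> "StatePanel":
        return cls.from_frame(pd.DataFrame(columns=list(CSV_COLUMNS)), validate=False)

    # -------------------------------------------------------------- properties

    @property
    def n_records(self) -> int:
        return int(self.year.size)

    @property
    def n_persons(self) -> int:
        return int(self.starts.size)

    @property
    def person_years(self) -> int:
        """Living person-years contributed (records with state != X)."""
        return int(np.count_nonzero(self.state_code != X))

    @property
    def df(self) -> pd.DataFrame:
        """DataFrame view in canonical (person_id, year) order."""
        if self._df is None:
            self._df = pd.DataFrame(
                {
                    "person_id": np.repeat(self.person_ids.astype(str), self.counts)
                    if self.n_records
                    else np.empty(0, dtype=str),
                    "year": self.year,
                    "age": self.age,
                    "sex": np.asarray(SEXES, dtype=object)[self.sex_code]
                    if self.n_records
                    else np.empty(0, dtype=object),
                    "education": np.asarray(EDUCATIONS, dtype=object)[self.edu_code]
                    if self.n_records
                    else np.empty(0, dtype=object),
                    "state": np.asarray(STATES, dtype=object)[self.state_code]
                    if self.n_records
                    else np.empty(0, dtype=object),
                }
            )
        return self._df

    def equals(self, other: "StatePanel") -> bool:
        return (
            self.n_records == other.n_records
            and np.array_equal(self.person_ids.astype(str), other.person_ids.astype(str))
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.year, other.year)
            and np.array_equal(self.age, other.age)
            and np.array_equal(self.sex_code, other.sex_code)
            and np.array_equal(self.edu_code, other.edu_code)
            and np.array_equal(self.state_code, other.state_code)
        )

    # ---------------------------------------------------------------- persons

    def take_persons(self, person_indices: np.ndarray, relabel: bool = False) -> "StatePanel":
        """Panel restricted to (or resampled over) the given person indices.

        With ``relabel=True`` the selected persons receive fresh sequential
        identifiers, which makes it safe to select the same person more than
        once — the with-replacement bootstrap relies on this.
        """
        idx = np.asarray(person_indices, dtype=np.int64)
        starts = self.starts[idx]
        counts = self.counts[idx]
        gather = _block_gather(starts, counts)
        new_starts = np.concatenate(([0], np.cumsum(counts)[:-1])).astype(np.int64)
        if relabel:
            width = max(1, len(str(max(idx.size - 1, 0))))
            ids = np.array([f"b{i:0{width}d}" for i in range(idx.size)], dtype=object)
        else:
            ids = self.person_ids[idx]
        return StatePanel._from_packed(
            self.year[gather],
            self.age[gather],
            self.sex_code[gather],
            self.edu_code[gather],
            self.state_code[gather],
            new_starts,
            counts,
            ids,
        )

    def last_of_block(self) -> np.ndarray:
        """Boolean mask marking each person's final record."""
        mask = np.zeros(self.n_records, dtype=bool)
        if self.n_records:
            mask[self.starts + self.counts - 1] = True
        return mask


def _int_column(df: pd.DataFrame, name: str) -> np.ndarray:
    col = pd.to_numeric(df[name], errors="coerce")
    bad = col.isna() | (col != np.floor(col.fillna(0)))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PanelFormatError(f"non-integer value in column {name!r} at data row {row + 1}")
    return col.to_numpy(dtype=np.int64)


def _coded_column(df: pd.DataFrame, name: str, categories: Iterable[str]) -> np.ndarray:
    codes = pd.Categorical(df[name].astype(str), categories=list(categories)).codes
    codes = np.asarray(codes, dtype=np.int8)
    if (codes < 0).any():
        row = int(np.flatnonzero(codes < 0)[0])
        value = df[name].iloc[row]
        raise PanelFormatError(
            f"unknown value {value!r} in column {name!r} at data row {row + 1}"
        )
    return codes


# ---------------------------------------------------------------------- io


def read_panel(path: str | Path) -> StatePanel:
    """Read and validate a person-year panel CSV.

    The header must be exactly ``person_id,year,age,sex,education,state``.
    Malformed rows raise :class:`PanelFormatError` naming the offending row;
    invariant violations raise :class:`PanelValidationError` naming the
    person and rule.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header != ",".join(CSV_COLUMNS):
        raise PanelFormatError(
            f"bad header in {path}: expected {','.join(CSV_COLUMNS)!r}, got {header!r}"
        )
    df = pd.read_csv(path, dtype={"person_id": str})
    return StatePanel.from_frame(df, validate=True)


def write_panel(panel: StatePanel, path: str | Path) -> None:
    """Write a panel as UTF-8 CSV in canonical order (round-trip identity)."""
    panel.df.to_csv(Path(path), index=False)


# --------------------------------------------------------------- validation


def validate_panel(panel: StatePanel) -> list[Violation]:
    """Check every panel invariant; return all violations (never raises).

    Rules reported: ``age_out_of_range``, ``non_consecutive_years``,
    ``age_year_mismatch``, ``inconsistent_stratum``, ``transition_mask``,
    ``death_not_terminal``.
    """
    v: list[Violation] = []
    if panel.n_records == 0:
        return v
    pid = np.repeat(panel.person_ids.astype(str), panel.counts)

    bad_age = (panel.age < AGE_MIN) | (panel.age > AGE_MAX)
    for i in np.flatnonzero(bad_age):
        v.append(
            Violation(pid[i], int(panel.year[i]), "age_out_of_range",
                      f"age {int(panel.age[i])} outside [{AGE_MIN}, {AGE_MAX}]")
        )

    last = panel.last_of_block()
    nxt = ~last  # record i and i+1 belong to the same person

    i = np.flatnonzero(nxt & np.concatenate((panel.year[1:] - panel.year[:-1] != 1, [False])))
    for k in i:
        v.append(
            Violation(pid[k], int(panel.year[k]), "non_consecutive_years",
                      f"non-consecutive years {int(panel.year[k])} -> {int(panel.year[k + 1])}")
        )

    i = np.flatnonzero(nxt & np.concatenate((panel.age[1:] - panel.age[:-1] != 1, [False])))
    for k in i:
        v.append(
            Violation(pid[k], int(panel.year[k]), "age_year_mismatch",
                      f"age must advance by 1 per year, got "
                      f"{int(panel.age[k])} -> {int(panel.age[k + 1])}")
        )

    same = np.concatenate(
        ((panel.sex_code[1:] == panel.sex_code[:-1])
         & (panel.edu_code[1:] == panel.edu_code[:-1]), [True])
    )
    for k in np.flatnonzero(nxt & ~same):
        v.append(
            Violation(pid[k], int(panel.year[k + 1]), "inconsistent_stratum",
                      "sex and education must be constant within a person")
        )

    ok = np.concatenate((ALLOWED[panel.state_code[:-1], panel.state_code[1:]], [True]))
    for k in np.flatnonzero(nxt & ~ok):
        v.append(
            Violation(pid[k], int(panel.year[k]), "transition_mask",
                      f"forbidden transition {STATES[panel.state_code[k]]} -> "
                      f"{STATES[panel.state_code[k + 1]]} (TransitionMask)")
        )

    for k in np.flatnonzero((panel.state_code == X) & ~last):
        v.append(
            Violation(pid[k], int(panel.year[k]), "death_not_terminal",
                      "records present after a death (X) record")
        )
    return v


# ---------------------------------------------------------------- inclusion


def apply_inclusion_rule(panel: StatePanel) -> StatePanel:
    """Restrict to persons contributing records in at least two calendar years.

    Deterministic and idempotent; matches the study-inclusion rule used to
    define the analytical sample.
    """
    keep = np.flatnonzero(panel.counts >= 2)
    if keep.size == panel.n_persons:
        return panel
    return panel.take_persons(keep)
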