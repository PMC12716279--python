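"""State space, age range, and stratification for the five-state model.

The model tracks movement between four living states — healthy (``H``),
hearing loss (``L``), dementia (``D``), and their comorbidity (``C``) — and
death (``X``), over single years of age from 60 to 99.  Morbidity is
irreversible: an acquired condition is never lost, and death is absorbing.
The allowed-transition mask below encodes exactly that structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Ordered state labels; the index of each label is its matrix position.
STATES: tuple[str, ...] = ("H", "L", "D", "C", "X")
LIVING_STATES: tuple[str, ...] = ("H", "L", "D", "C")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
H, L, D, C, X = range(5)
N_STATES = 5
N_LIVING = 4

AGE_MIN = 60
AGE_MAX = 99
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGES.size  # 40 single-year ages

SEXES: tuple[str, ...] = ("male", "female")
EDUCATIONS: tuple[str, ...] = ("none", "secondary", "tertiary")

#: Ordered (origin, destination) pairs a trajectory may realize.
ALLOWED_TRANSITIONS: frozenset[tuple[str, str]] = frozenset(
    {
        ("H", "H"), ("H", "L"), ("H", "D"), ("H", "C"), ("H", "X"),
        ("L", "L"), ("L", "C"), ("L", "X"),
        ("D", "D"), ("D", "C"), ("D", "X"),
        ("C", "C"), ("C", "X"),
        ("X", "X"),
    }
)

#: Boolean 5x5 mask, ``ALLOWED[i, j]`` true iff i -> j is a legal move.
ALLOWED = np.zeros((N_STATES, N_STATES), dtype=bool)
for _i, _j in ALLOWED_TRANSITIONS:
    ALLOWED[STATE_INDEX[_i], STATE_INDEX[_j]] = True
ALLOWED.setflags(write=False)


class StratumError(ValueError):
    """Raised for an unknown sex or education level."""


@dataclass(frozen=True)
class Stratum:
    """A (sex, education) cell of the population; ``"all"`` pools a dimension."""

    sex: str = "all"
    education: str = "all"

    def __post_init__(self) -> None:
        if self.sex not in SEXES + ("all",):
            raise StratumError(f"unknown sex {self.sex!r}")
        if self.education not in EDUCATIONS + ("all",):
            raise StratumError(f"unknown education {self.education!r}")

    @property
    def label(self) -> str:
        return f"{self.sex}:{self.education}"

    @classmethod
    def from_label(cls, label: str) -> "Stratum":
        sex, _, education = label.partition(":")
        return cls(sex or "all", education or "all")

    def record_mask(self, sex_code: np.ndarray, edu_code: np.ndarray) -> np.ndarray:
        """Boolean mask over records with the given integer sex/education codes."""
        mask = np.ones(sex_code.shape, dtype=bool)
        if self.sex != "all":
            mask &= sex_code == SEXES.index(self.sex)
        if self.education != "all":
            mask &= edu_code == EDUCATIONS.index(self.education)
        return mask


#: The fully pooled population.
ALL_STRATA = Stratum("all", "all")


def concrete_strata() -> list[Stratum]:
    """The six fully specified (sex, education) cells."""
    return [Stratum(s, e) for s in SEXES for e in EDUCATIONS]
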