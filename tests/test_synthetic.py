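"""Synthetic register: truth surfaces, panel simulation, microsim oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hearspan import (
    Stratum,
    build_default_spec,
    conditional_expectancies,
    microsimulate_summaries,
    simulate_panel,
    surface_from_spec,
    tabulate_transitions,
    validate_panel,
)
from hearspan.states import AGES, STATE_INDEX
from hearspan.synthetic import (
    GompertzMortality,
    IncidenceCurve,
    SpecError,
    SyntheticModelSpec,
    with_overrides,
)


def constant_mortality_spec(q: float, n: int = 1000, seed: int = 5,
                            incidence: dict | None = None) -> SyntheticModelSpec:
    """Single-living-state style spec: constant death probability q, no onset."""
    spec = build_default_spec(n_individuals=n, seed=seed)
    return with_overrides(
        spec,
        mortality=GompertzMortality(
            a=q, b=0.0, state_multipliers={"H": 1.0, "L": 1.0, "D": 1.0, "C": 1.0}
        ),
        incidence=incidence or {},
        start_state_weights={
            "male": {"H": 1.0, "L": 0.0, "D": 0.0, "C": 0.0},
            "female": {"H": 1.0, "L": 0.0, "D": 0.0, "C": 0.0},
        },
    )


# ------------------------------------------------------------- default spec


def test_default_start_state_weights(default_spec):
    m = default_spec.start_state_weights["male"]
    f = default_spec.start_state_weights["female"]
    assert m["H"] == pytest.approx(0.925)
    assert m["L"] == pytest.approx(0.058)
    assert m["D"] + m["C"] == pytest.approx(0.017)
    assert f["H"] == pytest.approx(0.932)
    assert f["L"] == pytest.approx(0.057)
    # dementia/comorbid split follows the entry composition
    assert m["D"] / m["C"] == pytest.approx(2.4 / 0.5)


def test_hearing_loss_adds_no_mortality(default_spec):
    r = default_spec.mortality.state_multipliers
    assert r["H"] == r["L"]
    assert r["D"] > r["L"] and r["C"] > r["L"]


def test_comorbidity_incidence_from_hl_dominates(default_spec):
    """p(L->C) exceeds p(H->D) and p(D->C) at every age, for both sexes."""
    for sex in ("male", "female"):
        lc = default_spec.incidence["L>C"].probability(AGES, sex)
        hd = default_spec.incidence["H>D"].probability(AGES, sex)
        dc = default_spec.incidence["D>C"].probability(AGES, sex)
        assert np.all(lc > hd)
        assert np.all(lc > dc)


def test_default_spec_passes_invariants(default_spec):
    default_spec.validate()


def test_spec_yaml_round_trip(default_spec, tmp_path):
    path = tmp_path / "spec.yaml"
    default_spec.to_yaml(path)
    back = SyntheticModelSpec.from_yaml(path)
    assert back.to_dict() == default_spec.to_dict()


# ------------------------------------------------------------ truth surface


def test_gompertz_scalar_evaluation():
    """q_D(70) = a * e^{b*(70-60)} * r_D for a=0.01, b=0.1, r_D=2.5."""
    spec = with_overrides(
        build_default_spec(),
        mortality=GompertzMortality(
            a=0.01, b=0.1, state_multipliers={"H": 1.0, "L": 1.0, "D": 2.5, "C": 2.5}
        ),
        incidence={},
        cap="rescale",  # this steep curve tops out above age 96
    )
    surface = surface_from_spec(spec, Stratum("all", "all"))
    q_d_70 = surface.matrix(70)[STATE_INDEX["D"], STATE_INDEX["X"]]
    assert q_d_70 == pytest.approx(0.01 * math.exp(1.0) * 2.5, abs=1e-15)


def test_zero_spec_gives_identity_matrices():
    spec = constant_mortality_spec(q=0.0)
    surface = surface_from_spec(spec, Stratum("male", "none"))
    assert np.allclose(surface.probs, np.broadcast_to(np.eye(5), (40, 5, 5)))


def test_default_surface_rows_sum_to_one(default_spec):
    surface = surface_from_spec(default_spec, Stratum("male", "all"))
    assert np.abs(surface.probs.sum(axis=2) - 1.0).max() < 1e-12
    surface.validate()


def test_overflow_cap_error_names_age_and_state(default_spec):
    hot = with_overrides(
        default_spec,
        mortality=GompertzMortality(
            a=0.5, b=0.1, state_multipliers={"H": 1.0, "L": 1.0, "D": 4.0, "C": 4.0}
        ),
    )
    with pytest.raises(SpecError, match=r"exceeds 1 at age \d+, origin state \w"):
        surface_from_spec(hot, Stratum("male", "none"))


def test_overflow_cap_rescale_renormalizes(default_spec):
    hot = with_overrides(
        default_spec,
        cap="rescale",
        mortality=GompertzMortality(
            a=0.5, b=0.1, state_multipliers={"H": 1.0, "L": 1.0, "D": 4.0, "C": 4.0}
        ),
    )
    surface = surface_from_spec(hot, Stratum("male", "none"))
    surface.validate()
    # the overflowing dementia row at the top age has no stay mass left
    assert surface.matrix(99)[STATE_INDEX["D"], STATE_INDEX["D"]] == pytest.approx(0.0)


# --------------------------------------------------------------- simulation


def test_same_seed_same_panel(default_spec):
    spec = with_overrides(default_spec, n_individuals=500, seed=11)
    assert simulate_panel(spec).equals(simulate_panel(spec))
    other = simulate_panel(with_overrides(spec, seed=12))
    assert not simulate_panel(spec).equals(other)


def test_forced_absorption_gives_two_record_trajectories():
    """With q = 1 everywhere, every trajectory is entry followed by death."""
    spec = constant_mortality_spec(q=1.0, n=300)
    entry_age = np.zeros(40)
    entry_age[0] = 1.0  # everyone enters at 60, well clear of the 99 closure
    entry_year = np.zeros(len(spec.entry_year_weights))
    entry_year[0] = 1.0
    spec = with_overrides(
        spec, entry_age_weights=entry_age.tolist(), entry_year_weights=entry_year.tolist()
    )
    panel = simulate_panel(spec)
    assert panel.n_persons == 300
    assert np.all(panel.counts == 2)
    assert np.all(panel.state_code[panel.last_of_block()] == STATE_INDEX["X"])


def test_simulated_transition_share_matches_truth(default_spec):
    """The share of H->L moves at age 60 among male pairs is binomial around
    the truth surface's p_HL(60)."""
    spec = with_overrides(default_spec, n_individuals=100_000, seed=909)
    panel = simulate_panel(spec)
    counts = tabulate_transitions(panel, Stratum("male", "all"))
    h, l = STATE_INDEX["H"], STATE_INDEX["L"]
    exposure = counts.exposures[0, h]
    share = counts.counts[0, h, l] / exposure
    p = surface_from_spec(default_spec, Stratum("male", "all")).matrix(60)[h, l]
    se = math.sqrt(p * (1 - p) / exposure)
    assert abs(share - p) < 3 * se


@pytest.mark.parametrize("seed", [1, 77])
def test_simulated_panels_are_grammatical(default_spec, seed):
    panel = simulate_panel(with_overrides(default_spec, n_individuals=2_000, seed=seed))
    assert validate_panel(panel) == []
    assert int(panel.age.max()) <= 99


# ------------------------------------------------------------------- oracle


def test_microsim_zero_spec_means_39_5_years():
    spec = constant_mortality_spec(q=0.0)
    s = microsimulate_summaries(spec, Stratum("male", "none"), "H", n=100, seed=3)
    assert s.mean_years["H"] == pytest.approx(39.5)
    assert all(s.ever_entered[h][j] == 0.0 for h in (80, 99) for j in ("L", "D", "C"))


def test_microsim_constant_death_geometric_series():
    """Constant q = 0.5: mean total years = sum 0.5^t - 0.5 ~ 1.5."""
    spec = constant_mortality_spec(q=0.5)
    s = microsimulate_summaries(spec, Stratum("all", "all"), "H", n=100_000, seed=9)
    total = sum(s.mean_years.values())
    expected = 2.0 * (1 - 0.5**40) - 0.5
    assert abs(total - expected) < 0.02  # ~5 Monte-Carlo standard errors


def test_microsim_hl_origin_reaches_comorbidity_more(default_spec):
    """Ever-entered comorbidity is higher from the HL origin than from healthy."""
    st = Stratum("female", "all")
    from_l = microsimulate_summaries(default_spec, st, "L", n=30_000, seed=21)
    from_h = microsimulate_summaries(default_spec, st, "H", n=30_000, seed=21)
    assert from_l.ever_entered[99]["C"] > from_h.ever_entered[99]["C"]


def test_total_years_from_dementia_non_increasing_in_its_mortality(default_spec):
    """Raising the dementia mortality multiplier cannot lengthen life from D."""
    les = []
    for r_d in (1.4, 1.8, 2.2):
        mult = dict(default_spec.mortality.state_multipliers)
        mult["D"] = r_d
        spec = with_overrides(
            default_spec,
            mortality=GompertzMortality(
                a=default_spec.mortality.a,
                b=default_spec.mortality.b,
                state_multipliers=mult,
                sex_multipliers=default_spec.mortality.sex_multipliers,
                education_multipliers=default_spec.mortality.education_multipliers,
            ),
        )
        surface = surface_from_spec(spec, Stratum("male", "all"))
        les.append(conditional_expectancies(surface).conditional_le("D"))
    assert les[0] >= les[1] >= les[2]
    # hearing-loss mortality is untouched by the dementia multiplier
    spec_hi = with_overrides(
        default_spec,
        mortality=GompertzMortality(
            a=default_spec.mortality.a,
            b=default_spec.mortality.b,
            state_multipliers={**default_spec.mortality.state_multipliers, "D": 1.4},
            sex_multipliers=default_spec.mortality.sex_multipliers,
            education_multipliers=default_spec.mortality.education_multipliers,
        ),
    )
    s_lo = surface_from_spec(default_spec, Stratum("male", "all"))
    s_hi = surface_from_spec(spec_hi, Stratum("male", "all"))
    l, x = STATE_INDEX["L"], STATE_INDEX["X"]
    assert np.allclose(s_lo.probs[:, l, x], s_hi.probs[:, l, x])
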