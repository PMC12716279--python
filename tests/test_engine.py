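"""Occupancy, fundamental matrices, and state expectancies."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hearspan import (
    Stratum,
    TransitionSurface,
    build_transient_supermatrix,
    conditional_expectancies,
    fundamental_matrix,
    occupancy_from_fundamental,
    occupancy_profile,
    random_surface,
    unconditional_expectancies,
)
from hearspan.engine import EngineError
from hearspan.estimation import StartingDistribution
from hearspan.states import ALLOWED, LIVING_STATES, N_AGES, N_STATES, STATE_INDEX


def identity_living_surface() -> TransitionSurface:
    probs = np.broadcast_to(np.eye(N_STATES), (N_AGES, N_STATES, N_STATES)).copy()
    return TransitionSurface(probs)


def single_state_surface(q: float) -> TransitionSurface:
    """Healthy-or-dead chain with constant annual death probability q."""
    probs = np.zeros((N_AGES, N_STATES, N_STATES))
    probs[:, 0, 0] = 1.0 - q
    probs[:, 0, 4] = q
    for i in (1, 2, 3, 4):
        probs[:, i, i] = 1.0
    return TransitionSurface(probs)


def three_age_toy_surface() -> TransitionSurface:
    """Nontrivial dynamics on ages 60-62, identity-living afterwards."""
    probs = np.broadcast_to(np.eye(N_STATES), (N_AGES, N_STATES, N_STATES)).copy()
    probs[0] = [
        [0.70, 0.10, 0.10, 0.05, 0.05],
        [0.00, 0.80, 0.00, 0.15, 0.05],
        [0.00, 0.00, 0.70, 0.20, 0.10],
        [0.00, 0.00, 0.00, 0.85, 0.15],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ]
    probs[1] = [
        [0.60, 0.20, 0.05, 0.05, 0.10],
        [0.00, 0.75, 0.00, 0.20, 0.05],
        [0.00, 0.00, 0.60, 0.25, 0.15],
        [0.00, 0.00, 0.00, 0.80, 0.20],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ]
    probs[2] = [
        [0.50, 0.25, 0.10, 0.05, 0.10],
        [0.00, 0.70, 0.00, 0.25, 0.05],
        [0.00, 0.00, 0.50, 0.30, 0.20],
        [0.00, 0.00, 0.00, 0.75, 0.25],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ]
    return TransitionSurface(probs)


def enumerate_paths(surface, origin, n_steps):
    """Exhaustive path-probability oracle: iterate over all state sequences."""
    start = STATE_INDEX[origin]
    dist = {tuple([start]): 1.0}
    for step in range(n_steps):
        new = {}
        for path, p in dist.items():
            for j in range(N_STATES):
                pj = surface.probs[step, path[-1], j]
                if pj > 0:
                    new[path + (j,)] = new.get(path + (j,), 0.0) + p * pj
        dist = new
    return dist


# ---------------------------------------------------------------- occupancy


def test_identity_surface_point_mass():
    prof = occupancy_profile(identity_living_surface(), "L")
    expected = np.zeros(N_STATES)
    expected[STATE_INDEX["L"]] = 1.0
    assert np.array_equal(prof.dist, np.tile(expected, (N_AGES, 1)))


def test_immediate_death_surface():
    prof = occupancy_profile(single_state_surface(1.0), "H")
    assert prof.dist[0, 0] == 1.0
    assert np.all(prof.dist[1:, STATE_INDEX["X"]] == 1.0)


def test_occupancy_rejects_dead_origin():
    with pytest.raises(EngineError):
        occupancy_profile(identity_living_surface(), "X")


def test_toy_surface_occupancy_matches_path_enumeration():
    surface = three_age_toy_surface()
    for origin in LIVING_STATES:
        paths = enumerate_paths(surface, origin, 3)
        prof = occupancy_profile(surface, origin)
        for age_idx in (1, 2, 3):
            marginal = np.zeros(N_STATES)
            for path, p in paths.items():
                marginal[path[age_idx]] += p
            assert np.allclose(prof.dist[age_idx], marginal, atol=1e-14)


# --------------------------------------------------------- fundamental matrix


def test_supermatrix_shape_and_substochastic(rng):
    surface = random_surface(rng)
    U = build_transient_supermatrix(surface)
    assert U.shape == (160, 160)
    assert np.all(U >= 0)
    assert np.all(U.sum(axis=1) <= 1 + 1e-12)
    # only the age -> age+1 superdiagonal blocks are populated
    for k in range(N_AGES):
        for m in range(N_AGES):
            if m != k + 1:
                block = U[k * 4 : (k + 1) * 4, m * 4 : (m + 1) * 4]
                assert np.all(block == 0)


def test_fundamental_of_zero_is_identity():
    assert np.array_equal(fundamental_matrix(np.zeros((8, 8))), np.eye(8))


def test_identity_shift_row_sums_are_ages_remaining():
    """Deathless identity chain: from (60, i) every age 60-99 is occupied."""
    U = build_transient_supermatrix(identity_living_surface())
    N = fundamental_matrix(U)
    for origin in LIVING_STATES:
        assert N[STATE_INDEX[origin], :].sum() == pytest.approx(N_AGES)


def test_single_state_chain_geometric_row_sum():
    U = build_transient_supermatrix(single_state_surface(0.5))
    N = fundamental_matrix(U)
    assert N[0, :].sum() == pytest.approx(2.0 - 0.5**39, abs=1e-12)


def test_fundamental_entries_match_path_enumeration():
    surface = three_age_toy_surface()
    N = fundamental_matrix(build_transient_supermatrix(surface))
    paths = enumerate_paths(surface, "H", 3)
    occ = occupancy_from_fundamental(N, "H")
    for age_idx in (0, 1, 2, 3):
        for j, state in enumerate(LIVING_STATES):
            expected = sum(
                p for path, p in paths.items() if path[age_idx] == STATE_INDEX[state]
            )
            assert occ[age_idx, j] == pytest.approx(expected, abs=1e-12)


@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_fundamental_equals_iterative_occupancy(seed):
    """Two algorithms, one answer, on arbitrary mask-respecting surfaces."""
    surface = random_surface(np.random.default_rng(seed))
    N = fundamental_matrix(build_transient_supermatrix(surface))
    for origin in LIVING_STATES:
        via_n = occupancy_from_fundamental(N, origin)
        via_recursion = occupancy_profile(surface, origin).dist[:, :4]
        assert np.abs(via_n - via_recursion).max() < 1e-10


# ------------------------------------------------------------- expectancies


def test_forced_death_expectancy_is_half_year():
    table = conditional_expectancies(single_state_surface(1.0))
    assert table.expectancy("H", "H") == pytest.approx(0.5)
    assert table.conditional_le("H") == pytest.approx(0.5)


def test_deathless_expectancy_is_39_5():
    table = conditional_expectancies(identity_living_surface())
    assert table.expectancy("H", "H") == pytest.approx(39.5)
    assert table.expectancy("H", "L") == 0.0
    assert table.expectancy("H", "D") == 0.0
    assert table.expectancy("H", "C") == 0.0


@pytest.mark.parametrize("q", [0.01, 0.1, 0.5, 1.0])
def test_constant_mortality_closed_form(q):
    table = conditional_expectancies(single_state_surface(q))
    expected = (1.0 - (1.0 - q) ** 40) / q - 0.5
    assert abs(table.conditional_le("H") - expected) < 1e-12


def test_conservation_of_person_years(rng):
    """sum_j e_j(60|i) + correction equals total survival mass."""
    surface = random_surface(rng)
    table = conditional_expectancies(surface)
    for origin in LIVING_STATES:
        prof = occupancy_profile(surface, origin)
        assert table.conditional_le(origin) + 0.5 == pytest.approx(
            prof.survival().sum(), abs=1e-12
        )


def test_more_death_never_lengthens_life(rng):
    surface = random_surface(rng)
    worse = surface.copy()
    # shift stay mass into death in every living row, where possible
    for i in range(4):
        shift = np.minimum(worse.probs[:, i, i], 0.05)
        worse.probs[:, i, i] -= shift
        worse.probs[:, i, 4] += shift
    worse.validate()
    base = conditional_expectancies(surface)
    bad = conditional_expectancies(worse)
    for origin in LIVING_STATES:
        assert bad.conditional_le(origin) <= base.conditional_le(origin) + 1e-12


def test_unconditional_point_mass_and_average():
    surface = three_age_toy_surface()
    table = conditional_expectancies(surface)
    point = StartingDistribution(
        stratum=Stratum(), weights=np.array([1.0, 0, 0, 0]), window=(60, 65), n_person_years=1
    )
    full = unconditional_expectancies(table, point)
    assert np.allclose(full.unconditional, table.conditional[0])
    half = StartingDistribution(
        stratum=Stratum(), weights=np.array([0.5, 0.5, 0, 0]), window=(60, 65), n_person_years=2
    )
    mixed = unconditional_expectancies(table, half)
    assert mixed.overall_le == pytest.approx(
        0.5 * table.conditional_le("H") + 0.5 * table.conditional_le("L")
    )
    # independent dot product
    assert np.allclose(
        mixed.unconditional, half.weights @ table.conditional, atol=1e-15
    )


def test_expectancy_frame_has_all_cells():
    surface = three_age_toy_surface()
    w = StartingDistribution(
        stratum=Stratum(), weights=np.array([0.9, 0.05, 0.03, 0.02]),
        window=(60, 65), n_person_years=100,
    )
    df = unconditional_expectancies(conditional_expectancies(surface), w).to_frame()
    assert set(df["origin"]) == {"H", "L", "D", "C", "weighted"}
    assert set(df["state"]) == {"H", "L", "D", "C", "total"}
    # conditional totals are exact row sums
    for origin in LIVING_STATES:
        sub = df[df["origin"] == origin]
        states = sub[sub["state"] != "total"]["years"].sum()
        total = sub[sub["state"] == "total"]["years"].iloc[0]
        assert states == pytest.approx(total, abs=1e-12)
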