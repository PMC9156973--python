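import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polopulse import (
    PulseSpec,
    RateParameters,
    SpeciesState,
    compute_observables,
    default_parameters,
    default_pulse,
    model1_rhs,
    read_trajectory,
    reference_rk4,
    run_two_cycle,
    simulate_model1,
    write_trajectory,
)
from polopulse.species import SPECIES, initial_state

from conftest import end_of_s_index

amounts = st.floats(0.0, 5.0, allow_nan=False)
rates = st.floats(0.0, 10.0, allow_nan=False)


@st.composite
def random_params(draw):
    values = {name: draw(rates) for name in RateParameters.field_names()}
    values["k_dephos_S"] = values["k_destab"] + draw(st.floats(0.01, 10.0))
    return RateParameters(**values)


@st.composite
def random_state(draw):
    return SpeciesState(**{name: draw(amounts) for name in SPECIES})


def test_all_rates_zero_gives_zero_derivatives():
    zeroed = {
        name: 0.0
        for name in RateParameters.field_names()
        if name.startswith(("k_", "gamma")) and name != "k_dephos_S"
    }
    # k_dephos_S stays tiny but positive to satisfy the fast/slow invariant;
    # with S_star = 0 it contributes no flux
    p = default_parameters().replace(**zeroed, k_dephos_S=0.01)
    state = SpeciesState(S=1.0, RS_free=0.5, P=1.0, C=2.0)
    dy = model1_rhs(state, 0.0, p, drive=1.0)
    assert all(getattr(dy, name) == 0.0 for name in SPECIES)


def test_single_binding_reaction_hand_evaluated():
    # S + RS_free -> RS_bound at k_bind * S * RS_free, nothing else active
    zeroed = {
        name: 0.0
        for name in RateParameters.field_names()
        if name.startswith(("k_", "gamma")) and name not in ("k_bind", "k_dephos_S")
    }
    p = default_parameters().replace(**zeroed, k_bind=1.0, k_dephos_S=0.01)
    dy = model1_rhs(SpeciesState(S=1.0, RS_free=1.0), 0.0, p, drive=0.0)
    assert dy.RS_bound == pytest.approx(1.0)
    assert dy.S == pytest.approx(-1.0)
    assert dy.RS_free == pytest.approx(-1.0)
    assert all(
        getattr(dy, name) == 0.0 for name in SPECIES if name not in ("S", "RS_free", "RS_bound")
    )


@settings(derandomize=True, max_examples=50, deadline=None)
@given(state=random_state(), p=random_params(), drive=st.floats(0.0, 5.0))
def test_derivatives_conserve_every_pool(state, p, drive):
    dy = model1_rhs(state, 0.0, p, drive)
    tol = 1e-9
    assert abs(dy.S + dy.RS_bound + dy.S_star + dy.S_bar) < tol      # Spd-2
    assert abs(dy.C + dy.S_bar + dy.C_star) < tol                    # Cnn
    assert abs(dy.RS_free + dy.RS_bound) < tol                       # Spd-2 receptor
    assert abs(dy.P + dy.S_bar) < tol                                # Polo (imposed mode)


def test_negative_state_rejected_with_field_named():
    state = SpeciesState(S=1.0, S_star=-0.5)
    with pytest.raises(ValueError, match="S_star"):
        model1_rhs(state, 0.0, default_parameters(), drive=0.0)


def test_negative_drive_rejected():
    with pytest.raises(ValueError, match="drive"):
        model1_rhs(SpeciesState(S=1.0), 0.0, default_parameters(), drive=-1.0)


def test_zero_drive_builds_no_scaffold(params):
    traj = simulate_model1(params, PulseSpec(amplitude=0.0), duration=10.0)
    assert np.allclose(traj.total_spd2, 0.0, atol=1e-12)
    assert np.allclose(traj.total_cnn, 0.0, atol=1e-12)


def test_conservation_drift_below_1e6(imposed_cycle):
    assert max(imposed_cycle.conservation_drift().values()) <= 1e-6


def test_species_stay_nonnegative(imposed_cycle):
    assert imposed_cycle.states.min() >= -1e-9


def test_adaptive_solution_matches_fixed_step_oracle(params):
    """Brute-force RK4 at dt=1e-3 min agrees with the adaptive integrator."""
    pulse = default_pulse()
    adaptive = simulate_model1(params, pulse, 15.0)
    oracle = reference_rk4(params, 15.0, initial_state(params, coupled=False), dt=1e-3, spec=pulse)
    assert np.allclose(adaptive.times, oracle.times)
    scale = np.maximum(np.abs(oracle.states).max(axis=0), 1e-12)
    assert (np.abs(adaptive.states - oracle.states) / scale).max() < 1e-4


def test_peak_ordering_polo_spd2_cnn(imposed_cycle):
    """Polo peaks first, then Spd-2, then Cnn over the cycle."""
    t = imposed_cycle.times
    assert (
        t[np.argmax(imposed_cycle.total_polo)]
        < t[np.argmax(imposed_cycle.total_spd2)]
        < t[np.argmax(imposed_cycle.total_cnn)]
    )


def test_cnn_keeps_growing_after_polo_peak(imposed_cycle):
    cnn = imposed_cycle.total_cnn
    i_polo = int(np.argmax(imposed_cycle.total_polo))
    assert cnn[end_of_s_index(imposed_cycle)] >= cnn[i_polo]


def test_observable_definitions_arithmetic(params):
    state = SpeciesState(S_star=2.0, S_bar=3.0, C_star=5.0)
    traj = simulate_model1(params, PulseSpec(amplitude=0.0), 0.1, init=state)
    traj.drive = np.ones_like(traj.times)  # imposed drive of 1 at every sample
    obs = compute_observables(traj)
    assert obs["total_polo"].iloc[0] == pytest.approx(4.0)
    assert obs["total_spd2"].iloc[0] == pytest.approx(5.0)
    assert obs["total_cnn"].iloc[0] == pytest.approx(8.0)


def test_peak_spd2_monotone_in_pulse_amplitude(params):
    peaks = [
        run_two_cycle(params, mode="imposed", pulse=default_pulse(amplitude=a)).total_spd2.max()
        for a in np.linspace(0.25, 2.0, 5)
    ]
    assert np.all(np.diff(peaks) >= 0)


def test_trajectory_table_round_trip(tmp_path, imposed_cycle):
    path = tmp_path / "traj.tsv"
    write_trajectory(imposed_cycle, path)
    df = read_trajectory(path)
    original = imposed_cycle.to_frame()
    assert list(df.columns) == list(original.columns)
    assert np.array_equal(df.to_numpy(), original.to_numpy())
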