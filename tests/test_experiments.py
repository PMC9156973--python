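import numpy as np
import pytest

from polopulse import (
    default_parameters,
    default_pulse,
    dose_sweep,
    halve_pool,
    perturb_recruitment,
    polo_metrics,
    qualitative_features,
    robustness_scan,
    run_two_cycle,
    sweep_to_frame,
)

from conftest import end_of_s_index


def test_second_cycle_starts_with_half_the_final_pcm(params):
    first, second = run_two_cycle(params, mode="imposed", return_first=True)
    assert second.total_cnn[0] == pytest.approx(0.5 * first.total_cnn[-1], rel=1e-6)
    assert second.total_cnn[0] > 0  # centrosomes inherit scaffold from the previous cycle


def test_zero_drive_first_cycle_leaves_no_inheritance(params):
    traj = run_two_cycle(params, mode="imposed", pulse=default_pulse(amplitude=0.0))
    assert traj.total_cnn[0] == 0.0
    assert traj.total_spd2[0] == 0.0


def test_receptors_reset_at_cycle_boundary(params):
    second = run_two_cycle(params, mode="coupled")
    assert second.species("R_occ")[0] == 0.0
    assert second.species("R_off")[0] == pytest.approx(params.RP_tot)


def test_two_cycle_mode_validated(params):
    with pytest.raises(ValueError):
        run_two_cycle(params, mode="nope")


def test_halve_pool_targets_one_total(params):
    assert halve_pool(params, "spd2").S_tot == params.S_tot / 2
    assert halve_pool(params, "ana1").RP_tot == params.RP_tot / 2
    assert halve_pool(params, "spd2").RP_tot == params.RP_tot
    with pytest.raises(KeyError):
        halve_pool(params, "cnn")


def test_halving_then_doubling_restores_params(params):
    assert halve_pool(params, "spd2").scale("S_tot", 2.0) == params


def test_ana1_half_dose_ends_s_phase_with_more_polo(params):
    """Fewer centriolar receptors are inactivated more slowly, so the pulse
    peaks later and more Polo remains at the end of S-phase."""
    wt = polo_metrics(run_two_cycle(params, mode="coupled"))
    half = polo_metrics(run_two_cycle(halve_pool(params, "ana1"), mode="coupled"))
    assert half["peak_time"] > wt["peak_time"]
    assert half["final_amount"] > wt["final_amount"]


def test_spd2_half_dose_reduces_polo_recruitment(params):
    wt = polo_metrics(run_two_cycle(params, mode="coupled"))
    half = polo_metrics(run_two_cycle(halve_pool(params, "spd2"), mode="coupled"))
    assert half["peak_amount"] < wt["peak_amount"]
    assert half["final_amount"] < wt["final_amount"]


def test_perturb_recruitment_identity_and_errors(params):
    assert perturb_recruitment(params, "centriole", 1.0) == params
    with pytest.raises(KeyError):
        perturb_recruitment(params, "cytoplasm", 0.5)
    with pytest.raises(ValueError):
        perturb_recruitment(params, "pcm", 0.0)


def test_impaired_centriole_recruitment_slows_and_delays_pulse(params):
    wt = run_two_cycle(params, mode="coupled")
    mut = run_two_cycle(perturb_recruitment(params, "centriole", 0.25), mode="coupled")
    i2 = int(round(2.0 / 0.05))
    assert (mut.total_polo[i2] - mut.total_polo[0]) < (wt.total_polo[i2] - wt.total_polo[0])
    assert polo_metrics(mut)["peak_time"] > polo_metrics(wt)["peak_time"]


def test_impaired_pcm_recruitment_lowers_pulse_amplitude(params):
    wt = polo_metrics(run_two_cycle(params, mode="coupled"))
    mut = polo_metrics(run_two_cycle(perturb_recruitment(params, "pcm", 0.25), mode="coupled"))
    assert mut["peak_amount"] < wt["peak_amount"]


def test_robustness_control_row_passes(params):
    df = robustness_scan(params, factors=(), include_control=True, mode="imposed")
    control = df[df.parameter == "none"].iloc[0]
    assert control.spd2_pulse and control.cnn_plateau


def test_extreme_cnn_disassembly_breaks_the_plateau(params):
    df = robustness_scan(
        params, factors=(1e6,), rates=("k_dephos_C",), include_control=False, mode="imposed"
    )
    assert not df.iloc[0].cnn_plateau


def test_robustness_scan_shape_and_error_capture(params):
    df = robustness_scan(params, factors=(0.5, 2.0), rates=("k_bind", "k_inh"), mode="coupled")
    assert len(df) == 5  # control + 2 rates x 2 factors
    assert (df.error == "").all()
    with pytest.raises(ValueError):
        robustness_scan(params, factors=(0.0,))


def test_sweep_grid_validation(params):
    with pytest.raises(ValueError, match="within"):
        dose_sweep(params, "ana1", grid=np.array([0.4, 1.0]))
    with pytest.raises(ValueError, match="identity"):
        dose_sweep(params, "ana1", grid=np.array([0.5, 2.0]))


def test_sweep_identity_factor_matches_direct_half_dose(params):
    res = dose_sweep(params, "spd2", grid=np.array([1.0]), rates=("k_bind",))
    wt = polo_metrics(run_two_cycle(params, mode="coupled"))
    half = polo_metrics(run_two_cycle(halve_pool(params, "spd2"), mode="coupled"))
    for metric in ("peak_amount", "peak_time", "final_amount"):
        assert res[0].ratios[metric][0] == pytest.approx(half[metric] / wt[metric], rel=1e-9)


def test_sweep_is_deterministic(params):
    a = sweep_to_frame(dose_sweep(params, "ana1", grid=np.array([0.5, 1.0]), rates=("k_inh",)))
    b = sweep_to_frame(dose_sweep(params, "ana1", grid=np.array([0.5, 1.0]), rates=("k_inh",)))
    assert a.equals(b)


def test_qualitative_features_requires_s_phase_annotation(params):
    from polopulse import simulate_coupled

    traj = simulate_coupled(params, 5.0)  # no s_phase_min attached
    with pytest.raises(ValueError):
        qualitative_features(traj)
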