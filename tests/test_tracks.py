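import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polopulse import (
    CentrosomeTrack,
    default_parameters,
    extract_pulse_features,
    fit_cnn_model,
    growth_vs_sphase_correlation,
    pair_centrosomes,
    peak_time_difference,
    read_tracks,
    simulate_model1,
    tracks_to_frame,
    write_tracks,
)
from polopulse.experiments import default_pulse
from polopulse.synth import gen_cnn_tracks


def make_track(times, intensities, cid="c0", **kwargs):
    return CentrosomeTrack("e0", cid, np.asarray(times, float), np.asarray(intensities, float), **kwargs)


def test_track_invariants_enforced():
    with pytest.raises(ValueError, match="5 timepoints"):
        make_track([0, 1, 2], [1, 2, 3])
    with pytest.raises(ValueError, match="increasing"):
        make_track([0, 1, 1, 2, 3], [1, 2, 3, 4, 5])
    with pytest.raises(ValueError, match="non-negative"):
        make_track([0, 1, 2, 3, 4], [1, -2, 3, 4, 5])


def test_growth_rate_formula_arithmetic():
    # initial 10, maximum 40 reached 15 minutes later -> 2 units/min
    t = np.linspace(0, 20, 21)
    y = np.concatenate([np.linspace(10, 40, 16), np.linspace(40, 20, 5)[:5]])
    f = extract_pulse_features(make_track(t, y), smoothing_window=1)
    assert f.initial_intensity == 10
    assert f.maximum_intensity == 40
    assert f.growth_period == pytest.approx(15.0)
    assert f.growth_rate == pytest.approx(2.0)
    assert not f.peak_at_boundary


def test_constant_track_flagged_with_zero_rate():
    f = extract_pulse_features(make_track(np.arange(6), np.full(6, 7.0)))
    assert f.growth_rate == 0.0
    assert f.peak_at_boundary


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    shift=st.floats(-20, 20),
    scale=st.floats(0.1, 50),
)
def test_features_equivariant_under_time_shift_and_intensity_scale(shift, scale):
    t = np.linspace(0, 10, 21)
    y = 5 + 3 * np.exp(-0.5 * (t - 6.0) ** 2)
    base = extract_pulse_features(make_track(t, y))
    moved = extract_pulse_features(make_track(t + shift, y * scale))
    assert moved.peak_time == pytest.approx(base.peak_time + shift, abs=1e-9)
    assert moved.growth_period == pytest.approx(base.growth_period)
    assert moved.growth_rate == pytest.approx(base.growth_rate * scale, rel=1e-9)


def test_peak_time_recovered_from_noisy_model_tracks():
    """Tracks sampled from a model trajectory with a known peak recover the
    peak time (sub-sample refinement) to within one sample interval in
    >= 95% of replicates."""
    params = default_parameters()
    pulse = default_pulse(s_phase_min=16.0)  # drive peaking at 8 min
    traj = simulate_model1(params, pulse, 16.0)
    sample_t = np.arange(0.0, 16.0 + 1e-9, 0.5)
    clean = np.interp(sample_t, traj.times, traj.total_polo)
    true_peak = traj.times[np.argmax(traj.total_polo)]
    rng = np.random.default_rng(42)
    hits = 0
    n = 200
    for _ in range(n):
        noisy = clean * np.exp(0.05 * rng.standard_normal(clean.size))
        f = extract_pulse_features(make_track(sample_t, noisy), smoothing_window=3, refine_peak=True)
        hits += abs(f.peak_time - true_peak) <= 0.5 + 1e-9
    assert hits / n >= 0.95


@pytest.mark.parametrize(
    "kind,expect_tb",
    [("linear", None), ("linear_plateau", 6.0), ("linear_decrease", 6.0)],
)
def test_noiseless_archetypes_fit_exactly(kind, expect_tb):
    t = np.linspace(0, 12, 25)
    if kind == "linear":
        y = 2 * t + 1.0
    elif kind == "linear_plateau":
        y = 1.0 + 2 * np.minimum(t, 6.0)
    else:
        y = 1.0 + 2 * np.minimum(t, 6.0) - 1.0 * np.maximum(t - 6.0, 0.0)
    fit = fit_cnn_model(make_track(t, y))
    assert fit.selected == kind
    assert fit.slopes["rise"] == pytest.approx(2.0, abs=1e-6)
    if expect_tb is not None:
        assert fit.breakpoint == pytest.approx(expect_tb, abs=1e-3)
    if kind == "linear_decrease":
        assert fit.slopes["fall"] == pytest.approx(-1.0, abs=1e-6)


def test_cnn_fit_requires_enough_points():
    with pytest.raises(ValueError, match="8 timepoints"):
        fit_cnn_model(make_track(np.arange(6), np.arange(6) + 1.0))


def test_near_noiseless_one_phase_data_never_selects_two_phase():
    tracks, _ = gen_cnn_tracks("linear", n_tracks=20, noise_cv=0.001, seed=0)
    assert all(fit_cnn_model(tr).selected == "linear" for tr in tracks)


def test_model_selection_accuracy_on_noisy_cohorts():
    for kind in ("linear", "linear_plateau", "linear_decrease"):
        tracks, _ = gen_cnn_tracks(kind, n_tracks=60, noise_cv=0.05, seed=1)
        acc = np.mean([fit_cnn_model(tr).selected == kind for tr in tracks])
        assert acc >= 0.9, f"{kind}: {acc}"


def test_peak_time_difference_trivial_cases():
    t = np.linspace(0, 10, 21)
    y = np.exp(-0.5 * (t - 4.0) ** 2)
    a = make_track(t, y)
    assert peak_time_difference(a, a) == 0.0
    shifted = make_track(t + 2.5, y, cid="c1")
    assert peak_time_difference(shifted, a) == pytest.approx(2.5)


def test_polo_track_peaks_before_spd2_track(coupled_cycle):
    """On noiseless tracks sampled from the model, the Polo channel peaks
    before the Spd-2 channel."""
    t = np.arange(0.0, 15.0 + 1e-9, 0.5)
    polo = make_track(t, np.interp(t, coupled_cycle.times, coupled_cycle.total_polo), cid="polo")
    spd2 = make_track(t, np.interp(t, coupled_cycle.times, coupled_cycle.total_spd2), cid="spd2")
    assert peak_time_difference(polo, spd2) < 0


def test_peak_time_difference_requires_overlap():
    t = np.linspace(0, 10, 21)
    y = np.exp(-0.5 * (t - 4.0) ** 2)
    with pytest.raises(ValueError, match="overlap"):
        peak_time_difference(make_track(t, y), make_track(t + 100, y, cid="c1"))


def _positioned(cid, xy, level):
    t = np.linspace(-5, 0, 6)
    return CentrosomeTrack(
        "e0", cid, t, np.full(6, float(level)),
        phases=np.full(6, "S"),
        positions=np.tile(xy, (6, 1)).astype(float),
    )


def test_pairing_brighter_is_old_mother():
    tracks = [_positioned("c0", [0.0, 0.0], 10.0), _positioned("c1", [1.0, 0.0], 6.0)]
    out = pair_centrosomes(tracks, distance_threshold=2.0)
    labels = dict(zip(out.centrosome_id, out.label))
    assert labels == {"c0": "OM", "c1": "NM"}


def test_pairing_beyond_threshold_is_unassigned():
    tracks = [_positioned("c0", [0.0, 0.0], 10.0), _positioned("c1", [5.0, 0.0], 6.0)]
    out = pair_centrosomes(tracks, distance_threshold=2.0)
    assert set(out.label) == {"unassigned"}


def test_pairing_is_order_invariant_and_tie_deterministic():
    tracks = [
        _positioned("c0", [0.0, 0.0], 5.0),
        _positioned("c1", [1.0, 0.0], 5.0),  # intensity tie -> lower id is OM
        _positioned("c2", [10.0, 0.0], 8.0),
        _positioned("c3", [11.0, 0.0], 3.0),
    ]
    out1 = pair_centrosomes(tracks, 2.0)
    out2 = pair_centrosomes(tracks[::-1], 2.0)
    assert out1.equals(out2)
    labels = dict(zip(out1.centrosome_id, out1.label))
    assert labels["c0"] == "OM" and labels["c1"] == "NM"
    assert labels["c2"] == "OM" and labels["c3"] == "NM"


def test_correlation_trivial_and_degenerate_cases():
    pairs = [(1, 2), (2, 4), (3, 6), (4, 8), (5, 10)]
    res = growth_vs_sphase_correlation(pairs)
    assert res["pearson_r"] == pytest.approx(1.0)
    assert res["r_squared"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(2.0)
    with pytest.raises(ValueError, match="zero-variance"):
        growth_vs_sphase_correlation([(1, 2)] * 6)
    with pytest.raises(ValueError, match="at least 5"):
        growth_vs_sphase_correlation([(1, 2), (2, 3), (3, 5), (4, 6)])


def test_track_table_round_trip(tmp_path):
    t = np.linspace(-5, 0, 6)
    tracks = [
        CentrosomeTrack(
            "e0", "c0", t, np.linspace(1, 2, 6),
            phases=np.full(6, "S"),
            positions=np.column_stack([t, t * 0 + 1.0]),
            mother_class="OM",
        )
    ]
    path = tmp_path / "tracks.tsv"
    write_tracks(tracks, path)
    back = read_tracks(path)
    assert len(back) == 1
    assert np.array_equal(back[0].times, tracks[0].times)
    assert np.array_equal(back[0].intensities, tracks[0].intensities)
    assert np.array_equal(back[0].positions, tracks[0].positions)
    assert back[0].mother_class == "OM"
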