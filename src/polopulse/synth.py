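"""Synthetic live-imaging data with known ground truth.

Generates the fixture inputs every pipeline stage consumes: embryo cohorts
of centrosome-intensity tracks sampled from model trajectories (per-cycle
pulse pacing, S-phase lengthening across cycles 11-13, NEB-aligned times),
positioned OM/NM track pairs with planted brightness asymmetry, Cnn tracks
from the three growth-curve archetypes, and exponential-saturation FRAP
series.  Measurement noise is multiplicative log-normal with a stated
coefficient of variation (fluorescence intensities are positive and
heteroscedastic); every generator is a pure function of its parameters and
an integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiments import run_two_cycle
from .frap import FRAPSeries
from .params import RateParameters, default_parameters
from .pulse_model import CYCLE_KRON_FACTORS, CYCLE_S_PHASE_MIN, MITOSIS_MIN
from .tracks import CentrosomeTrack

__all__ = [
    "gen_embryo_cohort",
    "gen_cnn_tracks",
    "gen_paired_tracks",
    "gen_frap_series",
]

#: Default imaging interval for intensity tracks (seconds).
TRACK_INTERVAL_S = 30.0


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of
    variation ``cv`` (exactly 1.0 when cv = 0)."""
    sigma = np.sqrt(np.log1p(cv**2))
    draws = rng.normal(0.0, 1.0, n)
    return np.exp(sigma * draws - sigma**2 / 2)


def gen_embryo_cohort(
    params: RateParameters | None = None,
    n_embryos: int = 15,
    cycles: tuple[int, ...] = (11, 12, 13),
    noise_cv: float = 0.05,
    seed: int = 0,
    mode: str = "coupled",
    interval_s: float = TRACK_INTERVAL_S,
    sphase_jitter_cv: float = 0.05,
    proteins: tuple[str, ...] = ("polo", "spd2", "cnn"),
) -> tuple[list[CentrosomeTrack], pd.DataFrame]:
    """Simulate a cohort of embryos imaged over one nuclear cycle each.

    Embryos are assigned to ``cycles`` round-robin.  Each embryo draws a
    multiplicative S-phase-length jitter; the cell-cycle pace handle k_R_on
    is scaled by the per-cycle factor divided by the same jitter, so a
    slower oscillator lengthens S-phase and slows pulse growth together.
    Per-centrosome observables (total Polo/Spd-2/Cnn from the two-cycle
    protocol) are sampled at the imaging interval, noised multiplicatively
    and aligned to NEB (t = 0 at mitotic entry, S-phase negative).

    Returns the tracks plus a ground-truth table (per embryo and protein:
    S-phase length, true peak time from cycle start, true growth features).
    """
    if not 0.0 <= noise_cv <= 0.5:
        raise ValueError(f"noise_cv must be in [0, 0.5], got {noise_cv}")
    params = default_parameters() if params is None else params
    rng = np.random.default_rng(seed)
    tracks: list[CentrosomeTrack] = []
    truth_rows = []
    for e in range(n_embryos):
        cycle = cycles[e % len(cycles)]
        jitter = float(np.clip(rng.normal(0.0, sphase_jitter_cv), -0.3, 0.3))
        s_len = CYCLE_S_PHASE_MIN[cycle] * (1.0 + jitter)
        pace = CYCLE_KRON_FACTORS[cycle] / (1.0 + jitter)
        p = params.scale("k_R_on", pace)
        traj = run_two_cycle(p, mode=mode, s_phase_min=s_len, mitosis_min=MITOSIS_MIN)
        dt = interval_s / 60.0
        sample_t = np.arange(0.0, s_len + MITOSIS_MIN + 1e-9, dt)
        observables = {
            "polo": traj.total_polo,
            "spd2": traj.total_spd2,
            "cnn": traj.total_cnn,
        }
        embryo_id = f"e{e:03d}"
        for protein in proteins:
            clean_dense = observables[protein]
            clean = np.interp(sample_t, traj.times, clean_dense)
            noisy = clean * _noise_factors(rng, noise_cv, clean.size)
            t_rel = sample_t - s_len
            phases = np.where(t_rel < 0, "S", "M")
            tracks.append(
                CentrosomeTrack(
                    embryo_id=embryo_id,
                    centrosome_id=f"{embryo_id}_{protein}",
                    times=t_rel,
                    intensities=noisy,
                    phases=phases,
                )
            )
            i_peak = int(np.argmax(clean_dense))
            peak_time = float(traj.times[i_peak])
            initial = float(clean_dense[0])
            maximum = float(clean_dense[i_peak])
            period = peak_time if peak_time > 0 else float(traj.times[-1])
            truth_rows.append(
                {
                    "embryo_id": embryo_id,
                    "protein": protein,
                    "cycle": cycle,
                    "s_phase_len": s_len,
                    "peak_time": peak_time,
                    "initial_intensity": initial,
                    "maximum_intensity": maximum,
                    "growth_period": period,
                    "growth_rate": (maximum - initial) / period,
                }
            )
    return tracks, pd.DataFrame(truth_rows)


def gen_cnn_tracks(
    model: str,
    n_tracks: int = 200,
    noise_cv: float = 0.05,
    seed: int = 0,
    slope: float = 2.0,
    breakpoint: float = 6.0,
    fall_slope: float = -1.0,
    intercept: float = 2.0,
    duration: float = 12.0,
    interval_s: float = TRACK_INTERVAL_S,
) -> tuple[list[CentrosomeTrack], pd.DataFrame]:
    """Cnn tracks drawn from one growth-curve archetype.

    ``model`` is ``linear`` (steady rise, cycle-11-like), ``linear_plateau``
    (rise then plateau, cycle-12-like) or ``linear_decrease`` (rise then
    fall, cycle-13-like); noise is multiplicative log-normal.
    """
    if model not in ("linear", "linear_plateau", "linear_decrease"):
        raise ValueError(f"unknown growth-curve model {model!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-9, interval_s / 60.0)
    if model == "linear":
        clean = intercept + slope * t
    elif model == "linear_plateau":
        clean = intercept + slope * np.minimum(t, breakpoint)
    else:
        clean = (
            intercept
            + slope * np.minimum(t, breakpoint)
            + fall_slope * np.maximum(t - breakpoint, 0.0)
        )
    if np.any(clean < 0):
        raise ValueError("archetype dips below zero; adjust slopes/intercept")
    tracks = []
    rows = []
    for i in range(n_tracks):
        noisy = clean * _noise_factors(rng, noise_cv, clean.size)
        cid = f"cnn{i:04d}"
        tracks.append(
            CentrosomeTrack(
                embryo_id=cid,
                centrosome_id=cid,
                times=t - duration,
                intensities=noisy,
                phases=np.full(t.size, "S"),
            )
        )
        rows.append({"centrosome_id": cid, "model": model, "breakpoint": breakpoint})
    return tracks, pd.DataFrame(rows)


def gen_paired_tracks(
    n_pairs: int = 20,
    om_nm_ratio: float = 1.5,
    position_jitter: float = 0.2,
    seed: int = 0,
    pair_distance: float = 1.0,
    grid_spacing: float = 8.0,
    nm_intensity: float = 5.0,
    intensity_cv: float = 0.05,
    n_timepoints: int = 6,
    interval_min: float = 0.5,
) -> tuple[list[CentrosomeTrack], pd.DataFrame]:
    """Positioned OM/NM centrosome pairs with planted ground truth.

    Pairs sit on a sparse grid (``grid_spacing`` micrometres apart, far
    beyond any sensible pairing threshold) with the two partners
    ``pair_distance`` apart; every recorded position is jittered by
    isotropic Gaussian noise of SD ``position_jitter``.  The old mother
    starts ``om_nm_ratio``-fold brighter than the new mother.
    """
    if om_nm_ratio <= 1:
        raise ValueError(f"om_nm_ratio must exceed 1, got {om_nm_ratio}")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_pairs)))
    t = np.arange(n_timepoints) * interval_min - n_timepoints * interval_min
    tracks = []
    rows = []
    for pair in range(n_pairs):
        cx = (pair % side) * grid_spacing
        cy = (pair // side) * grid_spacing
        base_nm = nm_intensity * float(_noise_factors(rng, 0.1, 1)[0])
        for which, sign in (("OM", -1.0), ("NM", +1.0)):
            level = base_nm * (om_nm_ratio if which == "OM" else 1.0)
            intens = level * (1.0 + 0.05 * np.arange(n_timepoints)) * _noise_factors(
                rng, intensity_cv, n_timepoints
            )
            pos = np.column_stack(
                [
                    cx + sign * pair_distance / 2 + rng.normal(0, position_jitter, n_timepoints),
                    cy + rng.normal(0, position_jitter, n_timepoints),
                ]
            )
            cid = f"p{pair:03d}_{which.lower()}"
            tracks.append(
                CentrosomeTrack(
                    embryo_id="e000",
                    centrosome_id=cid,
                    times=t,
                    intensities=intens,
                    phases=np.full(n_timepoints, "S"),
                    positions=pos,
                )
            )
            rows.append({"centrosome_id": cid, "pair_id": pair, "label": which})
    return tracks, pd.DataFrame(rows)


#: Imaging intervals used in the FRAP experiments, per protein (seconds).
FRAP_INTERVALS_S = {"polo": 4.0, "spd2": 15.0, "cnn": 30.0}


def gen_frap_series(
    k: float = 0.0693,
    amplitude: float = 1.0,
    baseline: float = 0.1,
    interval: float = FRAP_INTERVALS_S["polo"],
    duration: float = 60.0,
    noise_cv: float = 0.05,
    n_curves: int = 1,
    seed: int = 0,
    protein: str = "polo",
    cycle: int = 12,
) -> tuple[list[FRAPSeries], pd.DataFrame]:
    """Exponential-saturation FRAP recovery series with known parameters."""
    if interval >= duration:
        raise ValueError("sampling interval must be shorter than the series duration")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-9, interval)
    clean = baseline + amplitude * (1.0 - np.exp(-k * t))
    series = []
    rows = []
    for i in range(n_curves):
        noisy = clean * _noise_factors(rng, noise_cv, t.size)
        sid = f"frap{i:04d}"
        series.append(
            FRAPSeries(times=t, intensities=noisy, protein=protein, cycle=cycle, series_id=sid)
        )
        rows.append(
            {
                "series_id": sid,
                "protein": protein,
                "cycle": cycle,
                "k": k,
                "amplitude": amplitude,
                "baseline": baseline,
                "t_half": float(np.log(2) / k),
                "initial_rate": amplitude * k,
            }
        )
    return series, pd.DataFrame(rows)
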