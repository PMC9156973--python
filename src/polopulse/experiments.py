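"""In-silico experiments on the pulse and scaffold models.

Implements the two-cycle simulation protocol (a burn-in cycle from zero
scaffold, PCM split between two centrosomes at the boundary, report the
second cycle), half-dose genetics (halving a conserved pool total),
recruitment-mutant analogues (scaling a recruitment rate), the 2-fold
robustness scan of qualitative model behaviour, and the 0.5-2x parameter
sweep comparing wild-type against half-dose conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SWEEP_RATES, RateParameters
from .pulse import PulseSpec
from .pulse_model import MITOSIS_MIN, simulate_coupled
from .scaffold_model import Trajectory, simulate_model1
from .species import SpeciesState, initial_state

__all__ = [
    "run_two_cycle",
    "halve_pool",
    "perturb_recruitment",
    "polo_metrics",
    "qualitative_features",
    "robustness_scan",
    "dose_sweep",
    "SweepResult",
    "sweep_to_frame",
    "default_pulse",
]

DEFAULT_S_PHASE_MIN = 12.0


def default_pulse(s_phase_min: float = DEFAULT_S_PHASE_MIN, amplitude: float = 1.0) -> PulseSpec:
    """Imposed pulse for one cycle: zero at cycle start, peak at mid-S-phase,
    back to zero at the S/M boundary."""
    return PulseSpec(amplitude=amplitude, t_peak=s_phase_min / 2, width=s_phase_min / 2)


def _split_state(final: SpeciesState, params: RateParameters, coupled: bool) -> SpeciesState:
    """Cycle-boundary bookkeeping: each of the two daughter centrosomes keeps
    half of the centrosomal scaffold; cytoplasmic pools are replenished so
    conservation holds; the Polo-receptor pool is reset to fully inactive
    (the reset happens during mitosis, between modelled cycles)."""
    rs_bound = final.RS_bound / 2
    s_star = final.S_star / 2
    s_bar = final.S_bar / 2
    c_star = final.C_star / 2
    state = SpeciesState(
        S=max(params.S_tot - rs_bound - s_star - s_bar, 0.0),
        RS_free=max(params.RS_tot - rs_bound, 0.0),
        RS_bound=rs_bound,
        S_star=s_star,
        S_bar=s_bar,
        C=max(params.C_tot - s_bar - c_star, 0.0),
        C_star=c_star,
        P=max(params.P_tot - s_bar, 0.0),
    )
    if coupled:
        state = state.replace(R_off=params.RP_tot)
    return state


def run_two_cycle(
    params: RateParameters,
    mode: str = "imposed",
    pulse: PulseSpec | None = None,
    s_phase_min: float = DEFAULT_S_PHASE_MIN,
    mitosis_min: float = MITOSIS_MIN,
    return_first: bool = False,
    **integrate_kwargs,
) -> Trajectory | tuple[Trajectory, Trajectory]:
    """Two-cycle protocol; returns the second-cycle trajectory.

    The first cycle starts with all scaffolding components at zero.  At the
    boundary the accumulated PCM is divided between two new centrosomes
    (scaffold species halved), cytoplasmic pools are replenished to conserve
    totals, and — in coupled mode — the Polo receptor pool is re-initialised
    to fully inactive.  The imposed pulse (or the receptor activation)
    restarts from zero at the start of each cycle.
    """
    if mode not in ("imposed", "coupled"):
        raise ValueError(f"mode must be 'imposed' or 'coupled', got {mode!r}")
    duration = s_phase_min + mitosis_min
    coupled = mode == "coupled"
    if coupled:
        first = simulate_coupled(
            params, duration, s_phase_min=s_phase_min, **integrate_kwargs
        )
    else:
        pulse = default_pulse(s_phase_min) if pulse is None else pulse
        first = simulate_model1(
            params, pulse, duration, s_phase_min=s_phase_min, **integrate_kwargs
        )
    init2 = _split_state(first.final_state(), params, coupled)
    if coupled:
        second = simulate_coupled(
            params, duration, init=init2, s_phase_min=s_phase_min, **integrate_kwargs
        )
    else:
        second = simulate_model1(
            params, pulse, duration, init=init2, s_phase_min=s_phase_min, **integrate_kwargs
        )
    return (first, second) if return_first else second


def halve_pool(params: RateParameters, component: str) -> RateParameters:
    """Model a half-dose genetic background by halving one conserved pool:
    ``spd2`` halves total Spd-2, ``ana1`` halves the centriolar Polo-receptor
    pool."""
    pools = {"spd2": "S_tot", "ana1": "RP_tot"}
    if component not in pools:
        raise KeyError(f"unknown component {component!r}; known: {sorted(pools)}")
    return params.scale(pools[component], 0.5)


def perturb_recruitment(params: RateParameters, site: str, factor: float) -> RateParameters:
    """Recruitment-mutant analogue: scale Polo recruitment at the centriole
    (receptor Polo-loading rate k_P_on) or at the PCM (scaffold stabilisation
    rate k_stab) by ``factor``."""
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor!r}")
    sites = {"centriole": "k_P_on", "pcm": "k_stab"}
    if site not in sites:
        raise KeyError(f"unknown site {site!r}; known: {sorted(sites)}")
    return params.scale(sites[site], factor)


def _end_of_s_index(traj: Trajectory) -> int:
    if traj.s_phase_min is None:
        raise ValueError("trajectory carries no S-phase duration")
    return int(np.argmin(np.abs(traj.times - traj.s_phase_min)))


def polo_metrics(traj: Trajectory) -> dict[str, float]:
    """The three pulse read-outs: peak amount of total Polo, timing of the
    peak (minutes from cycle start) and the amount at the end of S-phase."""
    polo = traj.total_polo
    i_peak = int(np.argmax(polo))
    i_s = _end_of_s_index(traj)
    return {
        "peak_amount": float(polo[i_peak]),
        "peak_time": float(traj.times[i_peak]),
        "final_amount": float(polo[i_s]),
    }


def qualitative_features(traj: Trajectory) -> dict[str, float | bool]:
    """Qualitative behaviour of one cycle, evaluated on the dense grid.

    Checks the observed assembly signature: the Spd-2 total forms a pulse
    that follows the Polo pulse (Polo peaks first, both fall well below their
    peaks by the end of S-phase), while the Cnn total keeps growing or
    plateaus (peaking last, with at most a small drawdown before the end of
    S-phase).
    """
    i_s = _end_of_s_index(traj)
    polo, spd2, cnn = traj.total_polo, traj.total_spd2, traj.total_cnn
    t = traj.times
    t_polo = float(t[np.argmax(polo)])
    t_spd2 = float(t[np.argmax(spd2)])
    t_cnn = float(t[np.argmax(cnn)])
    frac_polo_end = float(polo[i_s] / polo.max()) if polo.max() > 0 else 1.0
    frac_spd2_end = float(spd2[i_s] / spd2.max()) if spd2.max() > 0 else 1.0
    cnn_s = cnn[: i_s + 1]
    i_pk = int(np.argmax(cnn_s))
    peak = float(cnn_s[i_pk])
    drawdown = float((peak - cnn_s[i_pk:].min()) / peak) if peak > 0 else 0.0
    spd2_pulse = t_polo < t_spd2 and frac_polo_end < 0.9 and frac_spd2_end < 0.9
    cnn_plateau = t_spd2 < t_cnn and drawdown <= 0.10
    return {
        "t_peak_polo": t_polo,
        "t_peak_spd2": t_spd2,
        "t_peak_cnn": t_cnn,
        "frac_polo_end": frac_polo_end,
        "frac_spd2_end": frac_spd2_end,
        "cnn_drawdown": drawdown,
        "spd2_pulse": spd2_pulse,
        "cnn_plateau": cnn_plateau,
    }


def robustness_scan(
    params: RateParameters,
    factors: tuple[float, ...] = (0.5, 2.0),
    mode: str = "imposed",
    rates: tuple[str, ...] = SWEEP_RATES,
    include_control: bool = True,
    **two_cycle_kwargs,
) -> pd.DataFrame:
    """Halve/double each reaction rate and flag the qualitative behaviour.

    Runs the two-cycle protocol for every (rate, factor) combination (plus an
    unperturbed control row) and records the qualitative feature flags.
    Integrator failures are recorded per run (``error`` column), not fatal.
    """
    if any(f <= 0 for f in factors):
        raise ValueError("perturbation factors must be positive")
    runs: list[tuple[str, float]] = []
    if include_control:
        runs.append(("none", 1.0))
    runs += [(name, f) for name in rates for f in factors]
    records = []
    for name, factor in runs:
        p = params if name == "none" else params.scale(name, factor)
        rec: dict = {"parameter": name, "factor": factor, "error": ""}
        try:
            traj = run_two_cycle(p, mode=mode, **two_cycle_kwargs)
            rec.update(qualitative_features(traj))
        except (RuntimeError, ValueError) as exc:
            rec.update({"spd2_pulse": False, "cnn_plateau": False, "error": str(exc)})
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class SweepResult:
    """Half-dose / wild-type metric ratios for one swept reaction rate."""

    parameter: str
    factors: tuple[float, ...]
    ratios: dict[str, tuple[float, ...]]  # metric -> per-factor half/WT ratio
    wt: dict[str, tuple[float, ...]]
    half: dict[str, tuple[float, ...]]


_METRICS = ("peak_amount", "peak_time", "final_amount")


def dose_sweep(
    params: RateParameters,
    component: str,
    grid: np.ndarray | None = None,
    rates: tuple[str, ...] = SWEEP_RATES,
    mode: str = "coupled",
    **two_cycle_kwargs,
) -> list[SweepResult]:
    """Vary each reaction rate over ``grid`` and compare WT vs half-dose runs.

    For every (rate, factor) pair, the two-cycle protocol is run under
    wild-type and half-dose (``component`` in {'spd2', 'ana1'}) conditions and
    the three Polo-pulse metrics are recorded as half-dose / WT ratios
    (a ratio < 1 means the half-dose condition has the lower value).
    """
    if grid is None:
        grid = np.geomspace(0.5, 2.0, 7)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0.5 - 1e-12 or grid.max() > 2.0 + 1e-12:
        raise ValueError("sweep grid must lie within [0.5, 2]")
    if not np.any(np.isclose(grid, 1.0)):
        raise ValueError("sweep grid must contain the identity factor 1.0")
    half_params = halve_pool(params, component)
    results = []
    for name in rates:
        wt: dict[str, list[float]] = {m: [] for m in _METRICS}
        half: dict[str, list[float]] = {m: [] for m in _METRICS}
        for factor in grid:
            m_wt = polo_metrics(
                run_two_cycle(params.scale(name, factor), mode=mode, **two_cycle_kwargs)
            )
            m_half = polo_metrics(
                run_two_cycle(half_params.scale(name, factor), mode=mode, **two_cycle_kwargs)
            )
            for m in _METRICS:
                wt[m].append(m_wt[m])
                half[m].append(m_half[m])
        ratios = {
            m: tuple(h / w for h, w in zip(half[m], wt[m])) for m in _METRICS
        }
        results.append(
            SweepResult(
                parameter=name,
                factors=tuple(grid),
                ratios=ratios,
                wt={m: tuple(v) for m, v in wt.items()},
                half={m: tuple(v) for m, v in half.items()},
            )
        )
    return results


def sweep_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Tidy table of sweep results: one row per (parameter, factor)."""
    records = []
    for res in results:
        for i, factor in enumerate(res.factors):
            rec = {"parameter": res.parameter, "factor": factor}
            for m in _METRICS:
                rec[f"wt_{m}"] = res.wt[m][i]
                rec[f"half_{m}"] = res.half[m][i]
                rec[f"ratio_{m}"] = res.ratios[m][i]
            records.append(rec)
    return pd.DataFrame.from_records(records)
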