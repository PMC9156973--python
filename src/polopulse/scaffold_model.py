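"""PCM-scaffold assembly model driven by a centriolar active-Polo input.

The model is a well-mixed mass-action reaction network.  A centriolar pool of
active Polo (the *drive*) phosphorylates receptor-bound Spd-2, releasing a
weak phospho-Spd-2 scaffold (S*) that either reverts rapidly or is stabilised
by binding cytoplasmic Polo and Cnn into a stable 1:1:1 scaffold unit (S-bar).
The stable scaffold catalytically converts Cnn into its own scaffold form
(C*), which disassembles at a baseline phosphatase rate that grows with
scaffold size.  Reactions:

    (1) S + RS_free  <-> RS_bound            k_bind * S * RS_free / k_unbind * RS_bound
    (2) RS_bound      -> S* + RS_free        k_phos_S * drive * RS_bound
    (3) S*            -> S                   k_dephos_S * S*
    (4) S* + P + C    -> S_bar               k_stab * S* * P * C
    (5) S_bar         -> S + P + C           k_destab * S_bar
    (6) S_bar         -> S* + P + C*         k_cat_C * S_bar
    (7) C*            -> C                   (k_dephos_C + gamma_C * C*) * C*

In imposed-pulse mode the drive is an external :class:`~polopulse.pulse.PulseSpec`
and is not drawn from the Polo pool; in coupled mode the drive is the
receptor-bound Polo ``R_occ`` produced by the pulse-generator reactions (see
:mod:`polopulse.pulse_model`) and Polo conservation includes the
receptor-bound pools: ``P + S_bar + R_occ + R_dead = P_tot``.

Observed totals mirror what a centrosomal fluorescence measurement sums over:
``total_polo = drive + S_bar``, ``total_spd2 = S* + S_bar``,
``total_cnn = S_bar + C*``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import RateParameters
from .pulse import PulseSpec, evaluate_pulse
from .species import IDX, SPECIES, SpeciesState, initial_state

__all__ = [
    "Trajectory",
    "model1_rhs",
    "simulate_model1",
    "compute_observables",
    "reference_rk4",
    "write_trajectory",
    "read_trajectory",
]

# default integration settings: stiff-capable adaptive method, dense output
GRID_DT = 0.05   # minutes
RTOL = 1e-8
ATOL = 1e-10


def _rhs(t: float, y: np.ndarray, p: RateParameters, drive_fn, coupled: bool) -> np.ndarray:
    """Mass-action right-hand side on the raw state vector."""
    S, RSf, RSb, Sst, Sbar, C, Cst, P, Roff, Ron, Rocc, Rdead = y
    drive = Rocc if coupled else drive_fn(t)

    v1f = p.k_bind * S * RSf
    v1r = p.k_unbind * RSb
    v2 = p.k_phos_S * drive * RSb
    v3 = p.k_dephos_S * Sst
    v4 = p.k_stab * Sst * P * C
    v5 = p.k_destab * Sbar
    v6 = p.k_cat_C * Sbar
    v7 = (p.k_dephos_C + p.gamma_C * Cst) * Cst

    dy = np.empty(12)
    dy[0] = -v1f + v1r + v3 + v5          # S
    dy[1] = -v1f + v1r + v2               # RS_free
    dy[2] = v1f - v1r - v2                # RS_bound
    dy[3] = v2 - v3 - v4 + v6             # S_star
    dy[4] = v4 - v5 - v6                  # S_bar
    dy[5] = -v4 + v5 + v7                 # C
    dy[6] = v6 - v7                       # C_star
    dy[7] = -v4 + v5 + v6                 # P

    if coupled:
        va = p.k_R_on * Roff
        vb = p.k_P_on * Ron * P
        vc = p.k_P_off * Rocc
        vd = p.k_inh * Rocc * (Rocc + Sbar)
        dy[8] = -va                       # R_off
        dy[9] = va - vb + vc              # R_on
        dy[10] = vb - vc - vd             # R_occ
        dy[11] = vd                       # R_dead (retains its bound Polo)
        dy[7] += -vb + vc                 # Polo exchanged with receptors
    else:
        dy[8:] = 0.0
    return dy


def _check_state(state: SpeciesState) -> None:
    for name in SPECIES:
        if getattr(state, name) < 0:
            raise ValueError(f"species {name!r} is negative: {getattr(state, name)!r}")


def model1_rhs(
    state: SpeciesState, t: float, params: RateParameters, drive: float
) -> SpeciesState:
    """Per-species rates of change of the scaffold model at one instant.

    ``drive`` is the centriolar active-Polo amount acting at time ``t``
    (external in imposed-pulse mode).  Receptor-state derivatives are zero;
    see :func:`polopulse.pulse_model.model2_rhs` for the pulse generator.
    """
    _check_state(state)
    if drive < 0:
        raise ValueError(f"drive must be non-negative, got {drive!r}")
    dy = _rhs(t, state.to_array(), params, lambda _t: drive, coupled=False)
    return SpeciesState.from_array(dy)


@dataclass
class Trajectory:
    """Dense model output: per-time species amounts, drive and observed totals."""

    times: np.ndarray                  # minutes, strictly increasing
    states: np.ndarray                 # shape (n_times, n_species)
    drive: np.ndarray                  # centriolar active Polo per time
    mode: str                          # "imposed" | "coupled"
    params: RateParameters
    s_phase_min: float | None = None   # end of S-phase, if the run models a cycle

    def species(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    @property
    def total_polo(self) -> np.ndarray:
        return self.drive + self.species("S_bar")

    @property
    def total_spd2(self) -> np.ndarray:
        return self.species("S_star") + self.species("S_bar")

    @property
    def total_cnn(self) -> np.ndarray:
        return self.species("S_bar") + self.species("C_star")

    def final_state(self) -> SpeciesState:
        return SpeciesState.from_array(self.states[-1])

    def conservation_drift(self) -> dict[str, float]:
        """Max relative drift of each conserved pool along the trajectory.

        Pools: Spd-2 (S + RS_bound + S* + S_bar), Cnn (C + S_bar + C*),
        Spd-2 receptor (RS_free + RS_bound), Polo receptor (four states), and
        Polo (P + S_bar, plus R_occ in coupled mode).  Drift is measured
        against the pool's initial value.
        """
        sp = self.species
        pools = {
            "spd2": sp("S") + sp("RS_bound") + sp("S_star") + sp("S_bar"),
            "cnn": sp("C") + sp("S_bar") + sp("C_star"),
            "rs_receptor": sp("RS_free") + sp("RS_bound"),
            "rp_receptor": sp("R_off") + sp("R_on") + sp("R_occ") + sp("R_dead"),
            "polo": sp("P")
            + sp("S_bar")
            + ((sp("R_occ") + sp("R_dead")) if self.mode == "coupled" else 0.0),
        }
        out = {}
        for name, series in pools.items():
            ref = series[0]
            scale = abs(ref) if abs(ref) > 0 else 1.0
            out[name] = float(np.max(np.abs(series - ref)) / scale)
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"time_min": self.times}
        for name in SPECIES:
            data[name] = self.species(name)
        data["drive"] = self.drive
        data["total_polo"] = self.total_polo
        data["total_spd2"] = self.total_spd2
        data["total_cnn"] = self.total_cnn
        return pd.DataFrame(data)


def compute_observables(traj: Trajectory) -> pd.DataFrame:
    """Observed centrosomal totals per timepoint.

    total_polo is the centriolar drive plus the Polo held in the stable
    scaffold (in coupled mode the drive *is* the receptor-bound Polo);
    total_spd2 sums Spd-2 in the weak and stable scaffolds; total_cnn sums
    Cnn in the stable scaffold and the Cnn scaffold proper.
    """
    return pd.DataFrame(
        {
            "time_min": traj.times,
            "total_polo": traj.total_polo,
            "total_spd2": traj.total_spd2,
            "total_cnn": traj.total_cnn,
        }
    )


def _integrate(
    params: RateParameters,
    drive_fn,
    coupled: bool,
    duration: float,
    init: SpeciesState,
    grid_dt: float,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration!r}")
    _check_state(init)
    t_eval = np.arange(0.0, duration + grid_dt / 2, grid_dt)
    t_eval[-1] = min(t_eval[-1], duration)
    sol = solve_ivp(
        _rhs,
        (0.0, duration),
        init.to_array(),
        args=(params, drive_fn, coupled),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t = {sol.t[-1]:.4f} min: {sol.message}")
    y = sol.y.T
    worst = y.min()
    if worst < -1e-9:
        name = SPECIES[int(np.unravel_index(np.argmin(y), y.shape)[1])]
        raise RuntimeError(f"species {name!r} went negative ({worst:.3e}) during integration")
    return sol.t, y


def simulate_model1(
    params: RateParameters,
    spec: PulseSpec,
    duration: float,
    init: SpeciesState | None = None,
    grid_dt: float = GRID_DT,
    rtol: float = RTOL,
    atol: float = ATOL,
    s_phase_min: float | None = None,
) -> Trajectory:
    """Integrate the scaffold model under an imposed centriolar Polo pulse.

    ``init`` defaults to a fresh cycle (all scaffold species zero, pools
    cytoplasmic).  Output is dense on a uniform ``grid_dt`` grid (minutes).
    """
    if init is None:
        init = initial_state(params, coupled=False)
    times, states = _integrate(
        params, lambda t: evaluate_pulse(t, spec), False, duration, init, grid_dt, rtol, atol
    )
    drive = np.asarray(evaluate_pulse(times, spec), dtype=float)
    return Trajectory(times, states, drive, "imposed", params, s_phase_min)


def reference_rk4(
    params: RateParameters,
    duration: float,
    init: SpeciesState,
    dt: float = 1e-3,
    spec: PulseSpec | None = None,
    coupled: bool = False,
    sample_every: int = 50,
) -> Trajectory:
    """Fixed-step classical 4th-order Runge-Kutta reference integration.

    Deliberately independent of the adaptive path: used as a brute-force
    oracle to validate :func:`simulate_model1` / ``simulate_coupled``.
    Samples are kept every ``sample_every`` steps (default: a 0.05-min grid
    for dt = 1e-3).
    """
    drive_fn = (lambda t: evaluate_pulse(t, spec)) if spec is not None else (lambda t: 0.0)
    n_steps = int(round(duration / dt))
    y = init.to_array()
    kept_t = [0.0]
    kept_y = [y.copy()]
    t = 0.0
    for i in range(n_steps):
        k1 = _rhs(t, y, params, drive_fn, coupled)
        k2 = _rhs(t + dt / 2, y + dt / 2 * k1, params, drive_fn, coupled)
        k3 = _rhs(t + dt / 2, y + dt / 2 * k2, params, drive_fn, coupled)
        k4 = _rhs(t + dt, y + dt * k3, params, drive_fn, coupled)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (i + 1) * dt
        if (i + 1) % sample_every == 0 or i + 1 == n_steps:
            kept_t.append(t)
            kept_y.append(y.copy())
    times = np.array(kept_t)
    states = np.array(kept_y)
    if coupled:
        drive = states[:, IDX["R_occ"]]
    elif spec is not None:
        drive = np.asarray(evaluate_pulse(times, spec), dtype=float)
    else:
        drive = np.zeros_like(times)
    return Trajectory(times, states, drive, "coupled" if coupled else "imposed", params)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as tab-delimited text (one row per timepoint)."""
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table written by :func:`write_trajectory`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
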