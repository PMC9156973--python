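"""Centriolar Polo-pulse generator and its coupling into the scaffold model.

A delayed negative feedback network at the mother centriole: an inactive Polo
receptor (R_off, Ana1-like) is activated by a cell-cycle-regulated kinase
(R_off -> R_on at k_R_on), active receptors load cytoplasmic Polo
(R_on + P -> R_occ), and the locally active Polo slowly phosphorylates
occupied receptors at additional sites, inactivating them irreversibly within
the cycle (R_occ -> R_dead).  The inactivated receptor is the *occupied*
off-state: its Polo stays bound (sequestered, no longer active) until the
receptor is reset by dephosphorylation during mitosis — which is outside the
modelled window, so within a cycle R_dead is an absorbing Polo sink.  Because
the activator creates its own inhibitor, receptor-bound Polo (R_occ) rises
and then falls — a pulse.  The inactivation rate is proportional to the
*total* locally active Polo, ``k_inh * R_occ * (R_occ + S_bar)``:
scaffold-bound Polo also feeds back on the centriolar receptors.

In coupled mode the scaffold model's drive at time t is R_occ(t) and Polo
conservation reads ``P + S_bar + R_occ + R_dead = P_tot``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import RateParameters
from .scaffold_model import Trajectory, _check_state, _integrate, _rhs
from .species import IDX, SpeciesState, initial_state

__all__ = [
    "model2_rhs",
    "simulate_coupled",
    "set_cycle_rate",
    "CycleCondition",
    "CYCLE_KRON_FACTORS",
    "CYCLE_S_PHASE_MIN",
    "MITOSIS_MIN",
]

#: Per-cycle scaling of the receptor-activation rate k_R_on.  The cell-cycle
#: oscillator activates more slowly at successive blastoderm cycles, so the
#: receptor kinase works more slowly: f11 > f12 > f13.
CYCLE_KRON_FACTORS: dict[int, float] = {11: 1.0, 12: 0.7, 13: 0.5}

#: S-phase duration per nuclear cycle (minutes).  S-phase lengthens at each
#: successive cycle; cycle 12 (12 min) is the default modelling condition.
CYCLE_S_PHASE_MIN: dict[int, float] = {11: 10.0, 12: 12.0, 13: 14.0}

MITOSIS_MIN: float = 3.0


def model2_rhs(state: SpeciesState, params: RateParameters) -> SpeciesState:
    """Rates of change of the receptor states and free Polo.

    Only the pulse-generator reactions contribute; scaffold species enter via
    the S_bar term of the feedback inactivation.  Receptor conservation holds
    by construction: the four receptor-state derivatives sum to zero.
    """
    _check_state(state)
    va = params.k_R_on * state.R_off
    vb = params.k_P_on * state.R_on * state.P
    vc = params.k_P_off * state.R_occ
    vd = params.k_inh * state.R_occ * (state.R_occ + state.S_bar)
    return SpeciesState(
        R_off=-va,
        R_on=va - vb + vc,
        R_occ=vb - vc - vd,
        R_dead=vd,
        P=-vb + vc,
    )


def simulate_coupled(
    params: RateParameters,
    duration: float,
    init: SpeciesState | None = None,
    grid_dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    s_phase_min: float | None = None,
) -> Trajectory:
    """Integrate pulse generator and scaffold model as one coupled system.

    The scaffold drive is the instantaneous receptor-bound Polo R_occ.
    ``init`` defaults to a fresh cycle with the whole receptor pool inactive.
    """
    if init is None:
        init = initial_state(params, coupled=True)
    times, states = _integrate(
        params, lambda t: 0.0, True, duration, init, grid_dt, rtol, atol
    )
    drive = states[:, IDX["R_occ"]].copy()
    return Trajectory(times, states, drive, "coupled", params, s_phase_min)


@dataclass(frozen=True)
class CycleCondition:
    """Model condition for one nuclear cycle: parameters plus phase durations."""

    params: RateParameters
    cycle: int
    s_phase_min: float
    mitosis_min: float = MITOSIS_MIN

    @property
    def cycle_min(self) -> float:
        return self.s_phase_min + self.mitosis_min


def set_cycle_rate(
    params: RateParameters,
    cycle: int,
    factors: dict[int, float] | None = None,
    s_phase_min: dict[int, float] | None = None,
) -> CycleCondition:
    """Condition the model on a nuclear cycle (11, 12 or 13).

    The cell-cycle oscillator enters the model solely through the
    receptor-activation rate: k_R_on is scaled by a per-cycle factor
    (decreasing with cycle number) while S-phase lengthens per cycle.
    """
    factors = CYCLE_KRON_FACTORS if factors is None else factors
    s_phase_min = CYCLE_S_PHASE_MIN if s_phase_min is None else s_phase_min
    if cycle not in factors or cycle not in s_phase_min:
        raise KeyError(f"unknown cycle {cycle!r}; known: {sorted(factors)}")
    scaled = params.scale("k_R_on", factors[cycle])
    return CycleCondition(params=scaled, cycle=cycle, s_phase_min=s_phase_min[cycle])
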