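"""Species state vector for the scaffold and pulse models.

All amounts are in arbitrary intensity units.  The state covers both the
scaffold-assembly species and the centriolar Polo-receptor states; runs in
imposed-pulse mode simply leave the receptor states at zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .params import RateParameters

__all__ = ["SpeciesState", "SPECIES", "IDX"]

#: Canonical species ordering used by the integrators.
SPECIES: tuple[str, ...] = (
    "S",        # cytoplasmic Spd-2
    "RS_free",  # unoccupied centriolar Spd-2 receptor
    "RS_bound",  # receptor.Spd-2 complex
    "S_star",   # weak phospho-Spd-2 scaffold
    "S_bar",    # stable Spd-2.Polo.Cnn scaffold unit (1:1:1)
    "C",        # cytoplasmic Cnn
    "C_star",   # Cnn scaffold
    "P",        # free cytoplasmic Polo
    "R_off",    # inactive centriolar Polo receptor
    "R_on",     # activated, unoccupied Polo receptor
    "R_occ",    # receptor-bound (locally active) Polo
    "R_dead",   # inactivated (feedback-phosphorylated) receptor
)

IDX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class SpeciesState:
    """Amounts of every model species (arbitrary units, all non-negative)."""

    S: float = 0.0
    RS_free: float = 0.0
    RS_bound: float = 0.0
    S_star: float = 0.0
    S_bar: float = 0.0
    C: float = 0.0
    C_star: float = 0.0
    P: float = 0.0
    R_off: float = 0.0
    R_on: float = 0.0
    R_occ: float = 0.0
    R_dead: float = 0.0

    def validate(self, tol: float = 1e-9) -> None:
        for name in SPECIES:
            value = getattr(self, name)
            if not (value >= -tol):
                raise ValueError(f"species {name!r} is negative: {value!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        return cls(**{name: float(y[i]) for i, name in enumerate(SPECIES)})

    def replace(self, **changes: float) -> "SpeciesState":
        return dataclasses.replace(self, **changes)


def initial_state(params: RateParameters, coupled: bool) -> SpeciesState:
    """Fresh-cycle initial condition: all scaffold species zero, pools free.

    In coupled mode the full Polo receptor pool starts inactive (R_off) and
    all Polo is cytoplasmic; in imposed-pulse mode the receptor states are
    unused and stay at zero.
    """
    state = SpeciesState(
        S=params.S_tot,
        RS_free=params.RS_tot,
        C=params.C_tot,
        P=params.P_tot,
    )
    if coupled:
        state = state.replace(R_off=params.RP_tot)
    return state
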