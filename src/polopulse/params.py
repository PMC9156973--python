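"""Reaction-rate parameters and conserved pool totals for the scaffold and pulse models.

The parameter set covers both the PCM-scaffold assembly model (receptor-mediated
Spd-2 recruitment, Polo-dependent phosphorylation, Spd-2/Polo/Cnn scaffold
stabilisation and catalytic Cnn conversion) and the centriolar Polo-pulse
generator (receptor activation, Polo loading and delayed self-limiting
inactivation).  Rates are first- or mass-action constants in units of
``1/min`` (scaled by arbitrary-intensity-unit powers for bi-/tri-molecular
steps); pool totals are amounts in arbitrary intensity units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "RateParameters",
    "SWEEP_RATES",
    "default_parameters",
    "load_parameters",
    "save_parameters",
]

#: The 13 reaction-rate constants swept in the robustness and dose analyses
#: (9 scaffold-model rates + 4 pulse-generator rates).  Pool totals are not
#: reaction rates and are perturbed separately (half-dose genetics).
SWEEP_RATES: tuple[str, ...] = (
    "k_bind",
    "k_unbind",
    "k_phos_S",
    "k_dephos_S",
    "k_stab",
    "k_destab",
    "k_cat_C",
    "k_dephos_C",
    "gamma_C",
    "k_R_on",
    "k_P_on",
    "k_P_off",
    "k_inh",
)

POOL_TOTALS: tuple[str, ...] = ("S_tot", "P_tot", "C_tot", "RS_tot", "RP_tot")


@dataclass(frozen=True)
class RateParameters:
    """Named reaction rates and conserved pool totals.

    Scaffold-model rates
    --------------------
    k_bind : cytoplasmic Spd-2 binding its centriolar receptor (per unit per min)
    k_unbind : receptor-bound Spd-2 release (per min)
    k_phos_S : active-Polo-catalysed conversion of receptor-bound Spd-2 into the
        weak phospho-Spd-2 scaffold S* (per Polo-activity unit per min)
    k_dephos_S : phosphatase-driven reversion S* -> S (per min); fast
    k_stab : effective trimolecular stabilisation S* + P + C -> S-bar
        (per unit^2 per min)
    k_destab : slow disassembly S-bar -> S + P + C (per min)
    k_cat_C : catalytic Cnn activation S-bar -> S* + P + C* (per min)
    k_dephos_C : baseline C* scaffold disassembly (per min)
    gamma_C : size-dependent increase of the per-unit C* disassembly rate
        (per unit per min); per-unit rate is ``k_dephos_C + gamma_C * C_star``

    Pulse-generator rates
    ---------------------
    k_R_on : activation of the inactive centriolar Polo receptor (per min);
        the handle through which the cell-cycle oscillator sets pulse pace
    k_P_on : Polo loading onto active receptors (per unit per min)
    k_P_off : Polo release from occupied receptors (per min)
    k_inh : delayed negative feedback -- inactivation of occupied receptors by
        locally active Polo (per unit per min); the per-receptor rate is
        proportional to the total local active Polo, ``R_occ + S_bar``

    Pool totals (arbitrary units)
    -----------------------------
    S_tot, P_tot, C_tot : total Spd-2, Polo and Cnn in the (well-mixed) system
    RS_tot : centriolar Spd-2 receptor sites
    RP_tot : centriolar Polo receptor sites (Ana1)
    """

    k_bind: float
    k_unbind: float
    k_phos_S: float
    k_dephos_S: float
    k_stab: float
    k_destab: float
    k_cat_C: float
    k_dephos_C: float
    gamma_C: float
    k_R_on: float
    k_P_on: float
    k_P_off: float
    k_inh: float
    S_tot: float
    P_tot: float
    C_tot: float
    RS_tot: float
    RP_tot: float

    def __post_init__(self) -> None:
        for name in self.field_names():
            value = getattr(self, name)
            if not (value >= 0.0):  # also rejects NaN
                raise ValueError(f"parameter {name!r} must be non-negative, got {value!r}")
        if not self.k_dephos_S > self.k_destab:
            raise ValueError(
                "k_dephos_S must exceed k_destab: the weak scaffold S* reverts "
                f"rapidly and the stable scaffold S-bar slowly "
                f"(got k_dephos_S={self.k_dephos_S}, k_destab={self.k_destab})"
            )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **changes: float) -> "RateParameters":
        """Return a copy with the named fields replaced."""
        return dataclasses.replace(self, **changes)

    def scale(self, name: str, factor: float) -> "RateParameters":
        """Return a copy with one named parameter multiplied by ``factor``."""
        if name not in self.field_names():
            raise KeyError(f"unknown parameter {name!r}")
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return self.replace(**{name: getattr(self, name) * factor})

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.field_names()}


#: Calibrated default parameter set.  The values reproduce the qualitative
#: behaviour of scaffold assembly over a nuclear cycle (a centriolar Polo pulse
#: peaking mid-S-phase, a following Spd-2 pulse, and a Cnn scaffold that keeps
#: growing and plateaus while Polo and Spd-2 decline) and are robust to 2-fold
#: perturbation of every reaction rate.  They are a calibrated in-house set;
#: units are arbitrary intensity units and minutes.
_DEFAULTS: dict[str, float] = {
    "k_bind": 4.2,
    "k_unbind": 1.4,
    "k_phos_S": 2.3,
    "k_dephos_S": 5.8,
    "k_stab": 21.0,
    "k_destab": 0.07,
    "k_cat_C": 0.21,
    "k_dephos_C": 0.006,
    "gamma_C": 0.028,
    "k_R_on": 0.62,
    "k_P_on": 4.5,
    "k_P_off": 0.24,
    "k_inh": 2.0,
    "S_tot": 1.0,
    "P_tot": 1.0,
    "C_tot": 3.0,
    "RS_tot": 0.5,
    "RP_tot": 0.95,
}


def default_parameters() -> RateParameters:
    """Return the calibrated default parameter set."""
    return RateParameters(**_DEFAULTS)


def load_parameters(path: str | Path) -> RateParameters:
    """Read a parameter set from a flat JSON key-value file.

    Unknown keys are rejected so that typos in hand-edited configs fail loudly;
    missing keys fall back to the calibrated defaults.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat JSON object")
    known = set(RateParameters.field_names())
    unknown = sorted(set(raw) - known)
    if unknown:
        raise KeyError(f"{path}: unknown parameter keys {unknown}")
    merged = dict(_DEFAULTS)
    merged.update({k: float(v) for k, v in raw.items()})
    return RateParameters(**merged)


def save_parameters(params: RateParameters, path: str | Path) -> None:
    """Write a parameter set as flat JSON."""
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
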