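"""Parametric imposed centriolar Polo-activity pulse.

In imposed-pulse mode the centriolar drive is an external, prescribed
function of time within the nuclear cycle: zero at cycle start, rising to a
single maximum at mid-S-phase and returning to zero.  The shape family is a
named, swappable strategy; the default is a raised-cosine bump, the simplest
smooth compactly-supported unimodal form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = ["PulseSpec", "evaluate_pulse", "register_pulse_shape", "load_pulse", "save_pulse"]


def _raised_cosine(t: np.ndarray, amplitude: float, t_peak: float, width: float) -> np.ndarray:
    """Raised-cosine bump supported on [t_peak - width, t_peak + width]."""
    u = (np.asarray(t, dtype=float) - t_peak) / width
    out = np.where(np.abs(u) < 1.0, 0.5 * amplitude * (1.0 + np.cos(np.pi * u)), 0.0)
    return out


def _triangular(t: np.ndarray, amplitude: float, t_peak: float, width: float) -> np.ndarray:
    u = np.abs(np.asarray(t, dtype=float) - t_peak) / width
    return np.where(u < 1.0, amplitude * (1.0 - u), 0.0)


_SHAPES: dict[str, Callable[[np.ndarray, float, float, float], np.ndarray]] = {
    "raised_cosine": _raised_cosine,
    "triangular": _triangular,
}


def register_pulse_shape(
    name: str, fn: Callable[[np.ndarray, float, float, float], np.ndarray]
) -> None:
    """Register a pulse shape ``fn(t, amplitude, t_peak, width)``.

    Shapes must be non-negative, zero at t = 0 and unimodal with their maximum
    (= amplitude) at t_peak; these properties are relied upon downstream.
    """
    _SHAPES[name] = fn


@dataclass(frozen=True)
class PulseSpec:
    """Imposed centriolar active-Polo pulse: peak ``amplitude`` at ``t_peak``
    (minutes from cycle start, mid-S-phase by default), half-support ``width``."""

    amplitude: float = 1.0
    t_peak: float = 6.0
    width: float = 6.0
    shape: str = "raised_cosine"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"pulse amplitude must be non-negative, got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"pulse width must be positive, got {self.width}")
        if self.t_peak < self.width:
            raise ValueError(
                "pulse must start from zero at cycle start: require t_peak >= width "
                f"(got t_peak={self.t_peak}, width={self.width})"
            )
        if self.shape not in _SHAPES:
            raise KeyError(f"unknown pulse shape {self.shape!r}; known: {sorted(_SHAPES)}")

    def __call__(self, t):
        return evaluate_pulse(t, self)


def evaluate_pulse(t, spec: PulseSpec):
    """Evaluate the centriolar active-Polo drive at time(s) ``t`` (minutes).

    Returns a scalar for scalar input, an array for array input.  The value is
    zero at t = 0 and outside the pulse support, and equals ``spec.amplitude``
    at ``spec.t_peak``.
    """
    scalar = np.isscalar(t)
    out = _SHAPES[spec.shape](np.atleast_1d(t), spec.amplitude, spec.t_peak, spec.width)
    return float(out[0]) if scalar else out


def load_pulse(path: str | Path) -> PulseSpec:
    """Read a PulseSpec from flat JSON; unknown keys rejected."""
    with open(path) as fh:
        raw = json.load(fh)
    known = {"amplitude", "t_peak", "width", "shape"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise KeyError(f"{path}: unknown pulse keys {unknown}")
    return PulseSpec(**raw)


def save_pulse(spec: PulseSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"amplitude": spec.amplitude, "t_peak": spec.t_peak, "width": spec.width, "shape": spec.shape},
            fh,
            indent=2,
        )
        fh.write("\n")
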