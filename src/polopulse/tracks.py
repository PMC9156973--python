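"""Quantitative analysis of centrosome-intensity tracks.

Implements the measurement pipeline applied to live-imaging centrosome
tracks: pulse-feature extraction (initial/maximum intensity, growth period
and rate, peak time), piecewise-linear growth-curve model selection for the
Cnn channel, signed peak-time differences between channels, old-mother /
new-mother (OM/NM) pairing of centrosomes by proximity and brightness, and
the growth-period vs S-phase-length correlation analysis.

Tracks are tab-delimited tables with columns ``embryo_id, centrosome_id,
time_min, intensity, phase`` and optional ``x_um, y_um, mother_class``.
Time is minutes relative to nuclear envelope breakdown (NEB = 0), so
S-phase timepoints are negative and carry phase label ``S``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import optimize, stats as sps

__all__ = [
    "CentrosomeTrack",
    "PulseFeatures",
    "CnnFit",
    "read_tracks",
    "write_tracks",
    "tracks_to_frame",
    "extract_pulse_features",
    "fit_cnn_model",
    "peak_time_difference",
    "pair_centrosomes",
    "growth_vs_sphase_correlation",
]

TRACK_COLUMNS = ["embryo_id", "centrosome_id", "time_min", "intensity", "phase"]
OPTIONAL_COLUMNS = ["x_um", "y_um", "mother_class"]


@dataclass
class CentrosomeTrack:
    """One centrosome's intensity time series with phase annotations."""

    embryo_id: str
    centrosome_id: str
    times: np.ndarray           # minutes, NEB at 0, strictly increasing
    intensities: np.ndarray     # arbitrary units, non-negative
    phases: np.ndarray | None = None      # "S" or "M" per timepoint
    positions: np.ndarray | None = None   # (n, 2) in micrometres
    mother_class: str | None = None       # "OM" | "NM" | None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size < 5:
            raise ValueError(
                f"track {self.centrosome_id!r}: need at least 5 timepoints, got {self.times.size}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"track {self.centrosome_id!r}: times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError(f"track {self.centrosome_id!r}: intensities must be non-negative")
        if self.intensities.size != self.times.size:
            raise ValueError("times and intensities must have equal length")

    def first_s_index(self) -> int:
        """Index of the first S-phase timepoint (0 if no phase labels)."""
        if self.phases is None:
            return 0
        hits = np.nonzero(np.asarray(self.phases) == "S")[0]
        return int(hits[0]) if hits.size else 0


def read_tracks(path: str | Path) -> list[CentrosomeTrack]:
    """Read a tab-delimited track table into per-centrosome tracks."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track columns {missing}")
    return tracks_from_frame(df)


def tracks_from_frame(df: pd.DataFrame) -> list[CentrosomeTrack]:
    out = []
    for (embryo, cid), sub in df.groupby(["embryo_id", "centrosome_id"], sort=True):
        sub = sub.sort_values("time_min")
        positions = None
        if {"x_um", "y_um"} <= set(sub.columns) and sub["x_um"].notna().all():
            positions = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        mother = None
        if "mother_class" in sub.columns:
            vals = sub["mother_class"].dropna().unique()
            mother = str(vals[0]) if len(vals) else None
        out.append(
            CentrosomeTrack(
                embryo_id=str(embryo),
                centrosome_id=str(cid),
                times=sub["time_min"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
                phases=sub["phase"].to_numpy() if "phase" in sub.columns else None,
                positions=positions,
                mother_class=mother,
            )
        )
    return out


def tracks_to_frame(tracks: list[CentrosomeTrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i, (t, y) in enumerate(zip(tr.times, tr.intensities)):
            row = {
                "embryo_id": tr.embryo_id,
                "centrosome_id": tr.centrosome_id,
                "time_min": t,
                "intensity": y,
                "phase": tr.phases[i] if tr.phases is not None else "S",
            }
            if tr.positions is not None:
                row["x_um"] = tr.positions[i, 0]
                row["y_um"] = tr.positions[i, 1]
            if tr.mother_class is not None:
                row["mother_class"] = tr.mother_class
            rows.append(row)
    return pd.DataFrame(rows)


def write_tracks(tracks: list[CentrosomeTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class PulseFeatures:
    """Growth features of one intensity pulse.

    ``growth_rate`` is (maximum - initial) / growth period, in intensity
    units per minute; ``peak_at_boundary`` flags tracks whose maximum sits on
    the first or last sample (no interior peak).
    """

    initial_intensity: float
    maximum_intensity: float
    growth_period: float
    growth_rate: float
    peak_time: float
    peak_at_boundary: bool = False


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _centroid_peak_time(times: np.ndarray, y_smooth: np.ndarray, frac: float = 0.7) -> float:
    """Sub-sample peak location: intensity-weighted centroid of the
    contiguous region around the maximum that stays above ``frac`` of the
    smoothed dynamic range.  Far less variable than a raw argmax when the
    pulse apex is flat relative to the sampling interval."""
    thr = y_smooth.min() + frac * (y_smooth.max() - y_smooth.min())
    i = int(np.argmax(y_smooth))
    lo, hi = i, i
    while lo > 0 and y_smooth[lo - 1] >= thr:
        lo -= 1
    while hi < y_smooth.size - 1 and y_smooth[hi + 1] >= thr:
        hi += 1
    weights = y_smooth[lo : hi + 1] - thr
    total = weights.sum()
    if total <= 0:
        return float(times[i])
    return float(np.sum(times[lo : hi + 1] * weights) / total)


def extract_pulse_features(
    track: CentrosomeTrack, smoothing_window: int = 3, refine_peak: bool = False
) -> PulseFeatures:
    """Measure a track's pulse: initial intensity at the first S-phase
    timepoint, maximum at the peak of the smoothed series (value read from
    the raw series), and the derived growth period and rate.

    A centred moving average (default 3 samples) locates the peak; tracks
    with no interior peak are flagged ``peak_at_boundary`` and, where the
    peak coincides with the initial timepoint, the growth period falls back
    to the full track span so the rate stays defined (zero for a flat track).
    With ``refine_peak`` the peak time is refined to sub-sample resolution
    by a thresholded centroid around the smoothed maximum — preferable when
    comparing peak timings of slowly-varying pulses across tracks.
    """
    y_smooth = _moving_average(track.intensities, smoothing_window)
    peak_idx = int(np.argmax(y_smooth))
    i0 = track.first_s_index()
    initial = float(track.intensities[i0])
    maximum = float(track.intensities[peak_idx])
    peak_time = float(track.times[peak_idx])
    if refine_peak:
        peak_time = _centroid_peak_time(track.times, y_smooth)
    boundary = peak_idx in (0, track.times.size - 1)
    period = peak_time - float(track.times[i0])
    if period <= 0:
        boundary = True
        period = float(track.times[-1] - track.times[i0])
    rate = (maximum - initial) / period
    return PulseFeatures(
        initial_intensity=initial,
        maximum_intensity=max(maximum, initial),
        growth_period=period,
        growth_rate=rate,
        peak_time=peak_time,
        peak_at_boundary=boundary,
    )


# --- Cnn growth-curve model selection -------------------------------------

_CNN_MODELS = ("linear", "linear_plateau", "linear_decrease")


@dataclass
class CnnFit:
    """Best-fitting growth-curve model for a Cnn track.

    Candidates: a single linear increase, a linear increase reaching a
    plateau, and a linear increase followed by a linear decrease (continuous
    piecewise-linear, free breakpoint).  Selection is by small-sample
    corrected AIC; scores for all three candidates are retained.
    """

    selected: str
    slopes: dict[str, float]
    intercept: float
    breakpoint: float | None
    scores: dict[str, float]        # AICc per candidate model
    sse: dict[str, float]
    features: PulseFeatures
    fitted: np.ndarray = field(repr=False, default=None)


def _design(t: np.ndarray, model: str, tb: float | None) -> np.ndarray:
    if model == "linear":
        return np.column_stack([np.ones_like(t), t])
    if model == "linear_plateau":
        return np.column_stack([np.ones_like(t), np.minimum(t, tb)])
    return np.column_stack([np.ones_like(t), np.minimum(t, tb), np.maximum(t - tb, 0.0)])


def _fit_fixed_breakpoint(t, y, model, tb):
    # weighted least squares with weights 1/y: fluorescence noise is
    # multiplicative, so residuals scale with the signal level
    X = _design(t, model, tb)
    w = 1.0 / np.maximum(np.abs(y), 1e-9 * max(float(np.abs(y).max()), 1.0))
    beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    resid = (y - X @ beta) * w
    return beta, float(resid @ resid)


def _fit_candidate(t: np.ndarray, y: np.ndarray, model: str):
    if model == "linear":
        beta, sse = _fit_fixed_breakpoint(t, y, model, None)
        return beta, sse, None
    # profile the breakpoint: coarse pass over interior sample times, then a
    # bounded 1-d refinement between the best point's neighbours.  Both
    # segments must contain at least 3 samples — a one-sample "plateau" is
    # noise-chasing, not a phase of the growth curve.
    interior = t[3:-3] if t.size >= 8 else t[1:-1]
    sses = [_fit_fixed_breakpoint(t, y, model, tb)[1] for tb in interior]
    k = int(np.argmin(sses))
    lo = interior[max(k - 1, 0)]
    hi = interior[min(k + 1, interior.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda tb: _fit_fixed_breakpoint(t, y, model, tb)[1],
            bounds=(lo, hi),
            method="bounded",
        )
        tb = float(res.x) if res.fun <= sses[k] else float(interior[k])
    else:
        tb = float(interior[k])
    beta, sse = _fit_fixed_breakpoint(t, y, model, tb)
    return beta, sse, tb


def _aicc(sse: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(sse, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_cnn_model(track: CentrosomeTrack) -> CnnFit:
    """Fit the three candidate growth-curve models and select by AICc.

    Requires at least 8 timepoints.  Ties (within 1e-9) prefer the simpler
    model, so noiseless one-phase data never selects a two-phase model.
    """
    t, y = track.times, track.intensities
    if t.size < 8:
        raise ValueError(f"need >= 8 timepoints for growth-curve fits, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all times equal")
    n_params = {"linear": 2, "linear_plateau": 3, "linear_decrease": 4}
    fits = {m: _fit_candidate(t, y, m) for m in _CNN_MODELS}
    scores = {m: _aicc(fits[m][1], t.size, n_params[m]) for m in _CNN_MODELS}
    # a "decrease" whose fitted second segment does not actually decline is
    # noise-chasing, not a distinct growth class: drop it from contention
    fall = float(fits["linear_decrease"][0][2])
    rise = float(fits["linear_decrease"][0][1])
    candidates = list(_CNN_MODELS)
    if fall >= -0.05 * abs(rise):
        candidates.remove("linear_decrease")
    # argmin with simpler-model preference on ties
    selected = min(candidates, key=lambda m: (scores[m] - 1e-9 * (m == "linear"), _CNN_MODELS.index(m)))
    beta, sse, tb = fits[selected]
    fitted = _design(t, selected, tb) @ beta
    peak_idx = int(np.argmax(fitted))
    peak_time = float(t[peak_idx]) if selected == "linear" else float(tb)
    initial = float(fitted[0])
    maximum = float(fitted.max())
    period = peak_time - float(t[0])
    if period <= 0:
        period = float(np.ptp(t))
    slopes = {"rise": float(beta[1])}
    if selected == "linear_decrease":
        slopes["fall"] = float(beta[2])
    features = PulseFeatures(
        initial_intensity=initial,
        maximum_intensity=maximum,
        growth_period=period,
        growth_rate=(maximum - initial) / period,
        peak_time=peak_time,
        peak_at_boundary=selected == "linear",
    )
    return CnnFit(
        selected=selected,
        slopes=slopes,
        intercept=float(beta[0]),
        breakpoint=tb,
        scores=scores,
        sse={m: fits[m][1] for m in _CNN_MODELS},
        features=features,
        fitted=fitted,
    )


def peak_time_difference(
    track_a: CentrosomeTrack, track_b: CentrosomeTrack, smoothing_window: int = 3
) -> float:
    """Signed peak-time difference in minutes (peak of A minus peak of B).

    Both tracks must overlap in time; a boundary-peak flag on either track
    is propagated as a warning.
    """
    if track_a.times[-1] < track_b.times[0] or track_b.times[-1] < track_a.times[0]:
        raise ValueError("tracks do not overlap in time")
    fa = extract_pulse_features(track_a, smoothing_window)
    fb = extract_pulse_features(track_b, smoothing_window)
    if fa.peak_at_boundary or fb.peak_at_boundary:
        warnings.warn("peak at track boundary; peak-time difference may be truncated")
    return fa.peak_time - fb.peak_time


def pair_centrosomes(
    tracks: list[CentrosomeTrack], distance_threshold: float
) -> pd.DataFrame:
    """Pair centrosomes at the start of S-phase and label OM/NM.

    Greedy mutual-nearest pairing: the globally closest unpaired pair within
    ``distance_threshold`` (micrometres) is accepted repeatedly; distance ties
    break on the lower centrosome id.  Within a pair the brighter centrosome
    at its first S-phase timepoint is the old mother (OM), the dimmer the new
    mother (NM); leftover tracks are ``unassigned``.
    """
    with_pos = [tr for tr in tracks if tr.positions is not None]
    if len(with_pos) < 2:
        raise ValueError("need at least two tracks with positions")
    ids = [tr.centrosome_id for tr in with_pos]
    pos = np.array([tr.positions[tr.first_s_index()] for tr in with_pos])
    bright = np.array([tr.intensities[tr.first_s_index()] for tr in with_pos])
    candidates = []
    for i in range(len(with_pos)):
        for j in range(i + 1, len(with_pos)):
            d = float(np.hypot(*(pos[i] - pos[j])))
            if d <= distance_threshold:
                a, b = sorted((ids[i], ids[j]))
                candidates.append((d, a, b, i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    label = {cid: "unassigned" for cid in ids}
    partner: dict[str, str | None] = {cid: None for cid in ids}
    pair_of: dict[str, int] = {}
    used: set[int] = set()
    n_pairs = 0
    for d, _, _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        # brighter -> OM; intensity ties break on lower centrosome id
        order = sorted((i, j), key=lambda k: (-bright[k], ids[k]))
        label[ids[order[0]]] = "OM"
        label[ids[order[1]]] = "NM"
        partner[ids[i]], partner[ids[j]] = ids[j], ids[i]
        pair_of[ids[i]] = pair_of[ids[j]] = n_pairs
        n_pairs += 1
    return pd.DataFrame(
        {
            "centrosome_id": ids,
            "label": [label[c] for c in ids],
            "partner_id": [partner[c] for c in ids],
            "pair_id": [pair_of.get(c, -1) for c in ids],
        }
    ).sort_values("centrosome_id", ignore_index=True)


def growth_vs_sphase_correlation(features) -> dict:
    """Correlate centrosome growth period with S-phase length.

    ``features`` is a sequence of (growth_period, sphase_length) pairs,
    n >= 5.  Returns the Pearson r and p-value, the least-squares regression
    slope/intercept and R^2, and the Henze-Zirkler multivariate-normality
    statistic and p-value (log-normal approximation) assessing whether the
    pairs are plausibly bivariate Gaussian (a premise of the Pearson test).
    """
    arr = np.asarray(list(features), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("features must be (growth_period, sphase_length) pairs")
    if arr.shape[0] < 5:
        raise ValueError(f"need at least 5 pairs, got {arr.shape[0]}")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    try:
        hz = pg.multivariate_normality(pd.DataFrame({"x": x, "y": y}), alpha=0.05)
        hz_stat, hz_p = float(hz.hz), float(hz.pval)
    except np.linalg.LinAlgError:  # singular covariance (e.g. exactly collinear)
        hz_stat, hz_p = float("nan"), float("nan")
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "r_squared": float(reg.rvalue**2),
        "hz_statistic": hz_stat,
        "hz_p": hz_p,
        "n": int(arr.shape[0]),
    }
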