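"""Cortical evoked-potential features and derived gain/slope statistics.

Feature definitions: P1 is the highest deflection between 15 and 30 ms
post stimulus onset, N1 the lowest between 25 and 60 ms, and P2 the
highest between 60 and 120 ms (all windows inclusive; earliest sample on
exact ties).  Amplitudes are referenced to the pre-stimulus baseline.
The analyzed amplitude complexes P1-N1 and N1-P2 are differences of
these extrema, which makes them baseline-independent and, because the P1
and N1 windows overlap, guarantees P1-N1 >= 0 and N1-P2 >= 0 on any
waveform.

Derived statistics: central gain is the complex amplitude divided by the
wave-1 amplitude evoked by the same tone; level- and interval-dependent
slopes are ordinary least-squares fits of a feature against sound level
in dB or against ln(ITI in ms) respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .abr import Wave1Features
from .preprocess import EpochedAverage

__all__ = [
    "AEPFeatureSet",
    "GainMeasures",
    "SlopeEstimate",
    "P1_WINDOW_MS",
    "N1_WINDOW_MS",
    "P2_WINDOW_MS",
    "extract_aep_features",
    "central_gain",
    "level_slope",
    "iti_slope",
]

P1_WINDOW_MS = (15.0, 30.0)
N1_WINDOW_MS = (25.0, 60.0)
P2_WINDOW_MS = (60.0, 120.0)


@dataclass
class AEPFeatureSet:
    """P1/N1/P2 amplitudes (µV re: baseline), latencies (ms), and the
    P1-N1 / N1-P2 amplitude complexes."""

    p1_amp: float
    n1_amp: float
    p2_amp: float
    p1_lat: float
    n1_lat: float
    p2_lat: float

    @property
    def p1n1(self) -> float:
        return self.p1_amp - self.n1_amp

    @property
    def n1p2(self) -> float:
        return self.p2_amp - self.n1_amp


@dataclass
class GainMeasures:
    """AEP/ABR amplitude ratios; ``defined`` is False when the wave-1
    amplitude was below the resolvability floor."""

    gain_p1n1: float
    gain_n1p2: float
    defined: bool = True


@dataclass
class SlopeEstimate:
    """OLS slope of a feature against level (dB) or ln(ITI in ms)."""

    slope: float
    intercept: float
    resid_sd: float
    n_points: int
    predictor: str

    def __post_init__(self):
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")


def _window_extremum(avg: EpochedAverage, window: tuple, mode: str):
    t = avg.time_ms
    mask = (t >= window[0]) & (t <= window[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"epoch does not cover window {window}")
    values = avg.mean[idx]
    pos = int(np.argmax(values) if mode == "max" else np.argmin(values))
    i = idx[pos]
    return float(avg.mean[i]), float(t[i])


def extract_aep_features(
    avg: EpochedAverage,
    p1_window: tuple = P1_WINDOW_MS,
    n1_window: tuple = N1_WINDOW_MS,
    p2_window: tuple = P2_WINDOW_MS,
    flip_polarity: bool = False,
) -> AEPFeatureSet:
    """Locate P1/N1/P2 extrema on an averaged cortical waveform.

    ``flip_polarity`` inverts the input waveform first, for recordings
    made with the opposite electrode polarity convention.  No ordering
    constraint is imposed between the P1 and N1 latencies.
    """
    t = avg.time_ms
    if t[0] > min(p1_window[0], 0.0) or t[-1] < p2_window[1]:
        raise ValueError("epoch too short: must cover 0 through the P2 window")
    if flip_polarity:
        avg = EpochedAverage(
            time_ms=avg.time_ms,
            mean=-avg.mean,
            sem=avg.sem,
            n_epochs_retained=avg.n_epochs_retained,
            condition=avg.condition,
            sem_defined=avg.sem_defined,
        )
    p1_amp, p1_lat = _window_extremum(avg, p1_window, "max")
    n1_amp, n1_lat = _window_extremum(avg, n1_window, "min")
    p2_amp, p2_lat = _window_extremum(avg, p2_window, "max")
    return AEPFeatureSet(
        p1_amp=p1_amp,
        n1_amp=n1_amp,
        p2_amp=p2_amp,
        p1_lat=p1_lat,
        n1_lat=n1_lat,
        p2_lat=p2_lat,
    )


def central_gain(
    features: AEPFeatureSet,
    wave1: Wave1Features,
    floor_uv: float = 0.01,
) -> GainMeasures:
    """Central auditory gain: complex amplitude over wave-1 amplitude.

    When the wave-1 amplitude is at or below ``floor_uv`` the ratio is
    unresolvable; the result carries NaN gains with ``defined=False``
    and should be excluded downstream.
    """
    if wave1.amplitude_uv <= floor_uv:
        return GainMeasures(gain_p1n1=float("nan"), gain_n1p2=float("nan"), defined=False)
    return GainMeasures(
        gain_p1n1=features.p1n1 / wave1.amplitude_uv,
        gain_n1p2=features.n1p2 / wave1.amplitude_uv,
        defined=True,
    )


def _ols(x: np.ndarray, y: np.ndarray, predictor: str) -> SlopeEstimate:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - (intercept + slope * x)
    resid_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return SlopeEstimate(
        slope=slope,
        intercept=intercept,
        resid_sd=resid_sd,
        n_points=n,
        predictor=predictor,
    )


def _as_xy(points: Mapping) -> tuple:
    if len(points) < 2:
        raise ValueError("need at least two points")
    x = np.array(sorted(float(k) for k in points))
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct predictor values")
    y = np.array([float(points[k]) for k in x])
    return x, y


def level_slope(points: Mapping) -> SlopeEstimate:
    """OLS slope of a feature against sound level in dB.

    ``points`` maps level (dB SPL) to the feature value.
    """
    x, y = _as_xy(points)
    return _ols(x, y, predictor="level_db")


def iti_slope(points: Mapping, normalize_to_350: bool = False) -> SlopeEstimate:
    """OLS slope of a feature against the natural log of ITI (in ms).

    With ``normalize_to_350`` the feature values are divided by the value
    at the 350 ms condition (which must be present and nonzero) before
    fitting, removing overall-amplitude differences between ears.
    """
    x, y = _as_xy(points)
    if normalize_to_350:
        at350 = np.flatnonzero(np.isclose(x, 350.0))
        if at350.size == 0:
            raise ValueError("normalization requires the 350 ms condition")
        ref = y[at350[0]]
        if ref == 0:
            raise ValueError("cannot normalize: value at 350 ms is zero")
        y = y / ref
    return _ols(np.log(x), y, predictor="ln_iti")
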