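"""Brainstem-response analysis: hearing-threshold detection, wave-1
feature extraction, and hearing-impairment classification.

Threshold rule: a click level is "detected" when the averaged
differential waveform deviates from baseline by at least twice its
time-dependent SEM somewhere inside the analysis window; the hearing
threshold is the lowest level such that that level *and every higher
level* are detected.  The supra-threshold consistency requirement
emulates the expert judgment of a characteristic deflection and guards
against isolated pointwise noise crossings.  Before applying the
criterion the mean waveform is smoothed with a short moving average
(default 0.5 ms, configurable, 0 disables) so that at high sampling
rates a single noisy sample cannot trigger a detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocess import EpochedAverage

__all__ = [
    "ThresholdResult",
    "Wave1Features",
    "HearingClass",
    "detect_threshold",
    "classify_hearing",
    "wave1_features",
    "bilateral_category",
    "bilateral_percentages",
]


@dataclass
class ThresholdResult:
    """Outcome of threshold detection over a click level series.

    ``threshold`` is in dB SPL, or None when no level satisfies the
    detection rule ("none-detected").  ``criterion`` holds, per level,
    the maximum of |smoothed mean| / SEM inside the analysis window.
    """

    threshold: float | None
    levels: np.ndarray
    detected: np.ndarray
    criterion: np.ndarray
    analysis_window: tuple

    @property
    def detected_by_level(self) -> dict:
        return {float(l): bool(d) for l, d in zip(self.levels, self.detected)}


@dataclass
class Wave1Features:
    """Wave-1 peak amplitude (re: waveform value at stimulus onset) and
    latency."""

    amplitude_uv: float
    latency_ms: float


@dataclass
class HearingClass:
    """NH/HI classification of one ear with the cutoff that was applied."""

    label: str
    cutoff_db: float
    cutoff_display: int
    flagged: bool = False


def _smooth(mean: np.ndarray, sampling_rate: float, smooth_ms: float) -> np.ndarray:
    if smooth_ms <= 0:
        return mean
    n = max(1, int(round(smooth_ms * sampling_rate / 1000.0)))
    if n % 2 == 0:
        n += 1
    if n == 1:
        return mean
    kernel = np.ones(n) / n
    return np.convolve(mean, kernel, mode="same")


def detect_threshold(
    level_series: Mapping[float, EpochedAverage],
    analysis_window: tuple = (1.0, 6.0),
    criterion: float = 2.0,
    smooth_ms: float = 0.5,
) -> ThresholdResult:
    """Find the hearing threshold from averaged click responses per level.

    A level is detected iff some sample of the (smoothed) mean waveform
    inside ``analysis_window`` has absolute deflection >= ``criterion``
    times the SEM at that sample ("at least twice" is inclusive).  The
    threshold is the lowest level with the criterion met at that level
    and at all higher levels; None if even the highest level fails.
    Missing levels are simply absent from the series and the rule is
    evaluated over the levels provided.
    """
    if not level_series:
        raise ValueError("empty level series")
    levels = np.array(sorted(float(l) for l in level_series), dtype=float)
    w0, w1 = analysis_window
    ratios = np.empty(len(levels))
    for i, level in enumerate(levels):
        avg = level_series[level]
        if not avg.sem_defined:
            raise ValueError(f"SEM undefined for level {level}; cannot detect")
        mask = (avg.time_ms >= w0) & (avg.time_ms <= w1)
        if not np.any(mask):
            raise ValueError("analysis window outside epoch")
        sm = _smooth(avg.mean, avg.sampling_rate, smooth_ms)[mask]
        sem = avg.sem[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(sem > 0, np.abs(sm) / sem, np.where(np.abs(sm) > 0, np.inf, 0.0))
        ratios[i] = np.max(r)
    detected = ratios >= criterion
    threshold: float | None = None
    # lowest level from which detection holds all the way up
    consistent = np.logical_and.accumulate(detected[::-1])[::-1]
    hits = np.flatnonzero(consistent)
    if hits.size:
        threshold = float(levels[hits[0]])
    return ThresholdResult(
        threshold=threshold,
        levels=levels,
        detected=detected,
        criterion=ratios,
        analysis_window=(w0, w1),
    )


def classify_hearing(
    threshold: float | None,
    wt_mean: float,
    wt_sd: float,
    k: float = 2.5,
) -> HearingClass:
    """Classify an ear as NH or HI against the WT threshold distribution.

    HI iff threshold > wt_mean + k * wt_sd (strict inequality; an ear at
    exactly the cutoff is NH).  A non-detected threshold (None/NaN) is
    classified HI and flagged.  ``cutoff_display`` is the cutoff rounded
    to the nearest integer dB for reporting.
    """
    if wt_sd <= 0:
        raise ValueError("wt_sd must be positive")
    cutoff = wt_mean + k * wt_sd
    display = int(round(cutoff))
    if threshold is None or (isinstance(threshold, float) and math.isnan(threshold)):
        return HearingClass("HI", cutoff, display, flagged=True)
    label = "HI" if threshold > cutoff else "NH"
    return HearingClass(label, cutoff, display)


def wave1_features(
    avg: EpochedAverage,
    search_window: tuple = (0.5, 2.5),
) -> Wave1Features:
    """Wave-1 peak amplitude and latency from an averaged tone response.

    Latency is the argmax of the mean waveform inside the search window
    (earliest sample on exact ties); amplitude is the waveform value at
    that latency minus its value at stimulus onset (t = 0).
    """
    w0, w1 = search_window
    t = avg.time_ms
    if w0 < t[0] or w1 > t[-1]:
        raise ValueError("search window outside epoch")
    mask = (t >= w0) & (t <= w1)
    idx = np.flatnonzero(mask)
    peak = idx[int(np.argmax(avg.mean[idx]))]
    onset = int(np.argmin(np.abs(t)))
    amplitude = float(avg.mean[peak] - avg.mean[onset])
    return Wave1Features(amplitude_uv=amplitude, latency_ms=float(t[peak]))


def bilateral_category(left_label: str, right_label: str) -> str:
    """Bilateral hearing status of an animal from its per-ear NH/HI labels.

    Returns ``"both_normal"``, ``"unilateral"`` or ``"bilateral"``
    (the latter meaning impairment in both ears).
    """
    n_hi = sum(label == "HI" for label in (left_label, right_label))
    return ("both_normal", "unilateral", "bilateral")[n_hi]


def bilateral_percentages(pairs: Sequence[tuple]) -> dict:
    """Percentage of animals per bilateral hearing category, rounded to
    the nearest integer percent.

    ``pairs`` is a sequence of (left_label, right_label) NH/HI tuples.
    """
    if not pairs:
        raise ValueError("no animals")
    counts = {"both_normal": 0, "unilateral": 0, "bilateral": 0}
    for left, right in pairs:
        counts[bilateral_category(left, right)] += 1
    n = len(pairs)
    return {key: int(round(100.0 * val / n)) for key, val in counts.items()}
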