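"""Raw-trace preprocessing: filtering, differential referencing, epoching,
artifact rejection, and epoch averaging with pointwise SEM.

The processing chain for brainstem responses is band-pass filter each
electrode trace (zero-phase, so latency endpoints are unbiased), subtract
bulla from vertex to obtain the differential signal, cut epochs around
stimulus onsets, drop artifact-contaminated epochs, and average with a
per-sample standard error of the mean.  Cortical potentials are analyzed
single-ended from the cortical electrode, unfiltered by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "ContinuousRecording",
    "EpochedAverage",
    "RejectionLog",
    "bandpass_abr",
    "differential_abr",
    "extract_epochs",
    "reject_artifact_epochs",
    "average_epochs",
    "epoch_and_average",
]


@dataclass
class ContinuousRecording:
    """Multi-channel continuous voltage recording with stimulus events.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``vertex``, ``bulla``, ``cortical``)
        to a 1-D voltage trace in microvolts.  All traces must have equal
        length.
    sampling_rate
        Sampling rate in Hz, shared by all channels.
    onsets_s
        Stimulus onset times in seconds, strictly increasing.
    event_attrs
        One row per onset with stimulus attributes (e.g. ``level_db``,
        ``iti_ms``, ``kind``, ``protocol``).
    """

    channels: dict
    sampling_rate: float
    onsets_s: np.ndarray
    event_attrs: pd.DataFrame

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {name: len(np.asarray(tr)) for name, tr in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if len(self.onsets_s) != len(self.event_attrs):
            raise ValueError("onsets and event_attrs must be aligned")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def events(self):
        """Iterate ``(onset_s, attrs_dict)`` pairs."""
        for onset, (_, row) in zip(self.onsets_s, self.event_attrs.iterrows()):
            yield float(onset), dict(row)

    def select_events(self, **attrs) -> np.ndarray:
        """Onset times of events whose attributes match ``attrs`` exactly."""
        mask = np.ones(len(self.onsets_s), dtype=bool)
        for key, value in attrs.items():
            col = self.event_attrs[key].to_numpy()
            if np.issubdtype(col.dtype, np.number):
                mask &= np.isclose(col.astype(float), float(value))
            else:
                mask &= col == value
        return self.onsets_s[mask]


@dataclass
class EpochedAverage:
    """Averaged waveform for one stimulus condition.

    ``mean`` and ``sem`` are per-sample over the retained (baseline-
    corrected) epochs; ``sem`` is the time-dependent standard error of
    the mean.  ``sem_defined`` is False when fewer than two epochs were
    available.
    """

    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_epochs_retained: int
    condition: dict = field(default_factory=dict)
    sem_defined: bool = True

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.time_ms) == len(self.mean) == len(self.sem)):
            raise ValueError("time, mean and sem must have equal length")
        if self.sem_defined and np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.time_ms)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "mean_uv": self.mean, "sem_uv": self.sem}
        )


@dataclass
class RejectionLog:
    """Record of artifact rejection: which epochs were dropped and why."""

    rejected_indices: np.ndarray
    peak_to_peak: np.ndarray
    threshold_uv: float
    all_rejected: bool = False


def bandpass_abr(
    trace: np.ndarray,
    sampling_rate: float,
    low: float = 100.0,
    high: float = 3000.0,
) -> np.ndarray:
    """Zero-phase band-pass filter for brainstem-response traces.

    A 4th-order Butterworth band-pass applied forward and backward
    (``sosfiltfilt``), so no latency shift is introduced and passband
    gain is within 1% of unity at the geometric-mean frequency.
    """
    trace = np.asarray(trace, dtype=float)
    if sampling_rate <= 2.0 * high:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz too low for band edge {high} Hz"
        )
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    sos = _signal.butter(4, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return _signal.sosfiltfilt(sos, trace)


def differential_abr(vertex: np.ndarray, bulla: np.ndarray) -> np.ndarray:
    """Differential brainstem signal: vertex minus bulla, sample by sample."""
    vertex = np.asarray(vertex, dtype=float)
    bulla = np.asarray(bulla, dtype=float)
    if vertex.shape != bulla.shape:
        raise ValueError("vertex and bulla traces must have equal length")
    return vertex - bulla


def extract_epochs(
    trace: np.ndarray,
    sampling_rate: float,
    onsets_s: Sequence[float],
    window_ms: tuple = (-10.0, 150.0),
):
    """Cut fixed-length epochs around stimulus onsets.

    Returns ``(time_ms, epochs)`` where ``time_ms`` is relative to onset
    and ``epochs`` has shape ``(n_events, n_samples)``.  Raises if any
    window falls outside the recording.
    """
    trace = np.asarray(trace, dtype=float)
    onsets_s = np.asarray(onsets_s, dtype=float)
    w0, w1 = window_ms
    if w1 <= w0:
        raise ValueError("window end must exceed window start")
    i0 = int(round(w0 * sampling_rate / 1000.0))
    n = int(round((w1 - w0) * sampling_rate / 1000.0))
    if n < 1:
        raise ValueError("epoch window shorter than one sample")
    starts = np.rint(onsets_s * sampling_rate).astype(np.int64) + i0
    if len(starts) == 0:
        raise ValueError("no events to epoch")
    if starts.min() < 0 or (starts.max() + n) > len(trace):
        raise ValueError("event window extends outside the recording")
    idx = starts[:, None] + np.arange(n)[None, :]
    epochs = trace[idx]
    time_ms = (np.arange(n) + i0) * 1000.0 / sampling_rate
    return time_ms, epochs


def reject_artifact_epochs(epochs: np.ndarray, k: float = 5.0):
    """Drop epochs whose peak-to-peak amplitude exceeds ``k`` times the
    median peak-to-peak across epochs.

    This is the documented stand-in for heartbeat-noise removal: large
    transient artifacts (heartbeat, movement) inflate an epoch's
    peak-to-peak range far beyond the median and are excluded before
    averaging.  Retained epochs keep their original order.

    Returns ``(retained_epochs, RejectionLog)``.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need at least one epoch")
    if k <= 0:
        raise ValueError("k must be positive")
    ptp = epochs.max(axis=1) - epochs.min(axis=1)
    threshold = k * float(np.median(ptp))
    rejected = np.flatnonzero(ptp > threshold)
    keep = np.setdiff1d(np.arange(epochs.shape[0]), rejected)
    log = RejectionLog(
        rejected_indices=rejected,
        peak_to_peak=ptp,
        threshold_uv=threshold,
        all_rejected=keep.size == 0,
    )
    return epochs[keep], log


def average_epochs(
    time_ms: np.ndarray,
    epochs: np.ndarray,
    condition: Mapping | None = None,
) -> EpochedAverage:
    """Baseline-correct epochs and average them with pointwise SEM.

    Each epoch has the mean of its pre-stimulus interval (all samples at
    ``time_ms < 0``) subtracted.  ``sem`` is the sample standard
    deviation across epochs divided by sqrt(n); with fewer than two
    epochs the SEM is undefined and flagged.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need at least one epoch to average")
    pre = time_ms < 0
    if np.any(pre):
        epochs = epochs - epochs[:, pre].mean(axis=1, keepdims=True)
    n = epochs.shape[0]
    mean = epochs.mean(axis=0)
    if n >= 2:
        sem = epochs.std(axis=0, ddof=1) / np.sqrt(n)
        sem_defined = True
    else:
        sem = np.full_like(mean, np.nan)
        sem_defined = False
    return EpochedAverage(
        time_ms=time_ms,
        mean=mean,
        sem=sem,
        n_epochs_retained=n,
        condition=dict(condition or {}),
        sem_defined=sem_defined,
    )


def epoch_and_average(
    trace: np.ndarray,
    sampling_rate: float,
    onsets_s: Sequence[float],
    window_ms: tuple = (-10.0, 150.0),
    condition: Mapping | None = None,
    artifact_k: float | None = 5.0,
) -> EpochedAverage:
    """Epoch a trace around onsets, reject artifacts, and average.

    ``artifact_k=None`` disables artifact rejection.  Raises if artifact
    rejection removes every epoch.
    """
    time_ms, epochs = extract_epochs(trace, sampling_rate, onsets_s, window_ms)
    if artifact_k is not None:
        epochs, log = reject_artifact_epochs(epochs, k=artifact_k)
        if log.all_rejected:
            raise ValueError("all epochs rejected as artifacts; average undefined")
    return average_epochs(time_ms, epochs, condition=condition)
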