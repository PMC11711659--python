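"""Synthetic evoked-potential data generation.

This module renders per-trial brainstem (ABR) and cortical (AEP) voltage
traces from a parametric waveform model, assembles them into continuous
multi-channel recordings following the four stimulation protocols used
downstream, and draws whole cohorts with genotype-dependent parameter
distributions.  It exists so that every analysis stage can be exercised
and calibrated without access to animal data.

Generative model
----------------
Each waveform deflection is a Gaussian-windowed monophasic bump with a
known polarity, peak latency, width (Gaussian sigma) and base amplitude,
so peak amplitude and latency are analytically known for oracle tests.
Brainstem components (latency < 10 ms) scale linearly with level above
the ear's true threshold::

    s_abr = level_gain * max(0, level - true_threshold)

Cortical components (latency in [15, 120] ms) additionally carry a
dimensionless cortical scale factor and a saturating recovery from
repetition suppression::

    s_aep = s_abr * aep_scale * (1 - exp(-ITI / adaptation_tau))

Gaussian sensor noise and an optional periodic biphasic heartbeat
transient (random phase) are added on top.  All randomness flows through
numpy Generator/SeedSequence streams, so seeded runs are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ContinuousRecording

__all__ = [
    "WaveComponent",
    "WaveTemplate",
    "EarSimParams",
    "Stimulus",
    "ProtocolSpec",
    "EarSession",
    "AnimalRecord",
    "CohortSimConfig",
    "DEFAULT_TEMPLATE",
    "CLICK_LEVELS",
    "LEVEL_SERIES_DB",
    "ITI_SERIES_MS",
    "PROTOCOL_ORDER",
    "default_protocols",
    "template_waveform",
    "heartbeat_train",
    "render_epoch",
    "simulate_ear_session",
    "simulate_cohort",
    "iter_cohort",
]

# Deflections earlier than this are brainstem components; at or after it,
# cortical components.
ABR_MAX_LATENCY_MS = 10.0
AEP_MIN_LATENCY_MS = 15.0
AEP_MAX_LATENCY_MS = 120.0

# Cortical components with base latency at or beyond this get the
# ear-specific latency shift (late waves only; the earliest cortical
# deflection is unshifted, matching the downstream contrast of interest).
LATE_AEP_LATENCY_MS = 30.0

CLICK_LEVELS = tuple(float(v) for v in range(20, 95, 5))
LEVEL_SERIES_DB = (70.0, 80.0, 90.0, 100.0)
ITI_SERIES_MS = (200.0, 250.0, 300.0, 350.0, 450.0)
PROTOCOL_ORDER = ("click-series", "tone-80dB", "level-series", "iti-series")


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian-windowed deflection of the evoked waveform."""

    polarity: int
    peak_latency_ms: float
    width_ms: float
    base_amplitude_uv: float

    def __post_init__(self):
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.width_ms <= 0:
            raise ValueError("width must be positive")
        if self.peak_latency_ms < 0:
            raise ValueError("latency must be non-negative")
        if self.base_amplitude_uv < 0:
            raise ValueError("base amplitude must be non-negative")

    @property
    def is_abr(self) -> bool:
        return self.peak_latency_ms < ABR_MAX_LATENCY_MS


@dataclass(frozen=True)
class WaveTemplate:
    """Morphology of the evoked response: a tuple of deflections.

    Brainstem components must peak before 10 ms; cortical components must
    peak within [15, 120] ms.
    """

    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        for c in comps:
            if not c.is_abr and not (
                AEP_MIN_LATENCY_MS <= c.peak_latency_ms <= AEP_MAX_LATENCY_MS
            ):
                raise ValueError(
                    f"cortical component latency {c.peak_latency_ms} ms outside "
                    f"[{AEP_MIN_LATENCY_MS}, {AEP_MAX_LATENCY_MS}] ms"
                )

    @property
    def abr_components(self) -> tuple:
        return tuple(c for c in self.components if c.is_abr)

    @property
    def aep_components(self) -> tuple:
        return tuple(c for c in self.components if not c.is_abr)


#: Default morphology: five brainstem waves followed by the P1/N1/P2-like
#: cortical triphasic complex.  Amplitudes/latencies are conventions tuned
#: for mouse-like waveforms, not measured values.
DEFAULT_TEMPLATE = WaveTemplate(
    (
        WaveComponent(+1, 1.5, 0.18, 3.0),
        WaveComponent(+1, 2.3, 0.20, 2.2),
        WaveComponent(+1, 3.1, 0.22, 4.0),
        WaveComponent(+1, 4.0, 0.25, 1.5),
        WaveComponent(+1, 4.8, 0.30, 1.0),
        WaveComponent(+1, 22.0, 3.5, 4.0),
        WaveComponent(-1, 38.0, 6.0, 3.0),
        WaveComponent(+1, 80.0, 12.0, 2.0),
    )
)


@dataclass
class EarSimParams:
    """Ground-truth physiological parameters of one simulated ear.

    ``level_gain`` is the multiplicative growth per dB above threshold;
    with the default 1/15, a component reaches its base amplitude 15 dB
    above threshold.  ``abr_latency_level_slope`` makes brainstem peak
    latencies decrease linearly with level above threshold (referenced to
    30 dB above threshold).
    """

    true_threshold: float = 35.0
    level_gain: float = 1.0 / 15.0
    adaptation_tau: float = 150.0
    aep_scale: float = 1.0
    latency_shift: float = 0.0
    noise_sd: float = 0.8
    heartbeat_rate: float = 5.0
    heartbeat_amp: float = 0.0
    abr_latency_level_slope: float = -0.005

    def __post_init__(self):
        if not 20.0 <= self.true_threshold <= 90.0:
            raise ValueError("true_threshold must lie in [20, 90] dB SPL")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.adaptation_tau <= 0:
            raise ValueError("adaptation_tau must be positive")
        if self.heartbeat_rate < 0:
            raise ValueError("heartbeat_rate must be non-negative")
        if self.level_gain < 0:
            raise ValueError("level_gain must be non-negative")


@dataclass(frozen=True)
class Stimulus:
    """One stimulus condition: kind, sound level, and preceding interval."""

    kind: str
    level_db: float
    iti_ms: float

    def __post_init__(self):
        if not 0.0 <= self.level_db <= 120.0:
            raise ValueError("stimulus level must lie in [0, 120] dB SPL")
        if self.iti_ms < 0:
            raise ValueError("preceding interval must be non-negative")


def _component_scale(comp: WaveComponent, params: EarSimParams, stim: Stimulus) -> float:
    excess = max(0.0, stim.level_db - params.true_threshold)
    s = params.level_gain * excess
    if not comp.is_abr:
        s *= params.aep_scale * (1.0 - np.exp(-stim.iti_ms / params.adaptation_tau))
    return s


def _component_latency(comp: WaveComponent, params: EarSimParams, stim: Stimulus) -> float:
    if comp.is_abr:
        excess = max(0.0, stim.level_db - params.true_threshold)
        return comp.peak_latency_ms + params.abr_latency_level_slope * (excess - 30.0)
    lat = comp.peak_latency_ms
    if lat >= LATE_AEP_LATENCY_MS:
        lat += params.latency_shift
    return lat


def template_waveform(
    template: WaveTemplate,
    params: EarSimParams,
    stimulus: Stimulus,
    time_ms: np.ndarray,
    components: str = "all",
) -> np.ndarray:
    """Deterministic (noise-free) waveform for one stimulus.

    ``components`` selects ``"all"``, ``"abr"`` or ``"aep"`` deflections.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    out = np.zeros_like(time_ms)
    for comp in template.components:
        if components == "abr" and not comp.is_abr:
            continue
        if components == "aep" and comp.is_abr:
            continue
        scale = _component_scale(comp, params, stimulus)
        if scale == 0.0:
            continue
        lat = _component_latency(comp, params, stimulus)
        amp = comp.polarity * comp.base_amplitude_uv * scale
        out += amp * np.exp(-0.5 * ((time_ms - lat) / comp.width_ms) ** 2)
    return out


def heartbeat_train(
    time_ms: np.ndarray,
    rate_hz: float,
    amp_uv: float,
    phase_ms: float,
    width_ms: float = 5.0,
) -> np.ndarray:
    """Periodic biphasic transient (Gaussian first derivative) train.

    ``phase_ms`` positions the first beat; beats recur every
    ``1000/rate_hz`` ms.  The wavelet is normalized so its positive peak
    equals ``amp_uv``.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    out = np.zeros_like(time_ms)
    if rate_hz <= 0 or amp_uv == 0:
        return out
    period = 1000.0 / rate_hz
    t0, t1 = time_ms[0], time_ms[-1]
    k_first = int(np.floor((t0 - 4 * width_ms - phase_ms) / period))
    k_last = int(np.ceil((t1 + 4 * width_ms - phase_ms) / period))
    for k in range(k_first, k_last + 1):
        centre = phase_ms + k * period
        u = (time_ms - centre) / width_ms
        out += amp_uv * u * np.exp(0.5 - 0.5 * u**2)
    return out


def render_epoch(
    template: WaveTemplate,
    params: EarSimParams,
    stimulus: Stimulus,
    rng: np.random.Generator,
    sampling_rate: float = 20000.0,
    window_ms: tuple = (-10.0, 150.0),
):
    """Render one noisy epoch of the full (ABR + AEP) waveform.

    Returns ``(time_ms, trace_uv)``.  The trace is the deterministic
    template waveform plus iid Gaussian noise (sd ``noise_sd``) plus a
    heartbeat transient train with uniformly random phase.
    """
    if sampling_rate < 10000.0:
        raise ValueError("sampling_rate must be at least 10 kHz")
    if not isinstance(stimulus, Stimulus):
        stimulus = Stimulus(*stimulus)
    w0, w1 = window_ms
    n = int(round((w1 - w0) * sampling_rate / 1000.0))
    time_ms = w0 + np.arange(n) * 1000.0 / sampling_rate
    trace = template_waveform(template, params, stimulus, time_ms)
    if params.noise_sd > 0:
        trace = trace + rng.normal(0.0, params.noise_sd, size=n)
    if params.heartbeat_amp != 0 and params.heartbeat_rate > 0:
        phase = rng.uniform(0.0, 1000.0 / params.heartbeat_rate)
        trace = trace + heartbeat_train(
            time_ms, params.heartbeat_rate, params.heartbeat_amp, phase
        )
    return time_ms, trace


# ---------------------------------------------------------------------------
# Protocols and sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolSpec:
    """One stimulation protocol: conditions, repetition count, channels."""

    name: str
    kind: str
    conditions: tuple
    n_reps: int
    sampling_rate: float
    channels: tuple


def default_protocols() -> dict:
    """The four stimulation protocols with their default parameters.

    Click series: 20-90 dB SPL in 5 dB steps, 500 repetitions per level
    at a 50 ms inter-onset interval.  Tone protocol: 16 kHz tones at
    80 dB SPL, 1000 repetitions at 300 ms ITI.  Level series: 70/80/90/
    100 dB SPL, 1000 repetitions each at 300 ms ITI.  ITI series:
    200/250/300/350/450 ms, 1000 repetitions each at 80 dB SPL.
    """
    return {
        "click-series": ProtocolSpec(
            name="click-series",
            kind="click",
            conditions=tuple(Stimulus("click", lv, 50.0) for lv in CLICK_LEVELS),
            n_reps=500,
            sampling_rate=20000.0,
            channels=("vertex", "bulla"),
        ),
        "tone-80dB": ProtocolSpec(
            name="tone-80dB",
            kind="tone",
            conditions=(Stimulus("tone", 80.0, 300.0),),
            n_reps=1000,
            sampling_rate=20000.0,
            channels=("vertex", "bulla", "cortical"),
        ),
        "level-series": ProtocolSpec(
            name="level-series",
            kind="tone",
            conditions=tuple(Stimulus("tone", lv, 300.0) for lv in LEVEL_SERIES_DB),
            n_reps=1000,
            sampling_rate=8000.0,
            channels=("cortical",),
        ),
        "iti-series": ProtocolSpec(
            name="iti-series",
            kind="tone",
            conditions=tuple(Stimulus("tone", 80.0, iti) for iti in ITI_SERIES_MS),
            n_reps=1000,
            sampling_rate=8000.0,
            channels=("cortical",),
        ),
    }


@dataclass
class EarSession:
    """All recordings for one ear plus its metadata and true parameters."""

    params: EarSimParams
    metadata: dict
    recordings: dict
    seed: int | None = None


_LEAD_S = 0.25
_GAP_S = 0.25
_TAIL_S = 0.30


def _render_protocol(
    spec: ProtocolSpec,
    params: EarSimParams,
    template: WaveTemplate,
    rng: np.random.Generator,
) -> ContinuousRecording:
    fs = spec.sampling_rate
    # lay out condition blocks on the sample grid
    blocks = []
    cursor = int(round(_LEAD_S * fs))
    for stim in spec.conditions:
        n_iti = int(round(stim.iti_ms * fs / 1000.0))
        if n_iti < 1:
            raise ValueError("inter-onset interval shorter than one sample")
        blocks.append((stim, cursor, n_iti))
        cursor += n_iti * spec.n_reps + int(round(_GAP_S * fs))
    n_total = cursor + int(round(_TAIL_S * fs))

    need_abr = "vertex" in spec.channels or "bulla" in spec.channels
    need_aep = "cortical" in spec.channels
    abr_sig = np.zeros(n_total) if need_abr else None
    aep_sig = np.zeros(n_total) if need_aep else None

    onsets = []
    attr_rows = []
    for stim, start, n_iti in blocks:
        seg_t = np.arange(n_iti) * 1000.0 / fs
        if need_abr:
            seg = template_waveform(template, params, stim, seg_t, components="abr")
            abr_sig[start : start + n_iti * spec.n_reps] += np.tile(seg, spec.n_reps)
        if need_aep:
            seg = template_waveform(template, params, stim, seg_t, components="aep")
            aep_sig[start : start + n_iti * spec.n_reps] += np.tile(seg, spec.n_reps)
        onset_idx = start + n_iti * np.arange(spec.n_reps)
        onsets.append(onset_idx / fs)
        attr_rows.extend(
            {
                "protocol": spec.name,
                "kind": stim.kind,
                "level_db": stim.level_db,
                "iti_ms": stim.iti_ms,
            }
            for _ in range(spec.n_reps)
        )

    onsets_s = np.concatenate(onsets)
    event_attrs = pd.DataFrame(attr_rows)

    hb = None
    if params.heartbeat_amp != 0 and params.heartbeat_rate > 0:
        phase = rng.uniform(0.0, 1000.0 / params.heartbeat_rate)
        t_all = np.arange(n_total) * 1000.0 / fs
        hb = heartbeat_train(t_all, params.heartbeat_rate, params.heartbeat_amp, phase)

    channels = {}
    half_sd = params.noise_sd / np.sqrt(2.0)
    for name in spec.channels:
        if name == "vertex":
            tr = 0.5 * abr_sig + rng.normal(0.0, half_sd, n_total)
            if hb is not None:
                tr += hb
        elif name == "bulla":
            tr = -0.5 * abr_sig + rng.normal(0.0, half_sd, n_total)
        elif name == "cortical":
            tr = aep_sig + rng.normal(0.0, params.noise_sd, n_total)
            if hb is not None:
                tr += hb
        else:
            raise ValueError(f"unknown channel {name!r}")
        channels[name] = tr

    return ContinuousRecording(
        channels=channels,
        sampling_rate=fs,
        onsets_s=onsets_s,
        event_attrs=event_attrs,
    )


def _scaled_protocols(protocols, n_reps, sampling_rates=None) -> dict:
    available = default_protocols()
    out = {}
    for name in protocols:
        if name not in available:
            raise ValueError(
                f"unknown protocol {name!r}; expected one of {sorted(available)}"
            )
        spec = available[name]
        if n_reps and name in n_reps:
            spec = replace(spec, n_reps=int(n_reps[name]))
        if sampling_rates and name in sampling_rates:
            spec = replace(spec, sampling_rate=float(sampling_rates[name]))
        out[name] = spec
    return out


def simulate_ear_session(
    params: EarSimParams,
    protocols: Sequence[str] = PROTOCOL_ORDER,
    seed=None,
    template: WaveTemplate = DEFAULT_TEMPLATE,
    n_reps: Mapping | None = None,
    sampling_rates: Mapping | None = None,
    metadata: Mapping | None = None,
) -> EarSession:
    """Simulate one ear's recordings for the requested protocols.

    ``n_reps`` and ``sampling_rates`` optionally override protocol
    defaults per protocol name (used to scale simulations down in tests).
    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the same
    seed yields bit-identical sessions.
    """
    specs = _scaled_protocols(protocols, n_reps, sampling_rates)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(PROTOCOL_ORDER))
    recordings = {}
    # spawn streams in canonical protocol order so a protocol's data does
    # not depend on which other protocols were requested
    for child, name in zip(children, PROTOCOL_ORDER):
        if name not in specs:
            continue
        rng = np.random.default_rng(child)
        recordings[name] = _render_protocol(specs[name], params, template, rng)
    return EarSession(
        params=params,
        metadata=dict(metadata or {}),
        recordings=recordings,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _default_genotype_effects() -> dict:
    return {
        "aep_scale": 0.5,
        "level_gain": 0.03,
        "adaptation_tau": 100.0,
        "latency_shift": 3.0,
    }


@dataclass
class CohortSimConfig:
    """Cohort-level simulation configuration.

    WT ear thresholds are drawn from a single Gaussian; deletion-carrier
    ears from a two-component mixture (normal-hearing vs hearing-
    impaired) with mixing weight ``df1_p_hi``, reproducing the bimodal
    threshold distribution with independent ears.  ``genotype_effects``
    are additive offsets applied to every deletion-carrier ear's
    parameters.
    """

    n_wt: int = 22
    n_df1: int = 29
    seed: int = 0
    wt_threshold_dist: tuple = (35.0, 4.5)
    df1_p_hi: float = 0.55
    df1_nh_dist: tuple = (36.0, 5.0)
    df1_hi_dist: tuple = (65.0, 7.0)
    genotype_effects: dict = field(default_factory=_default_genotype_effects)
    ear_independence: bool = True
    base_params: EarSimParams = field(default_factory=EarSimParams)

    def __post_init__(self):
        if self.n_wt < 0 or self.n_df1 < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not 0.0 <= self.df1_p_hi <= 1.0:
            raise ValueError("df1_p_hi must lie in [0, 1]")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CohortSimConfig":
        data = dict(data)
        if "base_params" in data and not isinstance(data["base_params"], EarSimParams):
            data["base_params"] = EarSimParams(**data["base_params"])
        for key in ("wt_threshold_dist", "df1_nh_dist", "df1_hi_dist"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("wt_threshold_dist", "df1_nh_dist", "df1_hi_dist"):
            d[key] = list(d[key])
        return d


@dataclass
class AnimalRecord:
    """Per-animal metadata plus both ear sessions."""

    animal_id: str
    genotype: str
    gender: str
    age_weeks: float
    left: EarSession
    right: EarSession


def _clip_threshold(value: float) -> float:
    return float(np.clip(value, 20.0, 90.0))


def _draw_ear_thresholds(config: CohortSimConfig, genotype: str, rng) -> tuple:
    """Draw ((thr_left, hi_left), (thr_right, hi_right)) for one animal.

    ``hi`` records which mixture component an ear was drawn from (None
    for WT ears, which come from a single Gaussian).
    """
    if genotype == "WT":
        mu, sd = config.wt_threshold_dist
        if config.ear_independence:
            return tuple((_clip_threshold(v), None) for v in rng.normal(mu, sd, 2))
        base = rng.normal(mu, sd)
        return tuple(
            (_clip_threshold(base + rng.normal(0.0, 2.0)), None) for _ in range(2)
        )
    # deletion carrier: per-ear mixture draw
    if config.ear_independence:
        out = []
        for _ in range(2):
            hi = bool(rng.random() < config.df1_p_hi)
            mu, sd = config.df1_hi_dist if hi else config.df1_nh_dist
            out.append((_clip_threshold(rng.normal(mu, sd)), hi))
        return tuple(out)
    hi = bool(rng.random() < config.df1_p_hi)
    mu, sd = config.df1_hi_dist if hi else config.df1_nh_dist
    base = rng.normal(mu, sd)
    return tuple(
        (_clip_threshold(base + rng.normal(0.0, 2.0)), hi) for _ in range(2)
    )


def _ear_params(config: CohortSimConfig, genotype: str, threshold: float) -> EarSimParams:
    params = replace(config.base_params, true_threshold=threshold)
    if genotype != "WT":
        updates = {
            key: getattr(params, key) + offset
            for key, offset in config.genotype_effects.items()
        }
        params = replace(params, **updates)
    return params


def iter_cohort(
    config: CohortSimConfig,
    protocols: Sequence[str] = (),
    template: WaveTemplate = DEFAULT_TEMPLATE,
    n_reps: Mapping | None = None,
    sampling_rates: Mapping | None = None,
) -> Iterator[AnimalRecord]:
    """Lazily generate animals one at a time (memory-friendly).

    With ``protocols=()`` the ear sessions carry metadata and true
    parameters but no waveform recordings.
    """
    ss = np.random.SeedSequence(config.seed)
    genotypes = ["WT"] * config.n_wt + ["Df1"] * config.n_df1
    children = ss.spawn(max(len(genotypes), 1))
    for i, (genotype, child) in enumerate(zip(genotypes, children)):
        meta_ss, left_ss, right_ss = child.spawn(3)
        rng = np.random.default_rng(meta_ss)
        gender = "F" if rng.random() < 0.5 else "M"
        age = float(np.clip(rng.normal(10.25, 1.35), 6.0, 16.0))
        (thr_l, hi_l), (thr_r, hi_r) = _draw_ear_thresholds(config, genotype, rng)
        prefix = "WT" if genotype == "WT" else "DF"
        animal_id = f"{prefix}{i + 1:03d}"
        ears = {}
        for side, thr, hi, ear_ss in (
            ("left", thr_l, hi_l, left_ss),
            ("right", thr_r, hi_r, right_ss),
        ):
            params = _ear_params(config, genotype, thr)
            meta = {
                "animal_id": animal_id,
                "genotype": genotype,
                "gender": gender,
                "age_weeks": age,
                "ear": side,
                "true_threshold": thr,
                "hi_component": hi,
            }
            if protocols:
                ears[side] = simulate_ear_session(
                    params,
                    protocols=protocols,
                    seed=ear_ss,
                    template=template,
                    n_reps=n_reps,
                    sampling_rates=sampling_rates,
                    metadata=meta,
                )
            else:
                ears[side] = EarSession(params=params, metadata=meta, recordings={})
        yield AnimalRecord(
            animal_id=animal_id,
            genotype=genotype,
            gender=gender,
            age_weeks=age,
            left=ears["left"],
            right=ears["right"],
        )


def simulate_cohort(
    config: CohortSimConfig,
    protocols: Sequence[str] = (),
    template: WaveTemplate = DEFAULT_TEMPLATE,
    n_reps: Mapping | None = None,
    sampling_rates: Mapping | None = None,
) -> list:
    """Materialize a whole cohort as a list of :class:`AnimalRecord`.

    Pass ``protocols=()`` (the default) to draw only metadata and true
    parameters, which is cheap even for hundreds of animals; request
    waveform protocols explicitly when they are needed.
    """
    return list(
        iter_cohort(
            config,
            protocols=protocols,
            template=template,
            n_reps=n_reps,
            sampling_rates=sampling_rates,
        )
    )


def cohort_metadata_frame(animals: Iterable[AnimalRecord]) -> pd.DataFrame:
    """One row per ear: animal_id, genotype, gender, age_weeks, ear,
    true_threshold."""
    rows = []
    for animal in animals:
        for session in (animal.left, animal.right):
            rows.append(dict(session.metadata))
    columns = ["animal_id", "genotype", "gender", "age_weeks", "ear", "true_threshold"]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]
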