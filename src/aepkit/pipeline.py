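"""End-to-end orchestration: simulate (or load) -> preprocess -> ABR ->
AEP -> cohort statistics, from a single config with full seeding and
deterministic text outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import abr as _abr
from . import aep as _aep
from . import stats as _stats
from .io import load_session, write_table
from .preprocess import bandpass_abr, differential_abr, epoch_and_average
from .simulate import (
    PROTOCOL_ORDER,
    AnimalRecord,
    CohortSimConfig,
    EarSession,
    iter_cohort,
)

__all__ = [
    "AnalysisParams",
    "RunConfig",
    "PipelineError",
    "analyze_ear_session",
    "build_cohort_table",
    "run_pipeline",
    "make_report",
    "STAT_MEASURES",
]

log = logging.getLogger("aepkit")

#: Measures fed to the cohort statistics stage.
STAT_MEASURES = (
    "p1n1_uv",
    "n1p2_uv",
    "gain_p1n1",
    "gain_n1p2",
    "level_slope_p1n1",
    "level_slope_n1p2",
    "iti_slope_p1n1",
    "iti_slope_n1p2",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisParams:
    """Algorithm parameters for every analysis stage."""

    abr_window: tuple = (-1.0, 12.0)
    abr_band: tuple = (100.0, 3000.0)
    detect_window: tuple = (1.0, 6.0)
    detect_criterion: float = 2.0
    detect_smooth_ms: float = 0.5
    wave1_window: tuple = (0.5, 2.5)
    aep_window: tuple = (-10.0, 150.0)
    aep_band: tuple | None = None
    artifact_k: float = 5.0
    hi_k: float = 2.5
    gain_floor_uv: float = 0.01
    n_perm: int = 2000
    flip_aep: bool = False

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AnalysisParams":
        data = dict(data)
        for key in (
            "abr_window",
            "abr_band",
            "detect_window",
            "wave1_window",
            "aep_window",
            "aep_band",
        ):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    simulation: CohortSimConfig = field(default_factory=CohortSimConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    protocols: tuple = PROTOCOL_ORDER
    n_reps: dict | None = None
    seed: int | None = None
    out_dir: str = "aepkit_run"
    session_dir: str | None = None

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "simulation" in data and not isinstance(data["simulation"], CohortSimConfig):
            data["simulation"] = CohortSimConfig.from_mapping(data["simulation"])
        if "analysis" in data and not isinstance(data["analysis"], AnalysisParams):
            data["analysis"] = AnalysisParams.from_mapping(data["analysis"])
        if "protocols" in data:
            data["protocols"] = tuple(data["protocols"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_mapping(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["protocols"] = list(self.protocols)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def effective_seed(self) -> int:
        return self.simulation.seed if self.seed is None else self.seed


def _condition_average(rec, trace, level_db=None, iti_ms=None, window=None, k=5.0):
    attrs = {}
    if level_db is not None:
        attrs["level_db"] = level_db
    if iti_ms is not None:
        attrs["iti_ms"] = iti_ms
    onsets = rec.select_events(**attrs)
    return epoch_and_average(
        trace, rec.sampling_rate, onsets, window_ms=window, condition=attrs, artifact_k=k
    )


def _abr_differential(rec, params: AnalysisParams) -> np.ndarray:
    # filtering and subtraction are both linear and the filter is
    # zero-phase, so filtering the difference once equals filtering each
    # electrode and then subtracting, at half the cost
    low, high = params.abr_band
    diff = differential_abr(rec.channels["vertex"], rec.channels["bulla"])
    return bandpass_abr(diff, rec.sampling_rate, low, high)


def _cortical_trace(rec, params: AnalysisParams) -> np.ndarray:
    trace = np.asarray(rec.channels["cortical"], dtype=float)
    if params.aep_band is not None:
        trace = bandpass_abr(trace, rec.sampling_rate, *params.aep_band)
    return trace


def analyze_ear_session(session: EarSession, params: AnalysisParams) -> dict:
    """Extract every per-ear measure from one session.

    Returns a flat dict: metadata, detected threshold, wave-1 features,
    tone-evoked AEP features and gains, per-condition amplitudes, and
    level/interval slopes.  Measures whose source protocol is absent are
    NaN.
    """
    row: dict = dict(session.metadata)
    nan = float("nan")

    rec = session.recordings.get("click-series")
    if rec is not None:
        diff = _abr_differential(rec, params)
        level_series = {}
        for level in sorted(rec.event_attrs["level_db"].unique()):
            level_series[float(level)] = _condition_average(
                rec, diff, level_db=float(level), window=params.abr_window,
                k=params.artifact_k,
            )
        result = _abr.detect_threshold(
            level_series,
            analysis_window=params.detect_window,
            criterion=params.detect_criterion,
            smooth_ms=params.detect_smooth_ms,
        )
        row["threshold_db"] = nan if result.threshold is None else result.threshold
    else:
        row["threshold_db"] = nan

    wave1 = None
    rec = session.recordings.get("tone-80dB")
    if rec is not None:
        diff = _abr_differential(rec, params)
        abr_avg = _condition_average(
            rec, diff, level_db=80.0, window=params.abr_window, k=params.artifact_k
        )
        wave1 = _abr.wave1_features(abr_avg, search_window=params.wave1_window)
        row["wave1_amp_uv"] = wave1.amplitude_uv
        row["wave1_lat_ms"] = wave1.latency_ms
        aep_avg = _condition_average(
            rec,
            _cortical_trace(rec, params),
            level_db=80.0,
            window=params.aep_window,
            k=params.artifact_k,
        )
        features = _aep.extract_aep_features(aep_avg, flip_polarity=params.flip_aep)
        row.update(
            p1_amp_uv=features.p1_amp,
            n1_amp_uv=features.n1_amp,
            p2_amp_uv=features.p2_amp,
            p1_lat_ms=features.p1_lat,
            n1_lat_ms=features.n1_lat,
            p2_lat_ms=features.p2_lat,
            p1n1_uv=features.p1n1,
            n1p2_uv=features.n1p2,
        )
        gains = _aep.central_gain(features, wave1, floor_uv=params.gain_floor_uv)
        row["gain_p1n1"] = gains.gain_p1n1
        row["gain_n1p2"] = gains.gain_n1p2
        row["gain_defined"] = gains.defined
    else:
        row.update(
            wave1_amp_uv=nan, wave1_lat_ms=nan, p1_amp_uv=nan, n1_amp_uv=nan,
            p2_amp_uv=nan, p1_lat_ms=nan, n1_lat_ms=nan, p2_lat_ms=nan,
            p1n1_uv=nan, n1p2_uv=nan, gain_p1n1=nan, gain_n1p2=nan,
            gain_defined=False,
        )

    def _series_features(rec, values, attr_name, col_key):
        out = {"p1n1": {}, "n1p2": {}, "p1_lat": {}, "n1_lat": {}, "p2_lat": {}}
        trace = _cortical_trace(rec, params)
        for v in values:
            avg = _condition_average(
                rec, trace, window=params.aep_window, k=params.artifact_k,
                **{attr_name: float(v)},
            )
            feats = _aep.extract_aep_features(avg, flip_polarity=params.flip_aep)
            out["p1n1"][v] = feats.p1n1
            out["n1p2"][v] = feats.n1p2
            out["p1_lat"][v] = feats.p1_lat
            out["n1_lat"][v] = feats.n1_lat
            out["p2_lat"][v] = feats.p2_lat
            row[f"p1n1_{col_key}_{v:g}"] = feats.p1n1
            row[f"n1p2_{col_key}_{v:g}"] = feats.n1p2
        return out

    rec = session.recordings.get("level-series")
    if rec is not None:
        levels = sorted(float(v) for v in rec.event_attrs["level_db"].unique())
        feats = _series_features(rec, levels, "level_db", "level")
        for key in feats:
            row[f"level_slope_{key}"] = _aep.level_slope(feats[key]).slope
    else:
        for key in ("p1n1", "n1p2", "p1_lat", "n1_lat", "p2_lat"):
            row[f"level_slope_{key}"] = nan

    rec = session.recordings.get("iti-series")
    if rec is not None:
        itis = sorted(float(v) for v in rec.event_attrs["iti_ms"].unique())
        feats = _series_features(rec, itis, "iti_ms", "iti")
        for key in feats:
            row[f"iti_slope_{key}"] = _aep.iti_slope(feats[key]).slope
    else:
        for key in ("p1n1", "n1p2", "p1_lat", "n1_lat", "p2_lat"):
            row[f"iti_slope_{key}"] = nan

    return row


def build_cohort_table(
    animals: Iterable[AnimalRecord],
    params: AnalysisParams | None = None,
) -> tuple:
    """Analyze every ear of every animal and assemble the cohort table.

    Returns ``(table, wt_stats)`` where ``wt_stats`` is the (mean, sd)
    of detected WT thresholds used for the NH/HI cutoff.  The table has
    one row per (animal, stimulated ear) with ``threshold_contra`` the
    stimulated ear's threshold and ``threshold_ipsi`` the opposite
    ear's.
    """
    params = params or AnalysisParams()
    rows = []
    for animal in animals:
        for session in (animal.left, animal.right):
            log.info("analyzing %s %s", animal.animal_id, session.metadata.get("ear"))
            rows.append(analyze_ear_session(session, params))
    if not rows:
        return pd.DataFrame(), (float("nan"), float("nan"))
    table = pd.DataFrame(rows)

    wt_thr = table.loc[
        (table["genotype"] == "WT") & table["threshold_db"].notna(), "threshold_db"
    ]
    if len(wt_thr) >= 2:
        wt_stats = (float(wt_thr.mean()), float(wt_thr.std(ddof=1)))
    else:
        wt_stats = (float("nan"), float("nan"))

    def _classify(thr):
        if not np.isfinite(wt_stats[1]) or wt_stats[1] <= 0:
            return "NA"
        value = None if (thr is None or (isinstance(thr, float) and math.isnan(thr))) else thr
        return _abr.classify_hearing(value, wt_stats[0], wt_stats[1], k=params.hi_k).label

    table["hi_class"] = table["threshold_db"].map(_classify)
    table["group"] = np.where(
        table["genotype"] == "WT", "WT", "Df1-" + table["hi_class"]
    )
    table["threshold_contra"] = table["threshold_db"]
    ipsi = table.set_index(["animal_id", "ear"])["threshold_db"]
    other = {"left": "right", "right": "left"}
    table["threshold_ipsi"] = [
        ipsi.get((aid, other[ear]), float("nan"))
        for aid, ear in zip(table["animal_id"], table["ear"])
    ]
    # stable column order: metadata first
    lead = [c for c in (
        "animal_id", "genotype", "gender", "age_weeks", "ear", "true_threshold",
        "threshold_db", "threshold_contra", "threshold_ipsi", "hi_class", "group",
    ) if c in table.columns]
    table = table[lead + [c for c in table.columns if c not in lead]]
    return table, wt_stats


def _run_stats(table: pd.DataFrame, params: AnalysisParams, seed: int) -> dict:
    """GLM screen, group comparisons, and ear-randomization tests for
    every standard measure.  Analyses that cannot run on the available
    data are recorded as skipped, not fatal."""
    summary: dict = {"glm": {}, "groups": {}, "randomization": {}}
    ss = np.random.SeedSequence(seed)
    rand_seeds = ss.spawn(len(STAT_MEASURES))
    for measure, rseed in zip(STAT_MEASURES, rand_seeds):
        if measure not in table.columns:
            continue
        sub = table.dropna(subset=[measure])
        try:
            res = _stats.fit_glm(sub, measure)
            summary["glm"][measure] = {
                "coef": res.params.to_dict(),
                "se": res.bse.to_dict(),
                "p": res.pvalues.to_dict(),
                "n_obs": res.n_obs,
                "n_dropped": res.n_dropped,
                "degenerate": res.degenerate,
            }
        except ValueError as exc:
            summary["glm"][measure] = {"skipped": str(exc)}
        groups = {
            name: grp[measure].to_numpy()
            for name, grp in sub.groupby("group")
            if len(grp) >= 2
        }
        try:
            if len(groups) >= 2:
                res = _stats.group_compare(groups)
                summary["groups"][measure] = {
                    "method": res.method,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "degenerate": res.degenerate,
                    "pairwise": {
                        " vs ".join(pair): dict(v) for pair, v in res.pairwise.items()
                    },
                }
            else:
                summary["groups"][measure] = {"skipped": "fewer than two groups"}
        except ValueError as exc:
            summary["groups"][measure] = {"skipped": str(exc)}
        try:
            res = _stats.within_between_randomization(
                sub, measure, n_perm=params.n_perm, seed=np.random.default_rng(rseed)
            )
            summary["randomization"][measure] = {
                "observed": res.observed,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "inside_ci": res.inside_ci,
                "n_perm": res.n_perm,
                "n_animals": res.n_animals,
            }
        except ValueError as exc:
            summary["randomization"][measure] = {"skipped": str(exc)}
    return summary


def _load_cohort_from_dir(session_dir: Path):
    """Group saved ear sessions (one .h5 per ear) into AnimalRecords."""
    paths = sorted(session_dir.glob("*.h5"))
    if not paths:
        raise PipelineError(f"stage 'load': no session files in {session_dir}")
    by_animal: dict = {}
    for path in paths:
        session = load_session(path)
        meta = session.metadata
        by_animal.setdefault(meta["animal_id"], {})[meta["ear"]] = session
    animals = []
    for animal_id, ears in sorted(by_animal.items()):
        if set(ears) != {"left", "right"}:
            raise PipelineError(
                f"stage 'load': animal {animal_id} missing an ear session"
            )
        meta = ears["left"].metadata
        animals.append(
            AnimalRecord(
                animal_id=animal_id,
                genotype=meta["genotype"],
                gender=meta["gender"],
                age_weeks=meta["age_weeks"],
                left=ears["left"],
                right=ears["right"],
            )
        )
    return animals


def run_pipeline(config: RunConfig):
    """Execute the full pipeline and write all stage outputs.

    Writes ``cohort_table.tsv``, ``stats_summary.json``, ``config.json``
    and ``manifest.json`` under ``config.out_dir``.  Identical
    config + seed produces byte-identical outputs.  Returns
    ``(manifest, cohort_table)``.
    """
    if config.session_dir is not None:
        session_dir = Path(config.session_dir)
        if not session_dir.is_dir():
            raise PipelineError(
                f"stage 'load': session directory {session_dir} does not exist"
            )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.effective_seed

    try:
        if config.session_dir is not None:
            animals = _load_cohort_from_dir(Path(config.session_dir))
        else:
            sim = dataclasses.replace(config.simulation, seed=seed)
            animals = iter_cohort(sim, protocols=config.protocols, n_reps=config.n_reps)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"stage 'simulate': {exc}") from exc

    try:
        table, wt_stats = build_cohort_table(animals, config.analysis)
    except Exception as exc:
        raise PipelineError(f"stage 'analyze': {exc}") from exc

    files = []
    config_path = out / "config.json"
    config_path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str))
    files.append(config_path.name)

    table_path = out / "cohort_table.tsv"
    write_table(table, table_path)
    files.append(table_path.name)

    try:
        if len(table):
            stats_summary = _run_stats(table, config.analysis, seed)
        else:
            stats_summary = {"empty_cohort": True}
    except Exception as exc:
        raise PipelineError(f"stage 'stats': {exc}") from exc
    stats_path = out / "stats_summary.json"
    stats_path.write_text(json.dumps(stats_summary, indent=2, sort_keys=True, default=float))
    files.append(stats_path.name)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "version": __version__,
        "wt_threshold_mean": wt_stats[0],
        "wt_threshold_sd": wt_stats[1],
        "n_rows": int(len(table)),
        "files": files,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest, table


def make_report(out_dir) -> Path:
    """Render a human-readable summary (markdown + figures) of a run.

    Sections with missing stage outputs are marked unavailable rather
    than failing.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Evoked-potential analysis report", ""]

    table_path = out / "cohort_table.tsv"
    table = None
    if table_path.exists():
        try:
            table = pd.read_csv(table_path, sep="\t")
        except pd.errors.EmptyDataError:
            table = pd.DataFrame()
    manifest = {}
    if (out / "manifest.json").exists():
        manifest = json.loads((out / "manifest.json").read_text())
    lines.append(f"- config hash: `{manifest.get('config_hash', 'unavailable')}`")
    lines.append(f"- seed: {manifest.get('seed', 'unavailable')}")
    lines.append("")

    if table is None or table.empty:
        lines.append("**Cohort table unavailable or empty; no data sections.**")
        (report_dir / "report.md").write_text("\n".join(lines) + "\n")
        return report_dir / "report.md"

    lines.append("## Cohort")
    lines.append("")
    counts = table.groupby(["genotype", "hi_class"]).size()
    lines.append(counts.to_frame("n_ears").to_markdown())
    lines.append("")

    lines.append("## Group medians")
    lines.append("")
    measures = [m for m in STAT_MEASURES if m in table.columns]
    med = table.groupby("group")[measures].median().round(4)
    lines.append(med.to_markdown())
    lines.append("")

    stats_path = out / "stats_summary.json"
    lines.append("## Statistics")
    lines.append("")
    if stats_path.exists():
        summary = json.loads(stats_path.read_text())
        for family in ("glm", "groups", "randomization"):
            entries = summary.get(family, {})
            lines.append(f"### {family}")
            lines.append("")
            for measure, res in entries.items():
                if "skipped" in res:
                    lines.append(f"- {measure}: skipped ({res['skipped']})")
                elif family == "glm":
                    sig = [k for k, p in res["p"].items() if isinstance(p, float) and p < 0.05]
                    lines.append(f"- {measure}: significant terms {sig or 'none'}")
                elif family == "groups":
                    lines.append(
                        f"- {measure}: {res['method']} p = {res['p']:.4g}"
                    )
                else:
                    lines.append(
                        f"- {measure}: observed {res['observed']:.3f}, null 95% CI "
                        f"[{res['ci_low']:.3f}, {res['ci_high']:.3f}], "
                        f"inside = {res['inside_ci']}"
                    )
            lines.append("")
    else:
        lines.append("**Statistics output unavailable.**")
        lines.append("")

    # growth-curve figures from per-condition columns
    for prefix, xlabel, fname in (
        ("p1n1_level_", "level (dB SPL)", "level_growth.png"),
        ("p1n1_iti_", "ITI (ms)", "iti_growth.png"),
    ):
        cols = sorted(
            [c for c in table.columns if c.startswith(prefix)],
            key=lambda c: float(c.removeprefix(prefix)),
        )
        if not cols:
            continue
        xs = [float(c.removeprefix(prefix)) for c in cols]
        fig, ax = plt.subplots(figsize=(5, 4))
        for group, grp in table.groupby("group"):
            mean = grp[cols].mean()
            sem = grp[cols].std(ddof=1) / np.sqrt(len(grp)) if len(grp) > 1 else 0
            ax.errorbar(xs, mean, yerr=sem, label=f"{group} (n={len(grp)})", marker="o")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("P1-N1 amplitude (µV)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(report_dir / fname, dpi=100)
        plt.close(fig)
        lines.append(f"![{fname}]({fname})")
        lines.append("")

    if {"threshold_db", "genotype"}.issubset(table.columns):
        fig, ax = plt.subplots(figsize=(5, 4))
        for genotype, marker in (("WT", "o"), ("Df1", "x")):
            sub = table[table["genotype"] == genotype]
            ax.scatter(
                np.arange(len(sub)), sub["threshold_db"], marker=marker, label=genotype
            )
        ax.set_ylabel("detected threshold (dB SPL)")
        ax.set_xlabel("ear index")
        ax.legend()
        fig.tight_layout()
        fig.savefig(report_dir / "thresholds.png", dpi=100)
        plt.close(fig)
        lines.append("![thresholds.png](thresholds.png)")
        lines.append("")

    path = report_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
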