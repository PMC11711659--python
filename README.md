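# aepkit

Auditory evoked-potential analysis in Python: from raw multi-channel
voltage traces to ABR hearing thresholds, cortical AEP features
(P1/N1/P2), central-gain and level-/interval-dependent slope statistics,
and cohort-level inference — plus a synthetic waveform simulator so that
every stage is testable and calibratable without animal data.

## What it does

- **simulate** — renders per-trial ABR/AEP voltage traces from a
  parametric waveform model (Gaussian-windowed deflections; linear growth
  with level above threshold; saturating recovery from repetition
  suppression with ITI; Gaussian noise and optional heartbeat artifacts),
  assembles the four stimulation protocols (click level series 20–90 dB
  SPL in 5 dB steps × 500 reps at 50 ms intervals; 80 dB tones × 1000 at
  300 ms ITI; level series 70/80/90/100 dB SPL; ITI series
  200/250/300/350/450 ms), and draws whole cohorts with bimodal
  deletion-carrier thresholds, independent ears, and configurable
  genotype effects.
- **preprocess** — zero-phase 100–3000 Hz band-pass, vertex-minus-bulla
  differential referencing, epoching, peak-to-peak artifact rejection
  (the documented stand-in for heartbeat-noise removal), and averaging
  with pointwise SEM.
- **abr** — hearing-threshold detection (lowest level whose averaged
  deflection reaches twice the time-dependent SEM, required consistently
  at all higher levels), wave-1 amplitude/latency, and NH/HI
  classification against the WT threshold distribution
  (mean + 2.5 SD cutoff).
- **aep** — P1 (15–30 ms max), N1 (25–60 ms min), P2 (60–120 ms max),
  P1-N1 and N1-P2 amplitude complexes, AEP/ABR central gain, and OLS
  slopes of features against level (dB) or ln(ITI).
- **stats** — Gaussian GLM predictor screen with Wald tests
  (`measure ~ C(genotype) + C(gender) + age + contralateral threshold +
  ipsilateral threshold`), within/between-animal correlation
  randomization test, Kruskal–Wallis + Dunn post-hoc, Mann–Whitney U,
  and Spearman rank correlation (exact p by enumeration at small n).
- **pipeline** — one-config orchestration with seeding, deterministic
  text outputs, HDF5 session containers, and a markdown + figure report.

## CLI

```bash
# end to end: simulate -> analyze -> statistics -> report
aepkit run-all --config config.yaml --seed 1 --out runs/demo

# or stage by stage
aepkit simulate --config config.yaml --seed 1 --out runs/demo/sessions
aepkit analyze  --session runs/demo/sessions/WT001_left.h5 --out ear.tsv
aepkit stats    --table runs/demo/cohort_table.tsv \
                --measure p1n1_uv --analysis randomization
aepkit report   --run-dir runs/demo
```

A minimal `config.yaml`:

```yaml
simulation:
  n_wt: 10
  n_df1: 16
  seed: 101
analysis:
  n_perm: 2000
protocols: [click-series, tone-80dB, level-series, iti-series]
n_reps:            # optional scale-down of protocol repetition counts
  click-series: 250
  tone-80dB: 250
out_dir: runs/demo
```

Python API mirrors the CLI: `aepkit.pipeline.run_pipeline(RunConfig(...))`
returns the manifest and cohort table (one row per animal × stimulated
ear).

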