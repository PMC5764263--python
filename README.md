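# eegdcm

Effective-connectivity analysis of motor execution (ME) vs motor imagery (MI)
on synthetic finger-tapping EEG, end to end:

1. **`synthetic_data`** — task paradigm (20 blocks/session; 4.0-s cue; 3–5 dot
   trials at 1.3-s intervals, dot 0.8 s + fixation 0.5 s; end-of-block button
   probe), ground-truth bilinear network dynamics over {PMC, SMA, M1, DLPFC},
   Gaussian-spread lead-field projection to a 32-channel 10–20 montage,
   mu/beta event-related desynchronization, eye-blink and spike artifacts,
   Bernoulli behavioural responses. Writes EDF + events TSV.
2. **`preprocess`** — 0.1–50 Hz zero-phase Butterworth band-pass, downsample
   to 512 Hz, epoch −1000..4000 ms around each block's first dot, blink
   template regression, block-level ±100 µV rejection, flat-channel detection
   and inverse-distance bad-channel interpolation.
3. **`ersp`** — Morlet (7-cycle) event-related spectral perturbation,
   dB-scaled to the pre-stimulus baseline; mu (8–12 Hz) / beta (13–20 Hz)
   band averages over per-trial windows; C3/C4 ERD indices.
4. **`source_recon`** — Tikhonov minimum-norm inverse on the known lead
   field; first-PC ROI time-series extraction with a deterministic sign
   convention.
5. **`dcm_core`** — bilinear dynamic causal models
   `dx/dt = (A + u·B)x + C·u_drive` with fixed self-decay, inverted by a
   variational-Laplace scheme (Gauss–Newton with Levenberg damping, Gamma
   fixed-point noise-precision update); free energy is the model-comparison
   currency.
6. **`bms`** — the 16-model space (PMC-input models 1–8, SMA-input models
   9–16), fixed-effects pooling of per-subject evidences, family-level
   inference (uniform family prior 1/2, model prior 1/16), within-family
   selection, Bayesian model averaging of B matrices.
7. **`group_stats`** — one-way ANOVA over edges, paired two-sided t-tests
   between streams, Benjamini–Hochberg FDR.
8. **`pipeline` / CLI** — orchestration over subjects × sessions ×
   (correct/incorrect) streams with a deterministic manifest.

Simplifications relative to a full anatomical pipeline are deliberate and
documented in the module docstrings: ICA blink removal is replaced by
deterministic template regression, and empirical-Bayes/BEM source
reconstruction by a Tikhonov minimum norm on a synthetic spherical lead
field. The neural model is the canonical bilinear state-space form, not a
neural-mass model.

## CLI

```sh
eegdcm simulate --session ME --n-blocks 20 --seed 1 --out runs/demo
eegdcm preprocess --in runs/demo.edf --events runs/demo.events.tsv --out runs/epochs.npz
eegdcm ersp --epochs runs/epochs.npz --out runs/ersp.tsv
eegdcm bms --evidence evidences.tsv --out runs/bms.json
eegdcm run-all --seed 1 --out runs/full        # simulate -> ... -> stats
```

`run-all` accepts a TOML config (`--config run.toml`) with top-level keys
(`n_subjects`, `n_blocks`, `model_indices`, ...) and `[simulate]` /
`[preprocess]` override tables; `--seed` takes precedence over the config.

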