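# synergybench

A simulation benchmark of five methods for extracting **spatial muscle
synergies** from surface-EMG envelope data: principal component analysis
(PCA), fixed-point independent component analysis (ICA), maximum-likelihood
factor analysis (FA), non-negative matrix factorization (NMF), and a sparse
undercomplete autoencoder (AE).

## Who this is for

Motor-control and myoelectric-interface researchers routinely factorize a
muscles × time activation matrix `M` into a few synergy vectors `W` and
activation coefficients `C` under the spatial synergy model

    M = g(W C + E),    g(x) = max(x, 0),

but the literature disagrees on which factorization to use.  Real recordings
have no ground truth, so this package builds one: it simulates activation
matrices from known `W` (unit-norm, exponential-weight synergies) and `C`
(synthetic EMG-like envelopes: moving-RMS filtered, resampled to 1,000
points, min–max normalized), adds Gaussian noise at controlled SNR over a
grid of channel counts (6–12 muscles) and SNRs (10–20 dB), and measures how
well each method recovers the signal and the generating synergies:

* **VAF** — variance accounted for by the rank-4 reconstruction,
* **SVS / ACS** — mean dot product between matched, sign-resolved,
  unit-normalized true and estimated synergy vectors / coefficient rows
  (optimal assignment on absolute dot products),
* **PA** — mean principal angle between the true and estimated synergy
  subspaces,
* a **chance baseline** from randomly generated synergy sets, and
* a **task-space check**: single-synergy features from a synthetic 6-class
  wrist-movement dataset fed to KNN / LDA / linear SVM / random-forest
  classifiers under shared stratified 5-fold cross-validation.

The extractors are scikit-learn-style transformers (`fit`, `transform`,
`inverse_transform`, `get_params`) operating on `(n_samples, n_channels)`
arrays, so they drop into sklearn pipelines; `extract_pca(M, k)`-style
helpers accept muscles × time matrices directly.

## Worked example

```python
import synergybench as sb

# one simulated 10-muscle trial at 15 dB with 4 ground-truth synergies
cfg = sb.SimulationConfig(n_channels=10, snr_db=15.0,
                          n_datasets=1, n_trials_per_dataset=1, seed=7)
trial = sb.generate_grid(cfg, channels=[10], snrs_db=[15.0])[0]

for result in (sb.extract_nmf(trial.M, 4, seed=0),
               sb.extract_pca(trial.M, 4)):
    rep = sb.evaluate_trial(trial, result)
    print(f"{result.method}: VAF={rep.vaf:.3f}  SVS={rep.svs:.3f}  "
          f"ACS={rep.acs:.3f}  PA={rep.pa_scalar_deg:.1f} deg")
```

prints

```
NMF: VAF=0.983  SVS=0.936  ACS=0.895  PA=5.7 deg
PCA: VAF=0.901  SVS=0.618  ACS=0.263  PA=5.7 deg
```

NMF reconstructs almost all of the signal energy and recovers the synergy
vectors closely (SVS 0.94).  PCA spans nearly the same subspace (PA ~6°) but
its orthogonality constraint prevents the components from aligning with the
non-negative, correlated true synergies, so its vector similarity is far
lower — at grid level it falls below the chance baseline, the benchmark's
most counterintuitive result.  (PCA's VAF is reported in its native
centered, explained-variance convention; NMF's is uncentered reconstruction
quality — see `docs/methods.md`.)

A full seeded run (simulate → extract → evaluate → summarize → classify):

```bash
synergybench all --scale tiny --seed 0 --out runs/demo
```

writes `metrics.csv` (one row per method × trial), summary/ANOVA/post-hoc
tables, a method × classifier accuracy table, and a manifest with content
hashes.  Stages are also available individually (`simulate`, `extract`,
`evaluate`, `classify`, `report`) and re-runnable from the on-disk artifacts.

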