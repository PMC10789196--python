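# icpolarity

Why do nearly all independent components (ICs) of scalp EEG come out with
*positive-dominant* scalp maps, and what does a flipped polarity say about
component quality?

ICA has a polarity indeterminacy: `(+map, +signal)` and `(-map, -signal)`
produce identical data, so each IC's sign is an engineering choice. The
de-facto standard EEG implementation resolves it implicitly: after symmetric
(ZCA) sphering `S = C^{-1/2}` the Infomax weights start at the identity, so
the iteration-0 mixing matrix is `C^{1/2}` — symmetric positive-definite with
a positive diagonal — and every initial scalp topography has a positive peak.
Components the algorithm locks onto quickly (clean, dipolar, high-variance
brain sources) keep that polarity; poorly determined components drift and may
flip. Flipped polarity then co-occurs with non-radial equivalent-dipole
orientations and high residual variance (RV).

`icpolarity` implements this analysis end to end on synthetic EEG with known
ground truth, for signal-processing and computational-neuroscience users who
want the mechanism reproducible rather than anecdotal:

- analytic single-sphere forward model (Legendre series) + idealized 10-10
  montage (`head_model`);
- a 62-channel synthetic-recording generator with radial/tangential brain
  dipoles, ocular/myogenic/electrode artifacts, and ground-truth mixing
  (`synthetic_data`);
- the concrete preprocessing steps: 1.5 Hz @ -6 dB Hamming FIR high-pass and
  full-rank average reference with reference recovery (`preprocess`);
- identity-initialized natural-gradient Infomax as a scikit-learn
  transformer, `InfomaxICA` (`ica`);
- topography skewness / dominance / mismatch metrics (`polarity`);
- equivalent-current-dipole fitting with RV and the radial-deviation angle
  (`dipole_fit`);
- k-means topography clustering, class rates by dominance group, the
  angle-by-RV density grid, and a multi-seed experiment runner + CLI
  (`analysis`, `cli`).

## Worked example

```python
from icpolarity import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(), seeds=[0, 1])
s = report.summary
print(f"{s['n_ics']} ICs from {s['n_datasets']} synthetic datasets")
print(f"positive-dominant: {s['pct_positive']:.1f}%   "
      f"negative-dominant: {s['pct_negative']:.1f}%")
print(f"skewness/dominance mismatch: {s['pct_mismatch']:.1f}%")
print(f"brain ICs positive: {100*s['brain_positive_rate']:.0f}%   "
      f"artifact/other ICs positive: {100*s['artifact_positive_rate']:.0f}%")
print("positive-IC density peak: angle %.0f deg, RV %.2f%%"
      % report.density_positive.peak())
print("negative-IC density peak: angle %.0f deg, RV %.2f%%"
      % report.density_negative.peak())
```

prints (about a minute on one CPU):

```
124 ICs from 2 synthetic datasets
positive-dominant: 68.5%   negative-dominant: 31.5%
skewness/dominance mismatch: 8.9%
brain ICs positive: 95%   artifact/other ICs positive: 63%
positive-IC density peak: angle 5 deg, RV 1.25%
negative-IC density peak: angle 95 deg, RV 1.25%
```

Reading: each 62-channel dataset yields one IC per channel. A clear majority
of ICs keep the positive initial polarity; ground-truth brain components keep
it far more often than artifact/noise components; the sign of the topography
skewness agrees with the peak sign for most ICs. The probability mass of
positive-dominant ICs sits at near-radial dipole angles with low residual
variance (gyral-type sources), while negative-dominant ICs concentrate near
90 deg — tangential, sulcal-type projections whose maps have balanced
positive and negative lobes, so their polarity is weakly constrained.

The same pipeline is scriptable from the shell:

```bash
icpolarity simulate --seed 0 --out rec.tsv
icpolarity decompose --recording rec.tsv --mixing-out mixing.tsv
icpolarity analyze --mixing mixing.tsv --out ic_records.tsv
icpolarity experiment --seeds 0,1,2 --outdir results/
icpolarity report --records ic_records.tsv
```

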