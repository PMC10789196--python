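# Methods

## The question

Scalp EEG decomposed with ICA yields independent components (ICs), each a time
series plus a scalp topography (a column of the mixing matrix rendered on the
electrodes). ICA cannot distinguish `(+map, +signal)` from `(-map, -signal)`:
the polarity of every IC is an engineering choice, not a physical fact. Yet in
practice almost all ICs come out *positive-dominant* — the peak-magnitude
electrode of the map is positive. This package implements the mechanism behind
that regularity and its downstream consequences, exercised entirely on
synthetic recordings with known ground truth:

1. **Mechanism.** With symmetric (ZCA) sphering `S = C^{-1/2}` and the Infomax
   weight matrix initialized at the identity, the iteration-0 mixing matrix is
   `S^{-1} = C^{1/2}` — symmetric positive-definite with a strictly positive
   diagonal. For well-conditioned, EEG-like covariance each column's
   peak-magnitude entry *is* its diagonal entry, so every initial topography
   is positive-dominant. Learning then preserves that polarity for components
   it can lock onto quickly — the clean, high-variance, dipolar ones — while
   poorly determined components drift and may flip.
2. **Consequences.** Positive-dominant ICs should therefore be enriched in
   brain sources, fit equivalent current dipoles with low residual variance
   (RV), and show near-radial dipole orientations (gyral crowns point
   outward); negative-dominant ICs collect tangential and poorly dipolar
   components.

## Forward model

A single homogeneous conducting sphere (radius `R = 85 mm`, conductivity
`sigma = 0.33 S/m`) stands in for the head. The surface potential of a dipole
at eccentric position `r0` with moment `p` is the classical Legendre series

```
V = (1/(4 pi sigma R^2)) * sum_{n>=1} ((2n+1)/n) (b/R)^(n-1)
    [ n p_r P_n(cos g) + p_t P_n'(cos g) sin-component ]
```

with `b = |r0|` and `g` the angle between `r0` and the electrode. At `r0 = 0`
it collapses to `V = 3 (p . r_hat) / (4 pi sigma R^2)`. The implementation is
validated against an independent closed form obtained from the generating
functions of the Legendre polynomials (see `tests/test_head_model.py`).

*Truncation.* The series tail decays like `(b/R)^n`. With the default 60
terms the relative truncation error is below 1e-8 for `b <= 0.7 R`, ~6e-5 at
`0.85 R`, and ~4% at the fitter's eccentricity cap of `0.95 R`. Simulator and
fitter share the same truncated operator, so dipole-recovery accuracy is not
limited by truncation; raise `HeadModel.n_terms` for standalone
high-eccentricity forward accuracy.

*Simplification.* A 3-shell head rescales potentials and blurs them slightly
but preserves the geometry (radial vs. tangential structure, map shapes) that
every claim here rests on; the homogeneous sphere keeps the model analytic.

*Montage.* Electrode positions follow the idealized spherical 10-10
construction: vertex at Cz, outer 10% ring at 72 deg inclination, midline at
18 deg steps, intermediate rows on the circle through their ring endpoints and
midline electrode at equal arc steps. The shipped `montage_62.tsv` fixture is
generated by this code and checked bit-exactly against it.

## Synthetic recordings

`default_scenario(seed)` defines the study conditions: 62 channels, 60 s at
250 Hz, 16 sources —

| class | n | geometry | waveform (unit RMS, then scaled) | RMS amplitude |
|---|---|---|---|---|
| brain, radial (gyral) | 8 | ecc 0.70–0.85 R, upper hemisphere, >=15 mm apart, moment within 10 deg of outward radial | 8–13 Hz noise x lognormal envelope | 15–30 nA·m |
| brain, tangential (sulcal) | 2 | same shell, moment within 10 deg of the tangent plane | 1/f noise x lognormal envelope | 15–30 nA·m |
| ocular | 2 | anterior-inferior orbits (y ~ 0.8 R), upward-anterior moment | sparse smooth blink pulses (~0.25/s) | 60–100 nA·m |
| myogenic | 2 | lateral 0.92 R, near-tangential | 20–45 Hz noise, burst-gated | 25–40 nA·m |
| single-electrode noise | 2 | identity column into one channel | burst-gated white noise | 6–10 uV |

Design notes:

- **Super-Gaussianity.** Infomax with the logistic nonlinearity assumes
  super-Gaussian sources. Brain waveforms are amplitude-modulated band-limited
  noise with a *lognormal* envelope (log-amplitude SD 0.5, ~0.5 Hz
  smoothness): excess kurtosis ~1.5–3, mirroring EEG burst statistics, with a
  bounded dynamic range so no single freak burst dominates a recording.
- **Independence.** Each source has its own child RNG stream. The sample
  correlation of two independent band-limited sources over 60 s has std
  ~0.045, so the maximum over all pairs typically lands at 0.05–0.12 — a
  sampling-resolution fact, not dependence.
- **Single-electrode artifacts** are intermittent broadband bursts
  (loose-contact "pops"). A *stationary Gaussian* single-channel source would
  be statistically identical to sensor noise and unrecoverable by any ICA, so
  intermittency is what makes the class meaningful.
- **SNR.** Sensor noise is white and independent per channel; its RMS is set
  so that the summed brain projection at the vertex channel is 10x the noise
  RMS (SNR 10).
- **Ground truth.** Stored mixing columns are exactly the average-referenced
  forward projections of the unit dipole moments (uV per nA·m); channel-noise
  sources mix through identity columns.

### What the generator does not emulate

No diffuse cortical background (the covariance is rank-16 plus a noise
floor), no non-stationarity across minutes, no volume-conduction blur from
skull inhomogeneity, no heart or line-noise classes, no eyes-open/closed
structure. Passing tests therefore demonstrate the *mechanism* and the
direction of its consequences, not the exact percentages any real database
would produce.

## Preprocessing

- **High-pass filter:** Hamming-window FIR, cutoff 1.5 Hz at -6 dB,
  transition bandwidth 1 Hz, order `ceil(3.3/(tb/sr))` rounded to even
  (827 taps at 250 Hz). Designed by spectral inversion of a unit-DC lowpass,
  so the DC null is exact; applied as a single forward convolution with
  group-delay compensation (zero phase) and edge-replication padding.
- **Full-rank average reference:** appends a zero channel for the initial
  reference electrode and subtracts the all-channel mean from every sample.
  Exact identities: the recovered reference equals minus the stacked-channel
  mean; the mean over the original n channels shrinks by the factor
  `1/(n+1)`; rank is preserved; the per-sample output mean is exactly zero.

That last identity is why the synthetic chain does **not** re-reference
before ICA: data whose per-sample mean is exactly zero have an exactly
singular covariance, which the sphering step (correctly) rejects. The
simulator instead emits recordings whose dipolar signal content is already
average-referenced while the amplifier noise is independent per channel —
full-rank data whose signal subspace behaves exactly like referenced EEG.
`fullrank_average_reference` is applied when ingesting external recordings
that carry a physical reference (CLI `decompose --reference`). Real pipelines
face the same rank deficit and handle it by rank reduction; that step is out
of scope here.

## ICA

Natural-gradient Infomax, logistic nonlinearity (extended sub/super-Gaussian
switching available), block updates over shuffled samples (block
`~sqrt(T/3)`), learning rate `0.001/ln(n_channels)` annealed by 0.9 whenever
the update direction turns by more than 60 deg relative to the last annealing
event, stop at squared weight change < 1e-6 or 512 passes. Weight blow-up
(|w| > 1e9) raises rather than silently restarting. **No polarity
post-processing of any kind is applied after fitting** — observing the
emergent polarity is the point. Components are ordered by descending mean
projected variance `mean_ch(A[:,k]^2) var(s_k)`.

The mixture-model decomposition used by some EEG pipelines is replaced by
this Infomax: the polarity mechanism is a property of sphering + identity
initialization, which both share, and the mixture machinery is orthogonal to
the question.

*Recovery metric.* The Amari index is permutation- and scale-invariant and
zero iff two mixings agree up to those indeterminacies. With 16 true sources
inside a 62-channel decomposition, each true column is first assigned its
best-matching component (Hungarian assignment on the absolute loadings);
non-injective matches inflate the index, as a failed recovery should.

*Iteration-0 polarity in the scenario.* On random well-conditioned SPD
sphering matrices the peak of every `C^{1/2}` column sits on the positive
diagonal (measured 100% over 200 draws x all columns). The scenario's
covariance is deliberately low-rank (16 sources + weak noise), and there the
peak can leave the diagonal for a minority of columns: scenario-level
iteration-0 positive dominance is ~75–98% by seed rather than exactly 100%.
This is a property of rank-deficient covariance, not of the mechanism; both
numbers are computed and reported.

## Per-IC metrics

- **Skewness** across electrodes, `m3/m2^{3/2}` without bias correction (the
  correction is a positive factor and cannot change a sign).
- **Dominance**: sign of the peak-magnitude entry; exact ties break to +1.
- **Mismatch**: `sign(skewness) != dominance`.
- **Equivalent dipole**: coarse grid (3 radii x 200 Fibonacci directions,
  0.3–0.85 R) with the moment solved by least squares against the
  average-referenced leadfield, then Nelder-Mead refinement from up to four
  well-separated best nodes, eccentricity capped at 0.95 R.
  `rv = 100 ||t - t_hat||^2 / ||t||^2`. Topographies are mean-subtracted
  before fitting (ICA maps are reference-free up to their mean). Multi-start
  matters: single-start simplex falls into a secondary basin for ~5–10% of
  planted dipoles.
- **Radial-deviation angle**: unfolded angle between fitted moment and the
  outward radial through the fitted position — 0 deg outward radial, 90 deg
  tangential, 180 deg inward radial. The unfolded convention is required
  because a polarity flip maps an outward-radial fit (small angle) to an
  inward-radial one (near 180 deg).
- **Class labels**: ground-truth classes transferred by Hungarian matching of
  `|unmixing . mixing_true|`; the 46 components matching no planted source are
  "other" (they decompose the sensor-noise subspace). A crude spectral-slope +
  focality labeller exists for real-data convenience and carries no claims.

## Aggregates

- **k-means** (k = 12, k-means++ seeding, 10 restarts) on L2-normalized
  topographies, run separately for positive- and negative-dominant groups;
  normalization keeps shape rather than amplitude as the similarity. Groups
  smaller than k keep cluster id -1.
- **Density grid**: 2-D histogram over angle (0–180 deg, 10 deg bins) x RV
  (0–50%, 2.5% bins), right-open bins except the last, out-of-range RV
  clipped into the top bin, normalized to total mass 1.
- **Experiment runner**: per seed — simulate, high-pass, sphere + Infomax,
  per-IC metrics — then pooled summaries (percent positive/negative,
  mismatch, class rates per dominance group, density grids, clusters). Output
  tables render to byte-stable TSV.

## Problem sizes and numerical choices

Twenty seeds of the 60 s / 62-channel scenario and 100 planted dipoles are
the package's canonical evaluation sizes; a full end-to-end decomposition
takes roughly 15 s, a dipole fit ~0.2 s. Tolerances that matter: sphering
rejects covariance with eigenvalue ratio below 1e-10; reconstruction and
inverse identities hold to 1e-8; dominance ties break to +1; `rv_max`
clipping keeps the density grid total at exactly 1.

## Known limitations

- The homogeneous sphere and idealized montage are geometric stand-ins; no
  anatomical claim attaches to fitted positions.
- Percentages (positive-dominance rate, mismatch rate) depend on the
  scenario's source mix and SNR; only their direction (majority positive,
  brain more positive than artifact, positive ICs radial with low RV) is the
  reproducible content.
- Rank-deficient inputs (exactly average-referenced files) are rejected at
  sphering rather than silently reduced.
- The extended-Infomax switching is implemented but the default scenario uses
  the logistic rule; sub-Gaussian sources are not part of the default
  conditions.
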