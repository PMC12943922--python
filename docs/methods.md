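# Methods

## Problem and pipeline

`ssaeeg` quantifies anesthetic depth from a single channel of frontal EEG
(µV, 128 Hz) by decomposing the signal into narrow spectral modes without
choosing basis functions or band edges in advance, and relating the modes'
instantaneous-frequency and power features to a clinical depth-of-anesthesia
index (BIS, 0–100).

The pipeline is:

1. **Epoching.** The recording is cut into 3-s epochs (384 samples) with a
   2-s hop, so consecutive epochs share 1 s.
2. **SSA.** The first 383 samples of each epoch are embedded with a 2-s
   window (K = 256) into an L×K = 128×256 Hankel trajectory matrix, which
   is decomposed by SVD into d = 128 eigentriples (σᵢ, uᵢ, vᵢ).
   Eigentriples are grouped — 0–1, 2–3, 4–6, 7–9, 10–19, 20–127 — and each
   group's rank-one sum is Hankelized by anti-diagonal averaging into one
   intrinsic mode function (IMF). The six IMFs sum exactly to the embedded
   series.
3. **Hilbert features.** Each IMF's analytic signal gives an instantaneous
   amplitude a(t) = |z(t)| and an instantaneous frequency from the
   derivative of the unwrapped phase. Two scalars summarize each IMF per
   epoch: CF, the a²-weighted mean IF (the first moment of the marginal
   Hilbert spectrum), and TP = 10·log₁₀(mean a²), in dB re 1 µV².
4. **Regression.** Per-epoch features are aggregated to an 8-s grid
   (median within each cell), medianed across the cohort, and the BIS is
   fit by OLS on the 12 parameters CF1–CF6, TP1–TP6. A reduced model keeps
   the parameters with p < 0.05 in the full fit (one pass, no stepwise
   iteration). Phase summaries split the 600-s span into three 200-s
   phases (maintenance / transition / emergence) and report per-parameter
   medians, IQRs, %change vs. maintenance, Kruskal–Wallis omnibus and
   Bonferroni-corrected pairwise Mann–Whitney tests.

## Numerical choices

- **Embedding length 383 vs. 384.** A 3-s epoch carries 384 samples, but a
  128×256 trajectory matrix requires N = L + K − 1 = 383. Epochs keep 384
  samples; the embedding uses the first 383 (`embed_length`, configurable).
  The 128×256 shape anchors the six-group split (group 6 spans ranks
  20–127).
- **Diagonal averaging** uses the anti-diagonal element counts
  min(s+1, L, K, N−s) as weights. This makes Hankelization an exact left
  inverse of the embedding (verified to 1e-12 in tests), which is the
  operative definition; published piecewise forms of the same operation are
  easy to mistype and are checked here against a brute-force double loop.
- **SVD** is full and deterministic (`numpy.linalg.svd`), with the sign
  convention that the largest-magnitude entry of each left singular vector
  is non-negative, so reruns are byte-identical. No truncation: group 6
  needs all 128 triples. For non-default window lengths (d ≠ 128) the
  group ranges are clipped to d and the last group extends to d − 1; empty
  groups yield zero IMFs.
- **Instantaneous frequency** is the central difference of the unwrapped
  analytic phase (one-sided at the ends). Samples whose amplitude is below
  1e-6 of the epoch peak have no meaningful phase and become missing;
  negative or above-Nyquist IF samples are excluded from CF and the
  marginal spectrum rather than clamped. A `trim_seconds` option discards
  epoch edges after the transform (default 0), since Hilbert edge effects
  on 3-s epochs can bias CF slightly.
- **TP normalization** is the per-sample mean of a² rather than the sum,
  so TP is invariant to epoch length.
- **Degenerate inputs.** An all-zero epoch yields six zero IMFs, a NaN
  contribution profile and a `degenerate` flag instead of an error; silent
  IMFs give missing CF/TP cells. Regression fits are complete-case (rows
  with any missing required cell are dropped and counted in the log); a
  rank-deficient design raises an error naming the offending columns.
- **%change** is 100·(median_phase − median_maint)/|median_maint|, so the
  sign always reflects the direction of change even when the maintenance
  median is negative.

## Synthetic recordings

The generator emulates the 10 minutes before emergence from
sevoflurane-type general anesthesia at 128 Hz, in three equal phases
cross-faded over 10 s:

| phase | delta (peak, Hz) | alpha spindles | fast band (RMS, Hz) | noise sd |
|---|---|---|---|---|
| maintenance | 20 µV @ 1.2 | 15 µV @ 11 Hz, 22/min × 2 s | 1.2 µV, 14–26 | 2.5 µV |
| transition | 12 µV @ 1.0 | 6 µV @ 10 Hz, 12/min × 1.5 s | 2.0 µV, 16–40 | 3.5 µV |
| emergence | 6 µV @ 0.8 | 2 µV @ 10 Hz, 3/min × 1 s | 1.8 µV, 20–36 | 5.0 µV |

Design considerations behind these defaults:

- Spindles are Hann-windowed bursts from a thinned Poisson process; the
  near-continuous maintenance duty cycle (~70%) reflects the strong frontal
  alpha of sevoflurane anesthesia and keeps the alpha modes anchored in
  eigentriple groups 2–3.
- The background is 1/f² (power) noise, matching the broadband rolloff of
  frontal EEG; with flatter noise the high-rank residual is already fast in
  maintenance and the emergence rise of CF6 disappears.
- Slow activity dominates total power in every phase — "low-amplitude
  beta" at emergence means exactly that — so the slow trend stays in IMF-1
  throughout and the mode ordering is stable.
- Each band's amplitude wanders slowly (sd 0.15 log₁₀ units, ~30-s
  timescale) and the fast band's center frequency follows a ±2.5 Hz slow
  walk, independently per recording. Without these the 12 features are
  collinear images of a single phase ramp and no individual coefficient
  can be resolved in the 12-regressor fit.
- A cohort applies ±10% per-recording jitter to amplitudes and frequencies
  through a documented seed tree (base seed → per-recording SeedSequence
  children → per-component draws); the BIS model is shared.

The programmed index is
BIS(t) = clip(64 − 10·log₁₀P_δ − 4·log₁₀P_α + 12·log₁₀P_β
\+ 1.5·(f_β − f_β,maint) + ε, 0, 100),
with per-second band powers smoothed over 15 s, f_β the fast-band center
frequency, and ε Gaussian (sd 1.5). On defaults it rises from ≈ 44
(maintenance) to ≈ 74 (emergence).

What the generator does **not** emulate: burst suppression, EMG/EOG and
movement artifacts, electrode pops, non-stationary spindle morphology, or
any physiologically mechanistic dynamics. Passing tests therefore show
that the pipeline recovers the programmed structure of a stylized but
spectrally realistic signal, not that it reproduces clinical BIS values on
real recordings.

## Problem sizes used by the verification scripts

The acceptance script and the heaviest tests use: 100 random series for
the Hankelization identity; 20 random matrices against a brute-force
eigen-oracle of XXᵀ; 200 OLS replicates at n = 75 (noise sd 3) for CI
coverage; 100 replicates for significance-selection recovery; the default
10-recording, 600-s cohort for the end-to-end fit; and 50 seeded
recordings for the emergence CF6-rise rate. These sizes give stable
percentages (binomial se ≲ 3%) while keeping a full run in the
low minutes on one core.

## Known limitations

- In-sample metrics only by default (the reduced model is selected and
  evaluated on the same table); cross-validation is available but not the
  default, mirroring common practice for this analysis.
- CF of very-low-frequency IMFs is poorly defined on 3-s epochs (fewer
  than two cycles); values below ~0.7 Hz carry large relative uncertainty.
- The 8-s grid / nearest-timestamp BIS matching assumes BIS timestamps
  within half a grid cell; sparser clinical exports produce missing rows
  that are dropped from fits.
- The six-group eigentriple split is fixed a priori; no automatic grouping
  (e.g. by w-correlation) is attempted.
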