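# Methods

`comaspectra` implements a quantitative-EEG pipeline for early outcome
prognostication in comatose patients after cardiac arrest, together with
a synthetic cohort generator that makes every stage testable without
clinical data. This note records the models, the parameters that matter,
and the design decisions taken where the procedure left genuine freedom.

## The analysis

### Spectral estimation

Resting EEG is band-pass filtered 1–40 Hz, down-sampled to 500 Hz, cut
into non-overlapping 5 s epochs, and average-referenced. Power spectra
are estimated per epoch and electrode on a fixed 2–40 Hz grid in 0.2 Hz
steps (191 bins) by the multitaper method: with a ±1 Hz smoothing
half-bandwidth and a 5 s window the time-bandwidth product is NW = 5,
giving K = 2·NW − 1 = 9 orthonormal Slepian (DPSS) tapers. Power at a
grid frequency is the uniform average over tapers of the squared tapered
DFT; no adaptive taper weighting and no zero-padding (the 5 s window
natively yields the 0.2 Hz grid). Epoch spectra are averaged, then
normalized by the sum of spectral values. The normalization scope is
per electrode by default (each electrode's 191-bin spectrum sums to 1),
which preserves the topographic contrast the cluster test uses; a
`global` mode (grand-sum normalization) is a config switch. Averaging
precedes normalization.

### Band discovery: cluster-based permutation test

Favourable-outcome (FO) and unfavourable-outcome (UO) spectra are
compared over the electrode × frequency plane with family-wise error
control by cluster-based permutation:

1. pointwise pooled-variance two-sample t at every (electrode, frequency)
   bin, df = n_FO + n_UO − 2; bins with zero pooled variance get t = 0
   with a logged warning;
2. cluster-forming mask |t| > the parametric two-sided critical value at
   `cluster_alpha` (default 0.05);
3. connected components per sign, where bins are adjacent when they share
   an electrode and are neighbouring frequency bins, or share a frequency
   bin and are neighbouring electrodes (no diagonal links); electrode
   neighbourhoods come from a Delaunay triangulation of 2-D template
   montage positions (a distance-threshold rule is available);
4. cluster mass = sum of t values over the cluster;
5. the null distribution is the most extreme cluster mass (max positive,
   min negative, collected separately per sign) over `n_perm` random
   reassignments of whole patients to groups (default 5000; never
   permutation of individual bins);
6. Monte-Carlo p with the add-one convention,
   p = (#{null at least as extreme} + 1)/(n_perm + 1), so the smallest
   attainable p is 1/(n_perm+1). A permutation that reproduces the
   observed labelling must count as "at least as extreme"; a relative
   tie tolerance of 1e-9 on the mass comparison protects that property
   against floating-point jitter between the vectorized permutation
   t-maps and the observed map.

Two-sided handling is per-tail by default: each tail is tested at
`alpha/2`, giving a level-`alpha` two-sided test; a single max-|mass|
null (`two_sided_mode="max_abs"`) is available. The discriminative band
is the longest contiguous frequency run covered by significant positive
clusters (FO above UO being the direction of interest); ties break
toward lower frequency, and a flag admits both signs.

### Outcome prediction

Stratified 5-fold cross-validation with matched FO/UO counts in every
train and test set (each class is shuffled and dealt round-robin with
offset starts; the per-fold |#FO − #UO| ≤ 1 invariant is verified and
violation is an error). Per fold, using training patients only: the
cluster test yields the fold's band (if no cluster is significant the
configured default band, 4.6–15.2 Hz, is used with a logged notice); each
patient's score is the unweighted mean of normalized power over all
electrodes and band bins; the threshold is the **maximum score among
training UO patients**. The rule "score > threshold ⇒ predict FO" (strict
inequality; a tie predicts UO) therefore classifies every training UO
patient correctly — zero training false positives, i.e. training PPV = 1
whenever any FO clears the threshold, which makes "maximal PPV" and
"correctly classifies all UO" the same rule. Held-out folds are scored
once with the frozen band and threshold.

The representative fold is the one whose extracted band spans the most
grid bins (ties: lowest fold index). Its frozen band and threshold are
applied unchanged to Day-2 spectra (same normalization pipeline).

Power predictions are combined with a binary clinical marker (EEG
reactivity or discontinuity) by a monotone OR: predict FO when either
source is favourable; a missing marker defers to power, a missing power
score defers to the marker, and a patient missing both is excluded with a
logged notice. The OR rule is an inference — it is the only monotone
combination consistent with published combined counts (combined TP at
least each component's TP; combined FP equal to the marker's FP when the
power rule has none).

### Metrics and sedation models

PPV, NPV, sensitivity, specificity and accuracy are computed from
TP/FP/FN/TN with exact Clopper–Pearson 95% CIs on each metric's own
numerator/denominator (beta-quantile inversion; lower bound 0 at zero
successes, upper bound 1 at full successes). Exact intervals are the
method of record because they reproduce published bounds (e.g. 18/18 →
lower bound 0.025^(1/18) ≈ 0.81) that Wald intervals do not. A metric
with zero denominator is reported as undefined, never 0. Report rounding
is half-up to 2 decimals.

Group comparisons use tie-corrected Kruskal–Wallis (retained even for two
groups) and the two-sided Fisher exact test in the minimum-likelihood
convention (sum of all tables, at fixed margins, no more probable than
the observed one, with 1e-12 numerical slack); a zero-margin table is
degenerate and returns p = 1 with a logged notice.

The sedation analysis fits four binomial logit models of P(FO) on the
Day-1 band-power score (PS) and the propofol/midazolam/fentanyl infusion
rates (P, M, F): main effects always, plus all three PS×rate interactions
(full model) or all but one (three reduced models). Fits are plain
fixed-effects maximum likelihood — no grouping factor exists in the
design, so no random effect is fitted. Non-administered agents enter as
rate 0; a patient with an unknown rate is excluded with a logged count.
Perfect separation raises an explicit error rather than returning
unbounded coefficients. Models are ranked by AIC = 2k − 2·logL, ties
broken by fewer parameters; ranking requires identical observation sets.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised: by default 45 FO and 46 UO patients, each with a Day-1 and a
Day-2 recording, on a 19-channel 10-20 template montage (a 63-channel
10-10 template is selectable; the analysis is montage-agnostic and the
smaller array keeps desk-scale runs fast).

Each channel is 1/f^β Gaussian background (β = 1, spectrally shaped
noise, flat below 1 Hz, RMS 10 µV) plus a band-limited oscillation.
The oscillation is Gaussian noise whose spectral amplitude envelope is
the local background envelope times (pedestal + Gaussian peak): the peak
is patient-specific (centre ~ Normal(10, 1.5) Hz clipped to the band,
width 2 Hz) and the pedestal equals the peak height (`osc_floor = 1`), so
the relative in-band power elevation is approximately uniform across the
band with an alpha-ish bump on top. The raw spectral support extends
1 Hz beyond `bump_band` (default 4.6–15.2 Hz) on each side
(`edge_widen`), compensating the ±1 Hz multitaper smoothing so the
full-strength smoothed elevation spans exactly the nominal band — this is
what makes "the injected band" a well-defined recovery target. The
oscillation RMS is `gain` × the background's nominal in-band RMS, with
gain 1.0 for FO on Day 1, 0.2 for FO on Day 2 (attenuation), and 0 for UO
(the UO in-band shape is pure 1/f — an assumption, exposed in config,
since only lower in-band power for UO is established). Channels covary
through a common oscillatory source (mixing coefficient 0.3) with
per-channel loadings ~ Uniform(0.5, 1.5); the rest of the oscillatory
power is channel-independent.

Two per-patient lognormal traits create realistic between-patient spread
of the band score: a gain jitter (σ = 0.3) and a sub-band
"delta-dominance" multiplier (σ = 0.5) scaling background power below the
band's low edge. The latter matters: the normalized band score moves
through the normalization denominator, so patients with heavy
low-frequency activity score lower regardless of outcome. Without it the
UO score distribution is implausibly tight (CV < 1%) and even the
attenuated Day-2 effect would separate the groups perfectly; with it the
generated cohorts reproduce the qualitative two-day structure — high PPV
and specificity with partial sensitivity on Day 1, chance-level
prediction when the Day-1 threshold is applied to Day 2.

The raw signal is synthesized at `fs_raw` (default 1200 Hz), band-pass
filtered 1–40 Hz, resampled to 500 Hz and epoched — through the same
preprocessing code real data would use. Test and acceptance runs
synthesize directly at 500 Hz and use 6–30 epochs per recording; the
resampling path is exercised by its own unit tests.

Sedation rates are truncated-at-zero normal draws with per-outcome,
per-day means/SDs and administration probabilities matching the marginal
structure of the emulated cohort (e.g. FO Day-1 propofol
2.46 ± 1.23 mg/kg/h, administered with probability 34/43); the joint
distribution across agents and days is not claimed. A whole sedation
record is missing with the cohort's marginal missingness (2/45 for FO).
Clinical markers are Bernoulli draws parameterized by sensitivity for FO,
specificity for UO, and missingness (reactivity 31/39, 31/36, 16/91;
discontinuity 30/44, 33/40, 7/91; epileptiform chosen at plausible
values 0.90/0.50/0.05 as no published counts constrain it). Missing
metadata is always encoded as missing ("NA"), never as zero.

Everything is deterministic given the seed: per-patient random streams
are spawned from one `SeedSequence`, so Day-1 data are identical whether
or not Day 2 is generated.

### What the generator does not emulate

No artifacts (ocular, cardiac, electrode pops), no burst-suppression
morphology, no temperature effects, no non-stationarity within a
recording, no true joint sedation-outcome-EEG dependence (sedation is
drawn independently of the EEG given outcome and day). Passing tests
therefore demonstrate the statistical machinery — calibration, leakage
freedom, band recovery, threshold behaviour — not clinical performance on
real recordings.

## Numerical and design choices

- **Band-pass filter**: zero-phase Butterworth, order 12 per pass
  (forward–backward). The order is chosen so that 50 Hz mains content is
  attenuated below 1% in amplitude after both passes for a 1–40 Hz band
  (|H(50)|² ≈ 0.005); a common 4th-order design only reaches ≈ 14% this
  close to the band edge. Passband is maximally flat (Butterworth); no
  phase distortion by construction.
- **Resampling**: polyphase FIR with the rational rate factor; output
  length round(n·fs_out/fs_in).
- **Channel interpolation**: unweighted mean of good neighbours
  (spherical splines are deliberately out of scope; the neighbour-mean is
  the tested default and the adjacency graph is the same one the cluster
  test uses).
- **ICA artifact removal**: not implemented; `ica_hook` is an identity
  extension point. Synthetic inputs are clean by construction.
- **Permutation chunking**: permutation t-maps are computed 200 at a time
  from group-sum/group-sum-of-squares matrices; connected components run
  per permutation on the sparse supra-threshold subgraph.
- **Degenerate inputs**: single-channel re-referencing, empty bands,
  all-zero spectra, zero-margin tables, groups smaller than two, classes
  smaller than k — all raise typed errors naming the problem; they are
  never silently coerced.
- **Representative-fold tie-break** and the **strict threshold
  inequality** are fixed, documented conventions (ties predict UO).
- **Problem sizes**: the default end-to-end run and the acceptance script
  use 91 patients × 30 epochs at 500 Hz with 500 permutations; the
  cluster-test calibration uses 200 null cohorts of 8+8 patients × 6
  epochs; band recovery uses 20 cohorts of 20+20 patients × 20 epochs.
  These sizes give stable Monte-Carlo estimates at desk scale and are the
  package's own defaults for its test conditions.

## Known limitations

- The per-electrode normalization couples frequency bins within an
  electrode; the cluster test's exchangeability argument is unaffected,
  but bin-level t-values are not independent (they never are for EEG).
- The threshold rule's test-set false-positive rate is an order
  statistic, ≈ 1/(n_UO,train + 1) per held-out UO patient, so pooled PPV
  below 1 is expected even under a strong effect.
- Day-2 behaviour depends on the persistence of patient traits across
  days (the generator keeps delta dominance and gain jitter fixed per
  patient); real day-to-day variability would loosen the Day-2 null
  further.
- EDF export is not provided; recordings are stored as raw float32 with a
  JSON sidecar. EDF reading for real data requires the optional `mne`
  dependency.
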