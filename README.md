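# comaspectra

Quantitative-EEG outcome prognostication for comatose patients after
cardiac arrest.

After resuscitation from cardiac arrest, many patients remain comatose
and clinicians must judge, within days, whether recovery of consciousness
is likely. Resting-EEG power spectra carry prognostic signal: on the
first day of coma, patients with favourable outcome (FO; cerebral
performance category 1–2 at three months) show elevated normalized power
in a theta–alpha band (~4.6–15.2 Hz) relative to patients with
unfavourable outcome (UO), and a threshold on the band-averaged power can
predict FO with very high positive predictive value — a "no false
positives" marker of good prognosis. This package implements that
analysis end to end, for methodologists and clinical-EEG researchers who
want to apply it to their own recordings or study its statistical
behaviour:

- **multitaper spectral estimation** — per 5 s epoch and electrode,
  2–40 Hz in 0.2 Hz steps, K = 2·NW − 1 = 9 Slepian tapers for ±1 Hz
  smoothing; epoch-averaged and normalized by the sum of spectral values;
- **cluster-based permutation testing** over the electrode × frequency
  plane (cluster mass = Σt over connected supra-threshold bins; max-mass
  permutation null; two-sided at α with α/2 per tail) to discover the
  discriminative band without multiple-comparison inflation;
- **cross-validated threshold classification** — stratified 5-fold CV
  with matched FO/UO counts; per fold, the band from the training-set
  cluster test and the threshold `max(training UO scores)`, so the rule
  `score > threshold ⇒ FO` has training specificity 1 (maximal PPV) by
  construction;
- **predictive metrics with exact 95% CIs** (Clopper–Pearson) for
  PPV/NPV/sensitivity/specificity/accuracy, and OR-combination of the
  power-based prediction with clinical EEG markers (reactivity,
  discontinuity);
- **sedation-interaction models** — binomial logit of P(FO) on the band
  score and propofol/midazolam/fentanyl infusion rates with
  score × rate interactions, compared by AIC — plus Kruskal–Wallis /
  Fisher-exact group comparisons;
- a **seeded synthetic cohort generator** (1/f background + outcome- and
  day-dependent band-limited oscillation, sedation and clinical-marker
  metadata with realistic marginals) so the full pipeline runs and is
  tested without any clinical data.

See `docs/methods.md` for the model details and design decisions.

## Worked example

Generate a small synthetic cohort, find the discriminative band, and
cross-validate the threshold classifier:

```python
import numpy as np
from comaspectra.synthetic import CohortConfig, generate_cohort
from comaspectra.pipeline import compute_spectra
from comaspectra.spectral import SpectrumGrid
from comaspectra.clusterstat import build_adjacency, cluster_permutation_test, extract_band
from comaspectra.prognosis import stratified_kfold, crossvalidate

config = CohortConfig(n_fo=20, n_uo=20, n_epochs_per_recording=30,
                      fs_raw=500.0, seed=8)
records = generate_cohort(config, days=(1,))
labels = {r.patient_id: r.outcome for r in records}
grid = SpectrumGrid()
spectra = compute_spectra(records, 1, "per_electrode", grid)

adjacency = build_adjacency(records[0].eeg[1].channel_positions,
                            list(records[0].eeg[1].channel_labels))
fo = [p for p, o in labels.items() if o == "FO"]
uo = [p for p, o in labels.items() if o == "UO"]
result = cluster_permutation_test(
    np.stack([spectra[p].values for p in fo]),
    np.stack([spectra[p].values for p in uo]),
    adjacency, n_perm=500, seed=8)
band = extract_band(result, grid)
print(f"discriminative band: {band.fmin}-{band.fmax} Hz")

folds = stratified_kfold(labels, k=5, seed=8)
cv = crossvalidate(spectra, labels, folds, adjacency, n_perm=500, seed=8)
print(f"pooled PPV {cv.pooled.ppv}")
print(f"pooled specificity {cv.pooled.specificity}")
print(f"pooled sensitivity {cv.pooled.sensitivity}")
```

prints

```
fold 0: no significant cluster; falling back to band 4.6-15.2 Hz
fold 1: no significant cluster; falling back to band 4.6-15.2 Hz
discriminative band: 5.8-14.6 Hz
pooled PPV 0.94 (0.70-1.00)
pooled specificity 0.95 (0.75-1.00)
pooled sensitivity 0.75 (0.51-0.91)
```

The full-cohort cluster test localizes the injected 4.6–15.2 Hz effect
(recovered edges sit inside it; at 20 patients per group the
supra-threshold region does not quite reach the true edges). Held-out
PPV and specificity are high — the maximal-PPV threshold rule is built
to avoid false positives — while sensitivity is partial: patients whose
oscillatory elevation is small relative to their spectral background
fall below the zero-false-positive threshold. Two of the five training
folds (16 + 16 patients) produce no significant cluster on their own and
fall back to the configured default band, with a logged notice; larger
cohorts discover the band in every fold.

The same pipeline runs from the shell:

```bash
comaspectra simulate --out cohort/ --seed 7
comaspectra spectra --in cohort/ --out spectra.tsv --day 1
comaspectra cluster-test --spectra spectra.tsv --meta cohort/cohort_meta.tsv \
    --day 1 --n-perm 5000 --seed 11 --out clusters.json
comaspectra cv-predict --spectra spectra.tsv --meta cohort/cohort_meta.tsv \
    --k 5 --seed 11 --out cv/
comaspectra run-all --out results/ --seed 7   # everything, one command
```

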