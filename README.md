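# uraman — chemometric urinalysis of Raman spectra

`uraman` is a reusable, tested implementation of a Raman chemometric
urinalysis pipeline for characterizing the *range of normal* of healthy
human urine. Raman spectra of urine capture signatures of hundreds of
metabolites at once (urea at 1002 cm⁻¹ dominates, with creatinine 680,
collagen 870, uric acid 981 and glucose 1071/1117 cm⁻¹); the pipeline
turns raw replicate scans into interpretable statistics:

1. **Preprocessing** — baseline correction with an asymmetric,
   iteratively reweighted polynomial fit (penalty clipped over peak
   channels so fluorescence background is removed without eating the
   peaks), replicate-scan averaging, and vector (L2) normalization.
2. **PCA** — mean-centered decomposition of the 400–1800 cm⁻¹ analysis
   window; variance-tier component selection (90/95/99/99.9%) and
   attribution of dataset variance to Raman shifts.
3. **DAPC** — a Gaussian linear discriminant on the leading principal
   component scores, used to classify donor attributes (sex, donor
   identity, menstruation) from a spectrum.
4. **Blind leave-one-out validation** — for every specimen, PCA *and*
   discriminant are refit on the remaining n−1 spectra and the held-out
   spectrum is predicted; accuracy, sensitivity and specificity are
   reported from the collected predictions.
5. **Distance statistics** — each specimen is reduced to its distance
   from a synthetic-urine negative control:
   TPD = √(Σᵢ₌₁..₄ (P_u,i − P_control,i)²) in PC-score space and TSD
   (the same distance over all windowed channels), analyzed by 2-way
   ANOVA and Tukey HSD.

A seeded synthetic-cohort generator (`uraman.synthetic_data`) emulates
the statistical structure of a urine specimen bank — per-donor
metabolite concentration profiles with sex/age/donor/day effects,
fluorescence baseline, replicate scans with noise, and a fixed control —
so every stage is testable without instrument data.

Audience: spectroscopists and biomedical data scientists building or
evaluating Raman-based urinalysis screens.

## Worked example

```python
import numpy as np
from uraman import synthetic_data as sd, spectra_io as io
from uraman import preprocess as pp, chemometrics as cm, stats, validation as val

# a small mixed-sex cohort with a 2x male urea band, plus control scans
cfg = sd.CohortConfig(n_female=15, n_male=15, specimens_per_donor=2,
                      scans_per_specimen=3, sex_multiplier={"urea": 2.0},
                      donor_cv=0.02, day_cv=0.01, noise_sd=0.002, seed=7)
scans, meta = sd.generate_cohort(cfg)
ctrl_scans, _ = sd.generate_control(cfg, 5)

spectra = pp.preprocess_set(io.assemble_set(scans + ctrl_scans, cfg.grid))
spectra = pp.truncate_window(spectra)          # 400-1800 cm^-1, 701 channels

pca = cm.fit_pca(spectra)
print(round(100 * np.cumsum(pca.variance_fraction)[3], 1))   # 99.2

labels = dict(zip(meta.specimen_id, meta.sex))
cohort = spectra.subset([i for i, s in enumerate(spectra.specimen_ids)
                         if s != "CTRL"])
res = val.loo_validate(cohort, labels, positive_class="F", tier_or_npcs=0.99)
print(res.accuracy, res.metrics.sensitivity, res.metrics.specificity)
# 1.0 1.0 1.0

table = stats.distance_table(spectra, pca, ["CTRL"])
print(round(float(table["tpd"].mean()), 3))    # 0.133
```

The first four principal components carry 99.2% of this cohort's
variance (the configured urea effect is the only strong variation);
with a 5σ class separation the blind leave-one-out routine classifies
every specimen's donor sex correctly; the mean four-component distance
of specimens from the synthetic-urine control is ≈ 0.13 in normalized
intensity units.

The same pipeline is scriptable from a shell:

```sh
uraman simulate cohort --seed 1 --out-dir sim/
uraman preprocess --scans sim/scans.csv --meta sim/metadata.csv --out pre.csv
uraman pca --set pre.csv --window 400:1800 --out model/
uraman loo --set pre.csv --meta sim/metadata.csv --label-column sex \
           --positive-class F --variance-tier 0.99 --out report.csv
uraman tpd --set pre.csv --model model/ --meta sim/metadata.csv --out distances.csv
uraman anova --distances distances.csv --meta sim/metadata.csv --factors sex,birth_year
uraman tukey --distances distances.csv --meta sim/metadata.csv --group donor_id
```

Every output directory receives a `manifest.json` (command line, config
snapshot, input digests, seed, version) so deterministic runs are
reproducible from the manifest alone.

## Layout

- `src/uraman/spectra_io.py` — CSV dialects (wide/long scans, metadata),
  grid resampling, the `SpectrumSet` container.
- `src/uraman/preprocess.py` — baseline correction, replicate
  averaging, vector normalization, window truncation.
- `src/uraman/chemometrics.py` — PCA, variance-tier selection, loading
  attribution, DAPC fit/predict, model persistence.
- `src/uraman/validation.py` — blind leave-one-out routine, confusion
  metrics (binary and one-vs-rest).
- `src/uraman/stats.py` — TPD/TSD, 2-way ANOVA (types I/II/III, two-step
  interaction protocol), Tukey HSD, per-donor TPD summaries.
- `src/uraman/synthetic_data.py` — seeded cohort, control, and 30-day
  generators.
- `src/uraman/cli.py` — the `uraman` command.
- `docs/methods.md` — models, assumptions, parameter choices and
  limitations.
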