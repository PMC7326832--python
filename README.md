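# reims — lipidomic tissue recognition for REIMS / iKnife workflows

Rapid evaporative ionisation mass spectrometry (REIMS) analyses the aerosol
produced by electrosurgical diathermy: the "surgical smoke" carries a
lipid-dominated negative-ion spectrum that differs between normal rectal
mucosa, adenoma and carcinoma. Coupled to a transanal excision platform,
this allows burn-by-burn tissue recognition during dissection — flagging an
involved margin while the surgeon can still act on it.

This package implements the complete analysis behind such a system, for
chemometricians and computational mass spectrometrists:

- **Spectral handling** — centroided spectra with patient/sample metadata, a
  fixed statistical axis (m/z 600–1000, half-open 0.1 Th bins), a plain-text
  interchange format and read-only mzML input.
- **Quality gating** — the signal-to-background statistic
  `median(top-20 peak intensities) / median(all intensities)`; spectra with
  a value below 1500 are excluded.
- **Preprocessing** — total-ion-count (TIC) normalisation and a
  zero-preserving log transform `log10(1 + 10^4 x)`.
- **Chemometrics** — hand-rolled NIPALS OPLS-DA (orthogonal partial least
  squares discriminant analysis): orthogonal components uncorrelated with
  class membership are filtered out, predictive components extracted, and
  new spectra classified by Mahalanobis distance to class centroids in
  predictive score space.
- **Validation** — leave-one-patient-out cross-validation (no fold ever
  sees its held-out patient), contingency tables, diagnostic metrics, the
  binary disease/no-disease task, an any-positive-spectrum sample rule, and
  reconstruction of integer 2×2 tables from rounded published summaries.
- **Discriminant ions** — per-bin one-way ANOVA with Benjamini–Hochberg FDR
  control and annotation against a lipid mass table.
- **Layer recognition** — the glycerophospholipid:triglyceride (GPL:TG)
  ratio as a mucosa / mixed / submucosa gauge, and a streaming mode that
  replays burns against a saved model archive.
- **Synthetic cohorts** — a generator with class-structured log-normal peak
  abundances, patient random effects, multiplicative noise, exponential
  baseline and injectable low-signal acquisitions, since no real spectra
  are publicly deposited.

## The model in brief

Spectra are binned, TIC-normalised and logged into a matrix **X**; classes
are one-hot encoded into **Y**. OPLS-DA removes `n_orth` components of **X**
whose scores are exactly uncorrelated with **Y** (weights taken from the
current loading projected off the span of **XᵀY**), then extracts `n_pred`
predictive components by two-block NIPALS. A spectrum's predictive scores
**t** are classified by

  d_c(t) = √((t − μ_c)ᵀ S⁻¹ (t − μ_c)),

the Mahalanobis distance to each class centroid μ_c under the pooled
within-class score covariance S; the nearest class wins (ties break
lexicographically). Accuracy is estimated by leave-one-patient-out
cross-validation with all preprocessing statistics recomputed per fold.

## Worked example

```sh
python examples/cross_validation.py
```

```
three-class contingency table (truth x predicted):
predicted  adenoma  normal  tumour
truth
adenoma         31       1       4
normal           0     121       0
tumour          11       0      98
three-class accuracy: 94.0%

binary accuracy 99.6%, sensitivity 99.3%, specificity 100.0%, PPV 100.0%, NPV 99.2%
```

The synthetic cohort mirrors the published study shape (47 patients, 77
samples, 266 spectra: 121 normal / 109 tumour / 36 adenoma). The dominant
error mode — adenoma predicted as tumour — is built into the generator
(adenoma means are damped copies of tumour means), and collapsing to the
binary disease/no-disease task largely removes it, exactly the behaviour
that makes the binary model the clinically relevant one. Other capabilities
have matching scripts in `examples/` (QC gating, discriminant ions, layer
indication, streaming recognition).

## Spectrum file format

One record per spectrum; `#` lines are comments:

```
>spectrum
spectrum_id = p01-T-00
patient_id = p01
sample_id = p01-T
tissue_label = tumour        # normal | adenoma | tumour | unknown
burn_index = 0               # optional
600.4798734347314	189.05
603.9973294120966	2.13
...
```

Peak lines are `m/z<TAB>intensity`, m/z strictly ascending, intensities
non-negative. The same format feeds the CLI pipeline:

```sh
reims --seed 1 simulate --out cohort.tsv
reims qc    --spectra cohort.tsv --out qc.tsv
reims train --spectra cohort.tsv --out model.json --binary
reims cv    --spectra cohort.tsv --out cv.tsv --summary cv.json --binary
reims predict --model model.json --spectra cohort.tsv --out burns.tsv
reims report --cv-summary cv.json
```

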