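# Methods

This note documents the models and procedures implemented in `oilspec`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic data can and cannot show.

## Study designs

Two built-in designs drive all desk-scale analyses.

* **Mexican design** (`build_design_mexican`): two market chia oils A and B,
  each adulterated with sunflower (S), rapeseed (R) and corn (C) oil at
  1, 2, 5, 10 and 50 mass %, plus the five native oils and nine additional
  50:50 combinations — 38 labelled blends × 3 preparations = 114 prepared
  samples.
* **Kenyan design** (`build_design_kenyan`): six chia oils U–Z from
  different growth sites, adulterated with sunflower at 10 and 50 mass % —
  17 blends; U100, X100, US90, US50, WS50 and XS90 prepared once, the rest
  twice, giving 28 prepared samples.  Site W carries no 90:10 blend, so its
  regression series has only two reference levels (0 and 50 %); the code
  accepts two-level series for exactly this reason.

Each prepared sample is measured 5 times per instrument; the joint design
yields 710 spectra per modality (570 Mexican + 140 Kenyan).

## Synthetic spectra

The generator emulates three instruments on fixed grids: EEM fluorescence
(excitation 300–550 nm × emission 350–700 nm, 10 nm steps, 26 × 36 = 936
points), NIR (800–2795 nm at 15 nm, 134 points) and Raman (350–3200 cm⁻¹,
1681 evenly spaced points).  The NIR point count and Raman sampling density
are chosen so that the fused vector has exactly 936 + 134 + 1681 = 2751
features, matching the instrument configuration being emulated (stated
ranges and NIR resolution fix everything except the Raman density).

**Endmembers.**  Each pure oil is a sum of Gaussian bands plus a low-order
polynomial baseline per modality; EEM features are 2-D Gaussians.  Band
placements follow standard vegetable-oil assignments — chlorophyll
fluorescence at excitation 405 nm / emission 670 nm (present in every chia
oil, nearly absent in the refined adulterants), tocopherol and
oxidation-product fluorescence (stronger in the adulterants), NIR C–H
overtone/combination bands, and the Raman C–C/C=C/CH₂ modes whose relative
amplitudes track polyunsaturation.  Kenyan site oils share the chia template
with deterministic per-site modulations plus seeded jitter; the Raman
fluorescence-background level varies strongly per oil, as it does in
practice.  The library guarantees pairwise cosine similarity of rendered
pure fused spectra below 1 − 10⁻³.

**Mixing** is linear in mass fraction with no interaction terms — the
standard Beer–Lambert-style assumption, adequate for desk-scale validation
and exactly assertable (a 50:50 blend is the pointwise mean of its
endmembers).

**Noise** (`NoiseModel`) is applied per measured spectrum in fixed order:
multiplicative gain `1 + N(0, 0.01)`, a smooth random cubic baseline drift
(coefficient SD 0.02; NIR/Raman only, since EEMs have no comparable drift
term here), then i.i.d. additive Gaussian noise with SD 0.005 on the
unit-scale intensities (≈ 0.5 % of a typical band amplitude).  These
defaults were fixed once as instrument-realistic values at which the
pipeline defaults reach the intended headline quality; they are exposed in
the config and CLI (`--noise-profile clean` disables noise entirely).  One
RNG stream per dataset, seeded explicitly, makes every output
bit-reproducible.

Replicate preparations are modelled as independent noise draws only; no
systematic preparation bias, photobleaching, inner-filter or temperature
effects are simulated.

## Preprocessing

NIR and Raman spectra are baseline-corrected as
`I_BC(k) = I(k) − cumsum[smooth(diff I, 20)]` and then SNV-transformed.
`smooth` is a centered moving average; an even span is forced down to the
next odd value (20 → 19) and endpoints are averaged over the largest
symmetric window that fits.  The first differences shorten the vector by
one, so the cumulative baseline is applied with a one-point offset,
anchoring the first point (`out[0] = I[0]`) and preserving length.  Window
shrinkage (rather than truncation) at the endpoints is an assumption and is
configurable.  Since `cumsum(diff I) = I(k) − I(0)`, the correction is a
high-pass filter: any affine trend maps to a constant (asserted
analytically in the tests) and features wider than roughly the smoothing
span are suppressed — endmember bandwidths were chosen narrow enough to
survive it.

SNV uses the sample (n−1) standard deviation; the difference from the
population form is negligible at n ≥ 134 but is fixed for
bit-reproducibility.  Constant spectra are rejected rather than silently
zeroed.

Fluorescence EEMs are flattened excitation-major and left raw in
single-modality analyses.  At fusion time the flattened EEM is SNV-scaled so
its intensities are commensurate with the preprocessed NIR/Raman blocks,
then the three blocks are concatenated in the fixed order fluorescence →
NIR → Raman (block offsets 0/936/1070).  Single-modality fluorescence
analyses can optionally apply SNV (`fluo_snv`), mirroring the
with/without-preprocessing comparison of fluorescence-only models.

## Augmentation and 5-class assembly

The classification task uses five classes: A, Adult A, B, Adult B, Adult.
Adult A and Adult B hold 15 design labels each (the twelve 1–10 %
adulterations plus the three 50:50 blends with that chia oil), i.e.
15 × 3 × 5 = 225 real spectra.  The three remaining classes are balanced to
225 rows by simulation: `Ĩ(k) = I(k) + SD(k)·ran(k)` with `I(k)` either the
class mean or an original spectrum (cycled in order), `SD(k)` the pointwise
sample SD of the class's real spectra, and `ran(k)` i.i.d. standard normal.

* Class A (and B): the 15 original spectra used five times (75 rows) + 75
  mean-based + 75 original-based simulated rows = 225.
* Class Adult: 90 real spectra (S100/R100/C100 and RS50/RC50/SC50) + 45
  mean-based + 45 original-based simulated rows from the 45 pure S/R/C
  spectra + one extra copy of those 45 = 225.

Augmentation operates on already-preprocessed spectra (order: preprocess →
augment), so simulated rows live in the model's feature space.  The literal
duplication of originals inflates apparent class support — nearest-neighbour
and training metrics benefit from exact duplicates — which is a caveat of
the assembly recipe itself, not of its implementation; the permutation-null
test shows the held-out TPR still collapses to chance when labels carry no
information.

## Classification protocol

The evaluation protocol is fully specified (the point-and-click workflow it
mirrors leaves it implicit): stratified 80/20 holdout per run; TPR = %
correct on the holdout; "training accuracy" = mean 5-fold CV accuracy inside
the training partition; per-class sensitivity/specificity/precision/accuracy
from a one-vs-rest collapse of the holdout confusion matrix.  Models: CART
decision tree (Gini, ≤ 100 splits), pooled-covariance LDA with automatic
shrinkage (mandatory at p ≫ n), 1-NN with Euclidean distance, and
standardized one-vs-one SVMs with linear and cubic-polynomial kernels.
Argmax/vote ties resolve to the lowest class index (scikit-learn's
convention).  Precision of a never-predicted class is reported as NaN and
excluded from aggregates with a warning — never imputed as zero.  Repeated
runs (default seeds 1–10) re-simulate the augmentation and re-split with the
same seed, so runs are independent end-to-end replicates; aggregates report
mean, sample SD and median.

## PLSR quantification

"Components" are PLS latent variables (standard chemometrics usage).  For
each series, candidate counts (1–32 for Mexican series; 3 to min(10, n−2)
for the small Kenyan series) are scored by leave-one-out CV; the count with
minimal RMSECV is selected, ties going to fewer components (parsimony; the
selection criterion is otherwise unstated in the emulated protocol).  R²,
RMSEP and RMSEP_range are computed from the CV predictions at the selected
count — prediction quality, not training fit.  The 3σ detection limit uses
the CV predictions of the 0 %-adulteration samples of the series as blanks
(out-of-model prediction of blanks being the conservative choice).  X is
mean-centred, not variance-scaled, inside PLSR; SNV already handles scale.

LOO folds are accelerated by an exact SVD row-space reduction (PLS is
equivariant under orthonormal feature rotation, and every fold's training
rows lie in the row space of the full centred matrix), and one PLS fit at
the maximal candidate count per fold yields the regression vectors of all
truncated counts via `B_a = W_a (P_aᵀ W_a)⁻¹ Q_aᵀ`.  The fast path is
verified against a naive per-fold fit on the raw features in the test
suite.

## Problem sizes and runtime

All shipped analyses are desk-scale: a series is 7 labels × 3 preparations
× 5 measurements = 105 spectra (Mexican) or 15–30 spectra (Kenyan); the
classification set is 1125 × 2751.  The full test suite runs in well under
two minutes on a single core, and the acceptance script (five replicate
seeds × two series × four modalities of full LOO-CV PLSR) in about half a
minute.

## What passing tests do and do not show

The synthetic generator reproduces the combinatorial structure of the
designs exactly and the spectral phenomenology qualitatively (low-rank
linear mixtures, modality-appropriate baselines, realistic noise ordering).
It does not reproduce measured spectral shapes, inter-batch chemistry,
nonlinear instrument response, or matrix effects.  Consequently, exact
counts, equation-level results and protocol properties transfer to real
data as-is, while the near-perfect classification and regression figures
obtained here demonstrate internal consistency of the pipeline under its
own assumptions — on real spectra the same pipeline will be limited by
chemistry, not by the code path.

## Known limitations

* Linear mixing ignores fluorescence inner-filter effects and
  intermolecular interactions; at high pigment loads real EEMs are
  sub-linear.
* The noise model has no wavelength-correlated component besides the smooth
  drift; real detectors show structured noise.
* The "validation accuracy" of the emulated workflow could not be given an
  operational definition distinct from the holdout TPR; the package reports
  the macro-averaged one-vs-rest holdout accuracy under that name and makes
  no attempt to reproduce externally reported validation-accuracy bands.
* Detection limits from CV-predicted blanks are optimistic when the blank
  predictions are nearly unbiased, as they are on clean synthetic data.
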