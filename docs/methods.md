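# Methods

This note documents the models, defaults and numerical choices behind the
package, what the synthetic phantoms do and do not emulate, and the design
decisions taken where the problem was genuinely open.

## Phantom model

Each subject is a 64³ voxel grid at 1 mm isotropic spacing containing an
axis-aligned ellipsoid tumor (semi-axes drawn uniformly from 8–14 voxels,
with a ≥ 2-voxel margin enforced) whose boundary is perturbed by a smooth
random field so masks are non-spherical but still exact ground truth.
Texture inside the tumor is a Gaussian random field synthesised by Gaussian
smoothing of white noise (spectral synthesis) with a class-specific
correlation length, renormalised to unit variance and scaled by a
class-specific heterogeneity SD. Class appearance defaults:

| parameter | glioblastoma | PCNSL | unit |
|---|---|---|---|
| CE-T1W pattern | rim 160 / core 60 | uniform 120 | a.u. |
| texture correlation length | 4.0 | 1.5 | voxels |
| heterogeneity SD | 25 | 8 | a.u. |
| tumor ADC mean | 1.0×10⁻³ | 0.7×10⁻³ | mm²/s |

Background "brain" is 40 a.u. CE-T1W, ADC 0.8×10⁻³ mm²/s, with mild smooth
spatial variation; additive acquisition noise defaults to SD 4 a.u. The ADC
gap mirrors the hypercellularity of lymphoma; the rim/core + heterogeneity
contrast mirrors ring enhancement and necrosis in glioblastoma. These
values were chosen once as a qualitatively realistic and clearly learnable
contrast; they are deliberately strong, so internal-validation AUCs sit at
the ceiling and the scientifically interesting quantity is the behaviour
under protocol shift.

The diffusion pair is generated as `S_b = S₀ · exp(−b·ADC_true)` with
b = 1000 s/mm², applied to the (noisy) b0 volume, so the two-point relation
holds exactly by construction and the ADC round-trip is exact to machine
precision even with acquisition noise on S₀. Noise reaches the ADC channel
through S₀ and through the protocol shift, which perturbs each volume
independently. An `atypical_fraction` knob is reserved for
necrotic/hemorrhagic PCNSL variants but defaults to 0: no quantitative
description of that subgroup was available to emulate.

**Protocol shift.** The external site is emulated per image (never the mask
or label) by, in order: thick-slice acquisition along z (slab averaging at
the target thickness, default 4 mm, then linear upsampling back to the
native grid), Gaussian blur (FWHM in mm), a global intensity scale, a
subject-level intensity drift (TE/TR nuisance), and additive noise. The
identity shift returns the input volumes bit-identically. The phantoms do
**not** model anatomy, multi-coil physics, motion, bias fields or Rician
noise statistics, so a passing pipeline here demonstrates correct mechanics
and protocol-sensitivity behaviour, not clinical performance.

**Seeding.** One master seed spawns per-subject streams via
`SeedSequence(entropy=cohort_seed, spawn_key=(index,))`; all derived seeds
stay below 2³¹. Every stage is a pure function of (inputs, config, seed);
a full experiment rerun reproduces the identical report hash.

## Preprocessing

CE-T1W intensities are z-normalised within a brain mask (mean 0, unit
sample SD; the same affine map applied outside the mask). This stands in
for histogram-landmark normalisation of real T1 data — the contract
preserved is a comparable intensity scale across subjects. Co-registration
is an explicit identity hook: phantoms are generated aligned. ADC outliers
are flagged (never zeroed) when beyond ±3 sample SDs of a single-pass mean
over the valid ROI voxels; statistics are per-ROI rather than per-brain, a
documented interpretation choice. Resampling uses tri-linear interpolation
(output shape `ceil(extent/target)`), nearest-neighbour for masks so they
stay binary.

## Feature engine

Gray levels: 32 equal-width bins over the within-mask min–max, half-open
with the top bin closed (quantization is therefore invariant to affine
intensity rescaling). GLCMs are accumulated symmetrically for the 13 unique
3-D directions (26-neighbourhood modulo sign) at distances 1–3; GLRLMs
count maximal equal-level runs per direction, broken at the mask boundary.
Texture descriptors are averaged over directions; GLCM is reported per
distance, GLRLM once. The 22 GLCM descriptors are the classic Haralick +
cluster set; the 21 GLRLM descriptors are the 16 standard run-length
measures plus five marginal descriptors (gray-level/run-length means and
entropies, max probability), fixed in `manifest.py` and asserted at import:
17 + (22×3 + 21) = 104 per source, × (original + 8 sub-bands) = 936.

First-order entropy and uniformity use the same 32-bin quantization;
energy is Σx² over masked voxels (distinct from uniformity = Σp²);
variance/SD are sample (n−1); kurtosis is Pearson (normal → 3).

Wavelets: single-level separable orthonormal Haar via PyWavelets with
periodization boundary handling — chosen so the Parseval identity is exact
on dyadic grids and odd dimensions remain well defined. Sub-band masks are
the truth mask sampled on the decimated lattice (`mask[::2,::2,::2]`). A
sub-band ROI that is empty, or admits no voxel pair at some displacement,
yields zeros for the affected features with a warning, keeping the vector
length at exactly 936.

Degenerate guards: a single-cell GLCM has correlation 0 (zero-variance
guard); IMC1/2 guard their entropy denominators; all divisions are
protected. Ties everywhere (selector argmax, elimination argmin) break by
manifest/column order for determinism.

## Feature selection

- **mRMR** (MID variant): greedily maximise `I(f;y) − mean_{s∈S} I(f;s)`
  with mutual information on 4 equal-frequency bins; default subset size 20
  (capped at the table width).
- **CFS**: best-first forward search on the merit
  `k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` (point-biserial class correlation,
  |Pearson| feature–feature), stopping after 5 consecutive non-improving
  expansions; zero-variance features are skipped with a warning.
- **Backward elimination**: univariate-AUC prefilter to 100 features, then
  drop the least-important feature under the inner model (componentwise GLM
  boosting) one at a time, scoring every set by inner 5-fold CV AUC and
  returning the best set. The prefilter keeps desk-scale runtime; the inner
  scorer mirrors the grid's boosting classifier.

By default selection is nested inside every CV training fold
(leakage-safe); a non-nested variant (select once on the full training
table) is available via `nested_selection=False`.

## Classifiers

- **RBF-SVM**: inner 5-fold grid over C ∈ {0.1, 1, 10} and
  gamma = scale × {0.5, 1, 2}, selected by CV AUC; decision-function scores.
- **GLM boosting**: hand-written componentwise gradient boosting with
  linear base learners on the binomial deviance, mstop = 100, step 0.1,
  internally standardised; |coefficient| doubles as feature importance.
- **Regularized random forest**: no penalised-admission forest exists in
  the installed stack, so it is approximated by a screening forest (100
  trees) admitting features with importance ≥ (1 − 0.8)·max, then a
  500-tree forest on the admitted set.
- **MLP** (hand-written in numpy, because the stated training recipe —
  per-class loss weights with plain SGD + momentum — is the contract):
  ReLU hidden layers from the dash string, 2-unit softmax, He init,
  batch 32, momentum 0.25, lr 10⁻³, no weight decay, class weight 1.467 on
  PCNSL terms, max 300 epochs with patience 30 on the member's held-out
  fold loss. Ten members (one per stratified fold, standardised by
  training-fold statistics) vote by majority; 5–5 ties resolve by mean
  PCNSL probability ≥ 0.5, and the continuous score for ROC analysis is
  the mean member probability (the voting paper-trail does not define one).
  The default sweep is 100-10, 500-100-10, 500-100-50-10 and
  500-250-100-50-20; deeper printed variants parse and run but are not in
  the default sweep.
- **Logistic baseline**: minimally ridge-stabilised (C = 10⁴) fit under the
  same CV protocol.

PCNSL is the positive class throughout (scores = P(PCNSL)).

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), verified against all-pairs
counting. Operating points maximise Youden's J = sensitivity +
specificity − 1 over midpoints of adjacent unique scores plus ±∞; J-ties
resolve toward higher specificity. CIs are 2000-resample stratified
percentile bootstraps (seeded); the reported interval is widened to contain
the point estimate if a percentile interval falls inside it. Stability is
RSD = 100·SD/mean over the repeated-CV AUC distribution, sample SD (fold
counts are small).

## Experiment sizes and runtime

The default experiment mirrors the study layout — 73/50 training, 18/12
internal, 28/14 external — on the combined CE+ADC channel (1872 features).
The repeated-CV scheme defaults to 2 repeats × 10 folds per grid model (the
full 10 × 10 = 100-run scheme is configurable and its split count is
verified by enumeration); this keeps the full default run at roughly 7
minutes on one CPU, a deliberate scaled-down operating point. Feature
extraction takes ≈ 0.2 s per 64³ channel.

## Known limitations

- Internal AUCs saturate at 1.0 on the default phantoms; discrimination
  difficulty can be tuned down via `heterogeneity_sd`/`adc_mean`, but the
  defaults prioritise robust recovery over a graded difficulty curve.
- The regularized-RF admission step is an approximation of guided
  regularised forests, not a reimplementation.
- The RSD of a model whose fold AUCs are all 1.0 is 0 by definition;
  stability comparisons are only informative away from the ceiling.
- Wavelet-band masks use lattice decimation, which can drop a one-voxel-
  thin structure entirely (handled by the zero-fill warning path).
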