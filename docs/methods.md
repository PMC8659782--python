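# Methods

This note documents the models and procedures implemented in `notoroot`, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Grading standard

Grades are assigned from single-root weight using the Wenshan *P.
notoginseng* standard (GB/T 19086-2008): grade I ≥ 25.0 g, II ≥ 17.0 g,
III ≥ 12.5 g, IV ≥ 8.5 g; lighter roots are below standard and raise an
error. Head count per 500 g also appears in the standard but is a property
of a lot, not of one image, so only weight drives synthetic labels. Because
the standard gives only floors, a requested grade's weight is drawn
uniformly between its floor and the next better grade's floor (grade I:
floor to 1.5× floor).

## Synthetic specimens

The generator emulates the four properties on which the commercial grades
visibly differ — projected size, outline irregularity, surface color, and
surface texture — not photorealism. A specimen is a superellipse (exponent
drawn from [2, 3]) modulated by a sinusoidal radial lobe term; lobe count
and relative amplitude increase from grade I (3–4 lobes, 6%) to grade IV
(6–9 lobes, 13%), mimicking the increasing shape irregularity of smaller
roots. Mean major-axis length decreases strictly I→IV (150, 122, 96, 74 px
on a 256 px canvas, SD 12 px — adjacent grades overlap, so silhouette size
alone does not grade perfectly). Surface color is a per-grade brownish base
(lighter for large roots) plus an oriented two-harmonic sinusoidal banding
whose amplitude and spatial frequency grow with grade number, plus iid
channel noise. The background is uniform light gray (level 230), bright
relative to any root surface, which keeps Otsu thresholding well posed (the
ground-truth mask and the pipeline's Otsu mask overlap with Jaccard > 0.99
on defaults).

What this does **not** establish: robustness to shadows, glare, soil
residue, camera noise, multi-root scenes, or the real covariance structure
of root appearance. Accuracies on synthetic data are upper bounds produced
by construction-separable classes, not estimates for field imagery.

Planted feature tables make each informative column a noisy linear encoding
of the class code (`X[:, j] = code·a_j + sd·ε`, loadings `a_j` ~ U[0.8,
1.2], default sd 0.5) and noise columns independent Gaussians. The encoding
is deliberately linear-in-code so that the noiseless table is exactly
recoverable by a linear fit, pinning down the ground truth that selection
algorithms are scored against. A latent-threshold construction (labels from
binned linear scores) would be more "ordinal" but makes exactness
unattainable and ground truth fuzzier.

## Preprocessing

Resize (bilinear) → Gaussian filter (5×5, σ = 0.3·((k−1)/2 − 1) + 0.8, the
common derived-σ rule) → ITU-R 601 luma grayscale → Otsu threshold
(smallest maximizer of between-class variance, ties broken downward) →
opening then closing with a square 5×5 element → hole filling → largest
connected component. The specimen side of the threshold is the side with
the smaller total intensity, which selects a dark root on a bright
background and is robust to polarity inversion. Degenerate inputs fail
loudly: constant images and empty foregrounds raise segmentation errors.

## Feature definitions worth flagging

* The color "variance" is the *square root* of the second central moment (a
  standard deviation) — implemented exactly as the grading model defines it,
  and named `var` in the canonical column list for consistency with the
  field's abbreviations (`Rvar`, `Svar`, …). Skewness is the signed real
  cube root of the third central moment; kurtosis the fourth root of the
  fourth central moment minus 3. H, S, V are rescaled to [0, 255] before
  moments so all 24 color features share one unit scale.
* Color and texture statistics are computed over the segmentation mask only;
  the uniform background would otherwise dominate every moment.
* GLCM quantization is uniform over [0, 255] (not per-image min–max) so
  texture features are comparable across images; accumulation is symmetric
  (each pair counted in both orders); features are averaged over the four
  directions at d = 2 with 64 levels. A windowed mode (mean of per-tile
  features over `window×window` tiles fully inside the mask) is available
  via `TextureConfig(window=...)` but is not the default: the global GLCM is
  deterministic, cheaper, and uses every masked pixel pair.
* GLCM correlation is the Haralick form with marginal means and standard
  deviations; for a single-level (zero-deviation) image it is defined as 1.
  Entropy uses log base 10, so a two-level equiprobable matrix has entropy
  log₁₀2 ≈ 0.30103.
* Elongation is normalized to longer/shorter min-rect side so it is ≥ 1 and
  orientation-invariant.

## RMSECV and the internal PLS

All three selection methods score a candidate subset by the 5-fold
cross-validated RMSE of a partial-least-squares regression predicting grade
codes 1–4 (grades are categorical everywhere else). The PLS is a univariate
SIMPLS on autoscaled features, written in-package because IRIV/VISSA
evaluate thousands of tiny fits per run and per-call overhead of a generic
implementation dominates the runtime; it is verified against an independent
PLS implementation in the tests. The component count (≤ 10) is chosen once
per selection run by CV on the full table and reused for all submodels —
nested per-submodel selection would multiply the cost by an order of
magnitude for no observed change in the selected sets.

## Selection algorithms

**IRIV.** Each round draws 500 random binary inclusion patterns (inclusion
probability 0.5), scores each submodel by RMSECV, and classifies every
variable by comparing the score distributions of submodels including vs
excluding it (Mann–Whitney, two-sided): significant decrease → strongly
informative; non-significant decrease → weakly informative; non-significant
increase → uninformative; significant increase → interfering. The latter
two classes are dropped and rounds repeat until only strong/weak variables
remain, then backward elimination removes variables while RMSECV does not
increase. "Does not increase" is judged with a 0.5% relative tolerance: at
n ≈ 200–400 a pure-noise column that is chance-correlated with the labels
lowers RMSECV by ~0.1–0.5%, inside CV sampling noise, and a strict
comparison would retain it.

**VISSA.** Per iteration, 500 weighted binary submodels are drawn (initial
inclusion weight 0.5 per variable), the best 5% by RMSECV are kept, and
each weight becomes that variable's frequency among the elite. Iteration
stops when all weights reach {0, 1} or when the elite RMSECV improves by
less than 2% — weight 1 is absorbing (a variable included in every
submodel can never leave), so once the informative variables have fixated
(within the first few iterations) further flat iterations only absorb noise
variables by random walk. Variables with final weight 1 are selected; a
table where nothing reaches weight 1 yields an empty selection with a
warning.

**SRA.** Classical stepwise regression on the coded labels: forward-add the
candidate with the smallest slope p-value if below 0.05, backward-remove
any included variable whose p-value exceeds 0.10, repeat to a fixed point.
Zero-variance columns and candidates that do not increase the design-matrix
rank are never entered, which makes exact duplicates safe.

On planted tables (5 informative + 35 noise, n = 200) IRIV recovers 5/5
informative with 0 noise across 10 seeds; VISSA 5/5 with ~1 noise on
average; false-positive control on pure-noise tables holds at ≤ 10% in
expectation (single null seeds can legitimately contain chance-predictive
columns, so the bound is a mean over seeds).

## Classifiers

Features are z-scored with training-set statistics before every model — RBF
kernels and gradient descent are scale-pathological on raw pixel/geometry
units. The SVM is a one-vs-one soft-margin RBF machine. The ELM uses random
Gaussian input weights, a sigmoid hidden layer (default 100 units), and
ridge-regularized (1e−6) least squares on one-hot targets. The BP network
is a single tanh hidden layer (default 20 units) trained by full-batch
gradient descent on softmax cross-entropy (rate 0.01, 1000 epochs), with a
divergence check. The stratified 7:3 split rounds per class and is seeded.

## Optimizers

GWO, real-coded GA (tournament size 2, arithmetic crossover 0.6, Gaussian
mutation 0.03 with SD 10% of range, elitism 1), and PSO (inertia 0.729,
c1 = c2 = 1.494, velocity clamp 20% of range) maximize 5-fold CV accuracy
over (c, g), defaulting to 100 iterations and population 20. Each
algorithm's default search box is its conventional range (GWO
[0.01, 100]²; GA c ≤ 100, g ≤ 1000 with lower bounds clamped to 0.01 since
the SVM needs strictly positive parameters; PSO c ∈ [0.1, 100], g ∈ [0.01,
1000]). Candidates are clipped to bounds, non-finite fitness discards the
candidate with a warning, and repeated (c, g) evaluations are cached at 6
significant digits. Best-so-far traces are monotone by construction.

## Pipeline and reproducibility

`run_pipeline` derives a sub-seed for every stochastic stage as
`crc32(f"{master}:{stage}") mod 2^31`, so adding a stage never perturbs the
randomness of earlier ones and a report is byte-identical across runs
(timings excluded). Selection and tuning operate on the training split only.
`compare_fusions` evaluates all requested feature subsets on one shared
split so accuracy differences are attributable to the feature groups.

## Problem sizes

Defaults were chosen so a full run is desk-scale: 256 px canvas, 100
specimens per grade (400 images) for the end-to-end runs, 500 submodels per
IRIV/VISSA round, and GWO at 20×100 with fitness caching. The acceptance
script completes in about a minute on one CPU; the test suite in about
three.

## Known limitations

* Synthetic accuracies (≈95–100%) reflect construction-separable classes;
  they qualitatively reproduce orderings (fused > shape-only, selection not
  worse than full features) but are not comparable to accuracies on real
  root imagery.
* The RMSECV-greedy selectors admit chance-correlated variables at small n;
  see the tolerance discussion above.
* The windowed GLCM mode averages only tiles fully inside the mask, so very
  thin structures may contribute no tiles.
* ELM and BP are reference implementations for model comparison, not
  speed-optimized.
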