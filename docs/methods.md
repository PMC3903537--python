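# Methods

This note records the models implemented in `atlasparc`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical conventions that a user extending or auditing the
package needs to know.

## Label-fusion model

### Multi-label STAPLE

Propagated segmentations d_1..d_J on the target grid are treated as raters
of a hidden true segmentation T over labels {0..L} (0 = background). Each
rater has a column-stochastic confusion matrix theta_j with
theta_j[s', s] = P(d_j(x) = s' | T(x) = s), assumed spatially constant and
voxel-wise independent. EM alternates

    E:  W_s(x) ∝ p_s(x) · prod_j theta_j[d_j(x), s]
    M:  theta_j[s', s] = sum_{x: d_j(x)=s'} W_s(x) / sum_x W_s(x)

with the E-step accumulated in log space (logsumexp normalisation) so long
products over many atlases cannot underflow. Initialisation: diagonal 0.95,
off-diagonal mass uniform. The stationary label prior p_s is, under the
default `empirical` policy, the mean vote fraction of each label over the
region of interest — the label frequency of the initial voting. We chose
vote fractions rather than the frequencies of the majority-vote *winners*
deliberately: a label that is frequently proposed but never wins an outright
majority (possible under systematic tie patterns) would otherwise receive
a near-zero prior and be unrecoverable by EM, which breaks exactly the
degenerate configurations (single rater, top-1 selection) where fusion
should reduce to a pass-through. The two definitions coincide in ordinary
multi-rater use. A `flat` (uniform) policy is available.

With the prior held fixed this is exact EM, so the observed-data
log-likelihood sum_x log sum_s p_s prod_j theta_j[d_j(x), s] is
non-decreasing; the per-iteration trace is stored on the result and
asserted in the tests. Convergence: max |delta theta| < 1e-4 or 30
iterations (both configurable). The fused label is the per-voxel argmax of
W; ties resolve to the smallest label id, and majority voting uses the same
rule.

### STEPS

STEPS adds two ingredients:

* **Spatially variant atlas selection.** Each resampled atlas image is
  scored against the target by the LNCC (below) with kernel SD sigma; at
  each voxel only the top-X ranked atlases enter the E-step product, and
  each atlas's M-step counts accumulate only over voxels where it was
  selected, so theta_j remains a performance estimate *where the atlas was
  used*. Rank ties resolve by atlas input order (stable sort), making the
  output deterministic and permutation-equivariant up to that documented
  rule.
* **Mean-field MRF prior.** The label prior at x becomes
  p_s · exp(−beta · sum_{y in N6(x)} (1 − W_s(y))) with W from the previous
  iteration, renormalised; out-of-grid and out-of-ROI neighbours count as
  background. beta = 0 disables the term; the default beta = 0.5 smooths
  isolated mislabels without visibly moving structure boundaries (the
  ablation test bounds the voxel difference at ≤ 5% on an easy cohort).
  With selection and MRF active the update is mean-field, so the
  likelihood-monotonicity guarantee applies to plain STAPLE only.

With X = J and beta = 0, STEPS reduces exactly to STAPLE (asserted at
~100% voxel agreement in the acceptance suite).

**Region of interest.** EM runs only where at least one atlas proposes a
nonzero label, dilated by 2 voxels (6-connected); outside, the fused label
is background and the posterior is a delta at background. This mirrors
brain-masked processing and bounds cost.

**Degenerate M-step columns.** If no posterior mass lands in a true-label
column (denominator < 1e-12), that column of theta_j keeps its previous
value instead of dividing by ~0.

## Similarity measures

* **LNCC**: per-voxel Pearson correlation from Gaussian-window local
  moments, LNCC = cov_sigma(T,M) / (std_sigma(T) · std_sigma(M)), with all
  local means/variances/covariances computed by Gaussian filtering with
  reflective boundary handling (avoids edge attenuation of the local
  statistics). Voxels where either local variance falls below
  1e-6 × that image's global variance — a scale-free guard — take the
  zero-variance convention value 0: locally flat patches carry no ranking
  information. The implementation is validated against a brute-force
  windowed weighted-correlation oracle to < 1e-6.
* **NMI** = (H(A)+H(B)) / H(A,B) from a joint histogram with 64 equal-width
  bins per image over each image's own range (invariant to separate
  monotone affine rescalings); constant images are rejected. Used as the
  symmetry score for mid-sagittal plane detection.
* **Dice** 2|A∩B|/(|A|+|B|); both-empty is defined as 1. Multi-label Dice
  matches ids exactly (never best-match); ids absent from both maps are
  excluded from the unweighted mean, ids present in only one score 0.

## Pipeline stages

* **Registration backends.** Registration proper is cited external
  machinery, so the package defines a backend contract —
  `register(moving, fixed, mask) -> Transform`, `invert`, `resample` with
  labels always nearest-neighbour — plus two built-ins that keep the rest
  of the pipeline hermetically testable: `identity`, and `translate`
  (exhaustive integer-voxel translation maximising NCC; FFT
  cross-correlation when unmasked, direct masked scan otherwise, default
  ±5 voxels). Production affine/B-spline tools plug in through the same
  contract.
* **Brain extraction.** Target→atlas affine registrations with the cost
  restricted to the atlas mask, transforms inverted, atlas masks propagated
  back, STAPLE-fused, and the consensus dilated by 4 voxels so later
  non-rigid steps can see the brain/CSF boundary. Dilation is iterated
  6-connected dilation in voxel units (the structuring element is a
  convention of this package; anisotropic spacing is not compensated).
* **Bias correction.** A homomorphic corrector: divide by
  exp(Gaussian-smoothed log intensity), smoothing within the mask by
  normalised convolution (default sigma 1.0 mm, chosen to sit above
  structure scale at rodent voxel sizes), then rescale to preserve the
  mask-mean intensity. It removes smooth multiplicative fields and is
  validated by planted-bias recovery (within-label CV reduced ≥ 25%);
  the config carries the reference N3 parameter set for users wiring an
  external N3 implementation instead.
* **Mid-sagittal plane.** The plane (offset along the left-right axis plus
  two tilt angles) maximising NMI between the image and its reflection:
  a coarse 1-voxel offset scan, then Nelder-Mead on (offset, a1, a2) with
  an explicit initial simplex (0.75 voxel / 1.5 degree steps — the default
  simplex would not explore zero-initialised angles). Validated to
  0.5 voxel / 1 degree on symmetric phantoms. If no candidate beats the
  grid mid-plane, that plane is returned with a warning.
* **Hemisphere splitting.** Structure id s becomes s (left) and s + 1000
  (right); plane-coincident voxels go left. Both choices are arbitrary and
  documented; splitting then merging (mod 1000) is the identity.

## Synthetic phantoms

The phantom module generates everything the pipeline consumes:

* **Geometry.** An ellipsoidal "brain" (semi-axes 0.40 × grid) tiled by
  nearest-seed (Voronoi) cells; seeds are drawn in the left half and
  mirrored (with 0.5-voxel jitter) so the phantom is near-bilaterally
  symmetric. This guarantees tiling, contiguity and an exact structure
  count. Default 48³ voxels at 0.1 mm and 4 structures per hemisphere — a
  small rodent-scale volume that keeps the full test suite fast while
  leaving thousands of voxels per structure.
* **Contrast.** Homologous structures share an intensity mean (means
  spread over 60–200 against background 15); a smooth multiplicative bias
  field exp(0.2 × smoothed noise) and additive Gaussian noise (SD 5)
  complete the MR-like appearance. Intensities are floored at 0.5, the
  magnitude-image positivity analogue, so log-domain processing is defined.
* **Cohorts.** Subjects are one base phantom under independent smooth
  random deformations (Gaussian-smoothed displacement fields, smoothness
  8 voxels, scaled to a stated per-component SD; folded draws are damped
  until the Jacobian stays positive). Labels and masks warp with
  nearest-neighbour so each subject's truth matches its image.
* **Raters.** Either iid confusion-matrix draws (the STAPLE generative
  model, used for parameter-recovery checks) or spatially correlated
  jitter via smooth deformations (the registration-error analogue).
* **Heterogeneous cohort.** The standard evaluation condition adds one
  subject corrupted by a strong localized deformation (magnitude 3 voxels
  inside a Gaussian window of roughly half the brain radius): wrong as an
  atlas in that region, detectably so from its image — the condition that
  separates locally ranked fusion from globally weighted fusion.
* **Planted effects.** One structure is grown/shrunk toward a requested
  volume ratio by distance-ordered morphology; growth annexes background
  voxels first and shrinkage peels to background, so other structures stay
  untouched (< 2%) and no spurious group effects are induced. The achieved
  ratio is recorded. Intensity images are left unchanged — the harness
  targets volumetry.

What the phantoms do **not** emulate: MR physics (no Rician noise model,
no partial-volume mixing, no susceptibility artefacts), realistic
neuroanatomy (no cortex/white-matter geometry, structures are convex-ish
Voronoi cells), and realistic registration error (built-in backends are
translation-only). Passing tests therefore demonstrate the correctness and
the relative behaviour of the fusion and statistics machinery under
controlled error models — not absolute accuracy on real mouse MRI, which
depends on the external registration quality and atlas databases.

## Evaluation and statistics

* **Averaging order.** "Mean Dice" is the mean over structures within a
  subject, then over subjects, weighting subjects equally (the alternative
  — pooling structures — overweights subjects with more structures
  present).
* **LOOCV.** Each subject in turn is the unlabelled target, the rest the
  atlas database; the left-out labels are used for scoring only (a
  leakage test asserts the fused output is invariant to them). The
  evaluation default disables brain extraction and bias correction: truth
  masks make extraction moot on phantoms and there is no bias worth
  correcting at fusion time; both stages remain available via the config.
* **Sweep.** Registrations/propagations are computed once per fold and
  reused across all grid cells; LNCC stacks are cached per sigma. The
  cached path is bit-identical to naive per-cell recomputation (asserted).
  Best-cell ties resolve to smallest X, then smallest sigma.
* **Method comparison.** The single-atlas score of a fold is the mean
  Dice over the individual propagated atlases. Per structure, two-tailed
  paired t-tests (paired by left-out subject — the only pairing the
  leave-one-out design supports) contrast STEPS with each baseline, with
  Benjamini–Hochberg correction at q = 0.05 across structures within each
  contrast. Structures with < 3 valid pairs or zero paired variance are
  flagged untestable and excluded from correction.
* **Group volumetry.** volume(s) = voxel count × voxel volume; TIV is the
  total nonzero-label volume, so structure volumes partition TIV when the
  labels tile the mask. The group test is Welch's unpaired two-tailed
  t-test by default: the compared cohorts are independent groups, so an
  unpaired test is the coherent choice even where a matched description
  appears; `paired=True` exists for genuinely matched designs. Volumes are
  compared raw or TIV-normalised; no log transform is applied by default.
  BH flags are validated against a brute-force sorted-threshold oracle.

## Numerical conventions and edge cases

* Voxel coordinates are 0-based index space; only volumetry and
  mm-specified kernels consult the spacing. Label maps are uint16 on disk.
* Grid compatibility: exact shape match, spacing equal within 1e-6
  relative.
* Priors are floored at 1e-8 before log; confusion entries at 1e-300
  inside logs.
* All phantom randomness descends from one seed via spawned
  `numpy.random.SeedSequence` streams: same seed, bit-identical cohorts,
  raters and results.
* Problem sizes in the test and acceptance suites (32³–64³ grids, 5–16
  subjects, 3–5 seeds per property) were chosen as the smallest cohorts at
  which the studied effects are comfortably above sampling noise.

## Known limitations

* Only affine (in fact translation) registration ships built-in; accuracy
  on real data is bounded by the external backend plugged in.
* The homomorphic bias corrector is intentionally simple; strong or
  high-frequency non-uniformity calls for a real N3-class method.
* Confusion matrices are spatially constant per atlas (standard STAPLE
  assumption); STEPS mitigates but does not remove this.
* Hard top-X selection is used (no soft rank weighting); the count X
  matters far more than the LNCC kernel width, consistent with the sweep
  results.
* `find_midsagittal` assumes near-bilateral symmetry and small tilts
  (coarse search covers ±quarter extent, ~±few degrees).
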