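# atlasparc

Fully automatic multi-atlas structural parcellation for small-animal brain
MRI, as a tested Python library and command-line tool.

Given an unlabelled 3D brain image and an atlas database — subjects with an
intensity image, expert structural labels, and a brain mask — the pipeline
produces a structural parcellation by **segmentation propagation and label
fusion**: brain extraction by mask propagation and consensus fusion,
intensity non-uniformity correction, per-atlas registration and
nearest-neighbour label propagation, STEPS label fusion, and optional
left/right hemisphere splitting about the automatically detected
mid-sagittal plane. On top of the pipeline sit leave-one-out parameter
optimisation and two-group volumetric statistics with FDR correction.

Everything is exercised hermetically on synthetic 3D phantoms with known
ground truth (the `phantom` module), so no external atlas data or
registration tools are required to build, test, or evaluate the package.

## The statistical core

**STAPLE** (simultaneous truth and performance level estimation) models each
propagated segmentation *d<sub>j</sub>* as a rater with an unknown confusion
matrix θ<sub>j</sub>, where θ<sub>j</sub>[s′, s] is the probability of
reporting label s′ where the hidden truth is s, and estimates truth and
performance jointly by EM:

- E-step: W<sub>s</sub>(x) ∝ p(s) · ∏<sub>j</sub> θ<sub>j</sub>[d<sub>j</sub>(x), s]
- M-step: θ<sub>j</sub>[s′, s] = Σ<sub>x: d<sub>j</sub>(x)=s′</sub> W<sub>s</sub>(x) / Σ<sub>x</sub> W<sub>s</sub>(x)

**STEPS** extends this with spatially variant atlas selection: at each voxel
only the top-X atlases ranked by the locally normalised cross-correlation
(LNCC) between the target and each resampled atlas image contribute, and the
label prior gains a mean-field Markov-random-field term over the
6-neighbourhood. Local ranking lets the fusion discard an atlas exactly
where its registration failed while still using it elsewhere — the failure
mode that global rater models cannot express.

The two STEPS parameters that matter are the LNCC Gaussian kernel SD σ
(voxels) and the top-X atlas count; `evalopt.default_sweep_grid()` spans
σ ∈ {1, 1.5, …, 6} × X ∈ {3, …, 9} (77 combinations) for leave-one-out
optimisation.

## Worked example

```python
import numpy as np
from atlasparc import (PhantomSpec, StepsParams, TranslationBackend,
                       PipelineConfig, make_cohort, multilabel_dice,
                       parcellate)

spec = PhantomSpec(shape=(32, 32, 32), n_structures_per_hemisphere=3, seed=11)
db = make_cohort(spec, n_subjects=5, deformation_sd=1.0, seed=21)

target, atlases = db.leave_out(0)          # subject 0 plays the unlabelled image
cfg = PipelineConfig(steps_params=StepsParams(sigma=2.0, top_x=2, beta=0.5),
                     brain_extraction=False, bias_correction=False)
res = parcellate(target.image, atlases, cfg, TranslationBackend(max_shift=3))

per_label, mean = multilabel_dice(res.labels, target.labels)
print(f"mean Dice vs truth: {mean:.3f}")
for lid, d in per_label.items():
    print(f"  structure {lid}: {d:.3f}")
```

Output:

```
mean Dice vs truth: 0.778
  structure 1: 0.786
  structure 2: 0.819
  structure 3: 0.610
  structure 4: 0.829
  structure 5: 0.867
  structure 6: 0.754
```

Each line is the Dice overlap (2|A∩B|/(|A|+|B|)) between the fused
segmentation and the left-out subject's own labels for one structure; the
mean is the unweighted average over structures. Fusing four imperfectly
aligned atlases (integer-translation registration against ~1-voxel smooth
deformations, so residual misalignment remains) recovers most structures
at Dice ≈ 0.75–0.87, well above the single propagated atlases on the same
fold.

The same flow from a shell:

```bash
atlasparc phantom --shape 32,32,32 --structures 3 --subjects 5 \
    --deformation-sd 1.0 --seed 21 --out atlas/
atlasparc parcellate --target atlas/s00_img.nii.gz --atlas-dir atlas/ \
    --backend translate --topx 2 --no-bias-correction --out parc/
atlasparc loocv --atlas-dir atlas/ --topx 2 --out loocv/
```

Other subcommands: `metrics`, `fuse`, `sweep`, `compare`, `groupstats`
(see `atlasparc --help`). Every run writes a `manifest.json` with the
resolved configuration and seed next to its outputs.

## Layout

- `atlasparc.phantom` — synthetic cohorts: brain-like multi-structure
  phantoms, smooth random deformations, confusion/jitter rater models,
  planted volume effects
- `atlasparc.imageio` — NIfTI-1 volumes and label maps, label tables, grid checks
- `atlasparc.metrics` — Dice, multi-label Dice, LNCC, NCC, NMI
- `atlasparc.fusion` — majority vote, multi-label STAPLE, STEPS
- `atlasparc.pipeline` — registration backend contract, brain extraction,
  bias correction, mid-sagittal plane, hemisphere splitting, `parcellate`
- `atlasparc.evalopt` — LOOCV, the (σ × X) sweep, method comparison
- `atlasparc.groupstats` — structure volumetry and two-group tests
- `atlasparc.cli` — the `atlasparc` command

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
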