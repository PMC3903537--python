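"""Synthetic brain-like phantoms for hermetic validation of the pipeline.

Real small-animal atlas databases are manually delineated MR volumes; none
are needed here. The generator emulates the features the parcellation
pipeline is sensitive to:

* a multi-structure "brain" — an ellipsoid tiled by nearest-seed (Voronoi)
  cells, with seeds mirrored about the mid-sagittal grid plane so the
  phantom is near-bilaterally symmetric and hemisphere splitting is
  meaningful;
* per-label MR-like contrast (homologous left/right structures share an
  intensity mean), a smooth multiplicative bias field, additive Gaussian
  noise;
* cohorts with per-subject morphological variation, produced by smooth
  random invertible deformations of one base phantom;
* simulated "propagated" segmentations with a known error structure —
  either voxel-wise confusion-matrix raters (the STAPLE generative model)
  or spatially correlated boundary jitter (the registration-failure
  analogue);
* two-group cohorts with a planted per-structure volume effect for the
  group-morphometry analysis.

All randomness descends from a single seed through spawned
``numpy.random.SeedSequence`` streams, so every artefact is bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, map_coordinates

from .imageio import (AtlasDatabase, AtlasPair, LabelEntry, LabelMap,
                      LabelTable, Volume)

__all__ = [
    "PhantomSpec",
    "RaterModel",
    "make_phantom",
    "make_cohort",
    "simulate_raters",
    "plant_group_effect",
]

log = logging.getLogger(__name__)

LEFT_RIGHT_AXIS = 0  # grid axis treated as left-right throughout


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of one synthetic brain.

    Defaults describe a small isotropic rodent-scale volume: 48^3 voxels at
    0.1 mm, 4 structures per hemisphere, moderate noise (SD 5 against tissue
    means of 60-200) and a 20% smooth multiplicative bias field.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    n_structures_per_hemisphere: int = 4
    noise_sd: float = 5.0
    bias_amplitude: float = 0.2
    bias_smoothness: float = 12.0
    #: SD (voxels) of the perturbation applied to mirrored seeds; breaks
    #: exact symmetry the way real anatomy does
    asymmetry_jitter: float = 0.5
    #: if True homologous structures share one id (L labels, hemisphere
    #: 'unassigned'); if False left/right get distinct ids (2L labels)
    bilateral_labels: bool = False
    background_mean: float = 15.0
    intensity_range: tuple[float, float] = (60.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError(f"grid shape must be 3D with all axes >= 16, got {self.shape}")
        if self.n_structures_per_hemisphere < 2:
            raise ValueError("need at least 2 structures per hemisphere")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias amplitude must be >= 0")


@dataclass(frozen=True)
class RaterModel:
    """Error model for simulated propagated segmentations.

    Exactly one of the two modes is active:

    * ``confusion`` — an (L+1, L+1) column-stochastic matrix over labels
      {0..L}; entry [s', s] is the probability the rater reports s' where
      the truth is s. Voxel errors are independent, the model STAPLE assumes.
    * ``jitter_sd`` > 0 — labels are resampled through a random smooth
      deformation of this SD (voxels), giving spatially correlated error.
    """

    confusion: np.ndarray | None = None
    jitter_sd: float = 0.0
    jitter_smoothness: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter magnitude must be >= 0")
        if self.confusion is not None:
            m = np.asarray(self.confusion, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError("confusion matrix must be square")
            if (m < -1e-12).any() or (m > 1 + 1e-12).any():
                raise ValueError("confusion entries must lie in [0, 1]")
            colsum = m.sum(axis=0)
            if not np.allclose(colsum, 1.0, atol=1e-9):
                raise ValueError("confusion matrix columns must sum to 1 within 1e-9")
            object.__setattr__(self, "confusion", m)


def diagonal_confusion(n_labels: int, diag: float) -> np.ndarray:
    """(L+1)x(L+1) matrix with given diagonal and uniform off-diagonal mass."""
    k = n_labels + 1
    off = (1.0 - diag) / (k - 1)
    m = np.full((k, k), off)
    np.fill_diagonal(m, diag)
    return m


# ---------------------------------------------------------------------------
# base phantom

def _brain_ellipsoid(shape: Sequence[int]) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.40 * np.asarray(shape)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _sample_seeds(rng: np.random.Generator, brain: np.ndarray, n: int,
                  spec: PhantomSpec) -> np.ndarray:
    """Seed points in the left half of the brain, mirrored (and jittered) right."""
    shape = brain.shape
    mid = (shape[LEFT_RIGHT_AXIS] - 1) / 2.0
    coords = np.argwhere(brain)
    left = coords[coords[:, LEFT_RIGHT_AXIS] < mid - 0.5]
    if len(left) < n:
        raise ValueError(
            f"{n} structures per hemisphere cannot tile {len(left)} left-hemisphere "
            f"voxels on a {tuple(shape)} grid")
    idx = rng.choice(len(left), size=n, replace=False)
    seeds_l = left[idx].astype(float)
    seeds_r = seeds_l.copy()
    seeds_r[:, LEFT_RIGHT_AXIS] = 2 * mid - seeds_r[:, LEFT_RIGHT_AXIS]
    if spec.asymmetry_jitter > 0:
        seeds_r = seeds_r + rng.normal(0, spec.asymmetry_jitter, seeds_r.shape)
    return np.vstack([seeds_l, seeds_r])


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap, LabelMap]:
    """Build one phantom: intensity volume, truth labels, brain mask.

    Labels 1..L tile the left hemisphere and L+1..2L the right (or 1..L both
    sides when ``bilateral_labels``); 0 is background.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_int, rng_bias, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4))

    brain = _brain_ellipsoid(spec.shape)
    n_h = spec.n_structures_per_hemisphere
    seeds = _sample_seeds(rng_geom, brain, n_h, spec)

    coords = np.argwhere(brain).astype(float)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # 0..2L-1, stable ties -> lowest seed index

    labels = np.zeros(spec.shape, dtype=np.int32)
    if spec.bilateral_labels:
        ids = (nearest % n_h) + 1
    else:
        ids = nearest + 1
    labels[tuple(np.argwhere(brain).T)] = ids

    table = LabelTable()
    if spec.bilateral_labels:
        for i in range(1, n_h + 1):
            table.add(i, LabelEntry(f"structure{i:02d}", "unassigned"))
    else:
        for i in range(1, n_h + 1):
            table.add(i, LabelEntry(f"structure{i:02d}_left", "left"))
            table.add(n_h + i, LabelEntry(f"structure{i:02d}_right", "right"))

    # homologous structures share an intensity mean, like real tissue contrast
    lo, hi = spec.intensity_range
    means_h = rng_int.permutation(np.linspace(lo, hi, n_h))
    mean_of = {0: spec.background_mean}
    for i in range(1, n_h + 1):
        mean_of[i] = float(means_h[i - 1])
        if not spec.bilateral_labels:
            mean_of[n_h + i] = float(means_h[i - 1])

    intensity = np.empty(spec.shape, dtype=np.float64)
    intensity[:] = spec.background_mean
    for lid, mu in mean_of.items():
        if lid:
            intensity[labels == lid] = mu

    if spec.bias_amplitude > 0:
        raw = gaussian_filter(rng_bias.standard_normal(spec.shape),
                              spec.bias_smoothness, mode="reflect")
        raw /= max(raw.std(), 1e-12)
        intensity = intensity * np.exp(spec.bias_amplitude * raw)
    if spec.noise_sd > 0:
        intensity = intensity + rng_noise.normal(0, spec.noise_sd, spec.shape)
        # magnitude images are non-negative (Rician noise floor); keep the
        # phantom strictly positive so log-domain processing is defined
        np.maximum(intensity, 0.5, out=intensity)

    vol = Volume(intensity.astype(np.float32), spec.spacing)
    lab = LabelMap(labels, table, spec.spacing)
    mask_table = LabelTable({1: LabelEntry("brain", "unassigned")})
    mask = LabelMap(brain.astype(np.int32), mask_table, spec.spacing)
    return vol, lab, mask


# ---------------------------------------------------------------------------
# smooth random deformations

def _random_displacement(rng: np.random.Generator, shape: Sequence[int],
                         sd: float, smoothness: float) -> np.ndarray:
    """(3, *shape) displacement field, Gaussian-smoothed, per-axis SD *sd*."""
    disp = np.empty((3,) + tuple(shape))
    for ax in range(3):
        f = gaussian_filter(rng.standard_normal(shape), smoothness, mode="reflect")
        f -= f.mean()
        f /= max(f.std(), 1e-12)
        disp[ax] = sd * f
    return disp


def _jacobian_ok(disp: np.ndarray, min_det: float = 0.05) -> bool:
    """Check the pull-back map x + d(x) does not fold (positive Jacobian)."""
    g = np.empty((3, 3) + disp.shape[1:])
    for i in range(3):
        for j in range(3):
            g[i, j] = np.gradient(disp[i], axis=j)
            if i == j:
                g[i, j] += 1.0
    det = (g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
           - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
           + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0]))
    return bool(det.min() > min_det)


def _warp(data: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    idx = np.indices(data.shape, dtype=np.float64)
    coords = idx + disp
    return map_coordinates(data, coords, order=order, mode="nearest")


def random_deformation(rng: np.random.Generator, shape: Sequence[int], sd: float,
                       smoothness: float = 8.0) -> np.ndarray:
    """Invertible smooth random displacement; folded draws are damped."""
    if sd == 0:
        return np.zeros((3,) + tuple(shape))
    disp = _random_displacement(rng, shape, sd, smoothness)
    attempts = 0
    while not _jacobian_ok(disp):
        attempts += 1
        disp *= 0.7
        warnings.warn(
            f"deformation field folded at SD {sd}; damped by 0.7 (attempt {attempts})")
        if attempts > 20:  # pragma: no cover - defensive
            raise RuntimeError("could not build an invertible deformation field")
    return disp


def make_cohort(spec: PhantomSpec, n_subjects: int, deformation_sd: float = 1.0,
                seed: int | None = None, deformation_smoothness: float = 8.0
                ) -> AtlasDatabase:
    """Cohort of subjects: one base phantom under independent smooth warps.

    Labels and masks are warped with nearest-neighbour interpolation so each
    subject's truth stays consistent with its intensity image. SD 0 returns
    identical copies of the base phantom.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if deformation_sd < 0:
        raise ValueError("deformation SD must be >= 0")
    base_img, base_lab, base_mask = make_phantom(spec)
    cohort_seed = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(cohort_seed).spawn(n_subjects)
    subjects = []
    for i, s in enumerate(streams):
        rng = np.random.default_rng(s)
        disp = random_deformation(rng, spec.shape, deformation_sd,
                                  deformation_smoothness)
        img = base_img.with_data(
            _warp(base_img.data.astype(np.float64), disp, order=1).astype(np.float32))
        lab = base_lab.with_data(_warp(base_lab.data, disp, order=0))
        msk = base_mask.with_data(_warp(base_mask.data, disp, order=0))
        subjects.append(AtlasPair(img, lab, msk, subject_id=f"s{i:02d}"))
    return AtlasDatabase(subjects, meta={"deformation_sd": deformation_sd,
                                         "seed": cohort_seed})


# ---------------------------------------------------------------------------
# simulated raters

def simulate_raters(truth: LabelMap, model: RaterModel, n_raters: int
                    ) -> list[LabelMap]:
    """Draw *n_raters* noisy segmentations of *truth* under the rater model."""
    if n_raters < 1:
        raise ValueError("need at least one rater")
    label_ids = [0] + truth.table.ids
    streams = np.random.SeedSequence(model.seed).spawn(n_raters)
    out: list[LabelMap] = []
    if model.confusion is not None:
        m = model.confusion
        if m.shape[0] != len(label_ids):
            raise ValueError(
                f"confusion matrix is {m.shape[0]}x{m.shape[0]} but the label "
                f"table implies {len(label_ids)} labels (incl. background)")
        code_of = {lid: c for c, lid in enumerate(label_ids)}
        truth_codes = np.zeros(truth.shape, dtype=np.int64)
        for lid, c in code_of.items():
            if lid:
                truth_codes[truth.data == lid] = c
        cum = np.cumsum(m, axis=0)
        ids_arr = np.asarray(label_ids)
        for s in streams:
            rng = np.random.default_rng(s)
            u = rng.random(truth.shape)
            obs = np.zeros(truth.shape, dtype=np.int64)
            for c in range(len(label_ids)):
                sel = truth_codes == c
                if sel.any():
                    obs_codes = np.searchsorted(cum[:, c], u[sel], side="right")
                    obs[sel] = ids_arr[np.clip(obs_codes, 0, len(label_ids) - 1)]
            out.append(truth.with_data(obs))
    else:
        for s in streams:
            rng = np.random.default_rng(s)
            disp = random_deformation(rng, truth.shape, model.jitter_sd,
                                      model.jitter_smoothness)
            out.append(truth.with_data(_warp(truth.data, disp, order=0)))
    return out


def make_heterogeneous_cohort(spec: PhantomSpec, n_subjects: int,
                              deformation_sd: float = 1.0, seed: int = 0,
                              corrupt_index: int = 0,
                              corruption_magnitude: float = 3.0) -> AtlasDatabase:
    """Deformed cohort with one locally corrupted subject.

    The standard evaluation cohort: inter-subject morphological variation
    plus a single atlas whose labels (and image) are badly wrong in one
    region — the condition under which locally ranked fusion (STEPS)
    separates from globally weighted fusion (STAPLE).
    """
    db = make_cohort(spec, n_subjects, deformation_sd, seed=seed)
    subjects = list(db.subjects)
    subjects[corrupt_index] = corrupt_subject(
        subjects[corrupt_index], magnitude=corruption_magnitude,
        seed=seed + 1)
    return db.replace(subjects, corrupt_index=corrupt_index)


def corrupt_subject(subject: AtlasPair, magnitude: float = 3.0,
                    radius_fraction: float = 0.45, smoothness: float = 4.0,
                    seed: int = 0) -> AtlasPair:
    """Apply a strong localized deformation to one subject — the
    registration-failure analogue.

    A smooth random displacement, windowed to a sphere (radius a fraction
    of the brain extent, centred off the brain centre), warps the image,
    labels and mask together, so the subject stays self-consistent but is
    locally wrong as an atlas; a locally ranked fusion can detect the
    mismatch from the image, a global one cannot.
    """
    rng = np.random.default_rng(seed)
    shape = subject.image.shape
    center = (np.asarray(shape) - 1) / 2.0
    offset = rng.normal(0, 0.15 * np.asarray(shape))
    c = center + offset
    radius = radius_fraction * 0.40 * min(shape)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    window = np.exp(-0.5 * r2 / radius**2)
    disp = _random_displacement(rng, shape, 1.0, smoothness)
    disp *= magnitude * window[None]
    img = subject.image.with_data(
        _warp(subject.image.data.astype(np.float64), disp, order=1).astype(np.float32))
    lab = subject.labels.with_data(_warp(subject.labels.data, disp, order=0))
    msk = subject.mask.with_data(_warp(subject.mask.data, disp, order=0))
    out = replace(subject, image=img, labels=lab, mask=msk)
    out.meta = dict(subject.meta, corrupted=True, corruption_magnitude=magnitude)
    return out


# ---------------------------------------------------------------------------
# planted group effects

def _resize_structure(labels: np.ndarray, sid: int, target_count: int,
                      brain: np.ndarray) -> np.ndarray:
    """Grow or shrink structure *sid* to ~target_count voxels.

    Growth annexes the nearest voxels of neighbouring structures (staying
    inside the brain); shrinkage peels the structure's own boundary and
    hands those voxels to the nearest other structure. Deterministic:
    distance ties break on flat voxel index.
    """
    out = labels.copy()
    m = out == sid
    current = int(m.sum())
    if target_count == current:
        return out
    if target_count > current:
        # annex background voxels first (no confound on other structures),
        # nearest-first; fall back to neighbouring structures if exhausted
        candidates = ~m
        d = distance_transform_edt(~m)
        cand_idx = np.flatnonzero(candidates.ravel())
        is_struct = (out.ravel()[cand_idx] > 0).astype(np.int8)
        order = np.lexsort((cand_idx, d.ravel()[cand_idx], is_struct))
        take = cand_idx[order[: target_count - current]]
        out.ravel()[take] = sid
    else:
        # peel the boundary inward; peeled voxels become background
        d_in = distance_transform_edt(m)
        m_idx = np.flatnonzero(m.ravel())
        order = np.lexsort((m_idx, d_in.ravel()[m_idx]))
        drop = m_idx[order[: current - target_count]]
        out.ravel()[drop] = 0
    return out


def plant_group_effect(db: AtlasDatabase, structure_id: int, scale: float,
                       group_labels: Sequence[str], treated_group: str,
                       seed: int = 0) -> AtlasDatabase:
    """Scale one structure's volume in the treated group of a cohort.

    Each treated subject's structure is morphologically grown (scale > 1) or
    shrunk (scale < 1) toward ``scale`` times its own volume; the mean
    achieved ratio is recorded in ``db.meta['achieved_ratio']``. Intensity
    images are left untouched — the harness targets volumetry, not fusion.
    """
    if scale <= 0:
        raise ValueError("volumetric scale factor must be > 0")
    if structure_id not in db.table:
        raise ValueError(f"structure id {structure_id} not in the label table")
    if len(group_labels) != len(db):
        raise ValueError("one group label per subject required")
    subjects = []
    ratios = []
    for subj, grp in zip(db, group_labels):
        lab = subj.labels
        mask = subj.mask
        if grp == treated_group and scale != 1.0:
            before = int((lab.data == structure_id).sum())
            if before == 0:
                raise ValueError(
                    f"structure {structure_id} empty in subject {subj.subject_id}")
            target = int(round(before * scale))
            brain = subj.mask.data > 0
            new = _resize_structure(np.asarray(lab.data), structure_id, target, brain)
            after = int((new == structure_id).sum())
            achieved = after / before
            ratios.append(achieved)
            if abs(achieved - scale) > 0.02 * scale:
                log.warning("subject %s: requested ratio %.3f, achieved %.3f",
                            subj.subject_id, scale, achieved)
            lab = lab.with_data(new)
            mask = mask.with_data(((mask.data > 0) | (new > 0)).astype(np.int32))
        subjects.append(replace(subj, labels=lab, mask=mask, group=grp))
    achieved_mean = float(np.mean(ratios)) if ratios else 1.0
    return db.replace(subjects, planted_structure=structure_id,
                      requested_ratio=scale, achieved_ratio=achieved_mean,
                      treated_group=treated_group)
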