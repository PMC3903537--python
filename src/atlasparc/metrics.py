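"""Overlap and similarity measures: Dice, LNCC, global NCC, NMI.

The locally normalised cross-correlation (LNCC) is the per-voxel Pearson
correlation of two images computed from Gaussian-window local moments:

    LNCC(x) = cov_sigma(T, M)(x) / (std_sigma(T)(x) * std_sigma(M)(x))

where every local mean/variance/covariance is a Gaussian filtering (SD
``sigma`` voxels, reflective boundaries) of the corresponding pointwise
product. Voxels where either local variance falls below a scale-free guard
epsilon = 1e-6 x global variance are assigned the zero-variance convention
value (0): a locally flat patch carries no ranking information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .imageio import LabelMap, Volume, require_same_grid

__all__ = ["LnccParams", "dice", "multilabel_dice", "lncc_map", "ncc", "nmi"]


@dataclass(frozen=True)
class LnccParams:
    """Gaussian kernel SD (voxels) and the value used at zero-variance voxels."""

    sigma: float = 2.0
    zero_variance_value: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"LNCC kernel sigma must be > 0, got {self.sigma}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Both masks empty is defined as perfect agreement (1.0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (sa + sb)


def multilabel_dice(a: LabelMap, b: LabelMap,
                    ids: list[int] | None = None) -> tuple[dict[int, float], float]:
    """Per-label Dice over nonzero ids plus the unweighted mean.

    Labels are matched id-wise. Ids absent from both maps score NaN and are
    excluded from the mean; ids present in only one map score 0.
    """
    require_same_grid(a, b)
    if ids is None:
        ids = sorted(set(a.present_ids()) | set(b.present_ids()))
    per_label: dict[int, float] = {}
    for lid in ids:
        ma = a.data == lid
        mb = b.data == lid
        if not ma.any() and not mb.any():
            per_label[lid] = float("nan")
        else:
            per_label[lid] = dice(ma, mb)
    vals = [v for v in per_label.values() if np.isfinite(v)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return per_label, mean


def _local_moments(t: np.ndarray, m: np.ndarray, sigma: float):
    f = lambda x: gaussian_filter(x, sigma, mode="reflect")
    mu_t, mu_m = f(t), f(m)
    var_t = f(t * t) - mu_t * mu_t
    var_m = f(m * m) - mu_m * mu_m
    cov = f(t * m) - mu_t * mu_m
    return var_t, var_m, cov


def lncc_map(target: Volume, moving: Volume,
             params: LnccParams | float = LnccParams()) -> Volume:
    """Per-voxel locally normalised cross-correlation in [-1, 1]."""
    if not isinstance(params, LnccParams):
        params = LnccParams(sigma=float(params))
    require_same_grid(target, moving)
    t = target.data.astype(np.float64)
    m = moving.data.astype(np.float64)
    var_t, var_m, cov = _local_moments(t, m, params.sigma)
    # scale-free zero-variance guard relative to each image's global variance
    eps_t = 1e-6 * max(float(t.var()), np.finfo(np.float64).tiny)
    eps_m = 1e-6 * max(float(m.var()), np.finfo(np.float64).tiny)
    bad = (var_t < eps_t) | (var_m < eps_m)
    denom = np.sqrt(np.clip(var_t, 0, None) * np.clip(var_m, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cov / denom
    out = np.clip(out, -1.0, 1.0)
    out[bad] = params.zero_variance_value
    return target.with_data(out)


def ncc(a: Volume | np.ndarray, b: Volume | np.ndarray,
        mask: np.ndarray | None = None) -> float:
    """Global (masked) normalised cross-correlation; 0 if either side is flat."""
    xa = a.data if isinstance(a, Volume) else np.asarray(a)
    xb = b.data if isinstance(b, Volume) else np.asarray(b)
    if xa.shape != xb.shape:
        raise ValueError(f"grid mismatch: {xa.shape} vs {xb.shape}")
    if mask is not None:
        xa, xb = xa[mask.astype(bool)], xb[mask.astype(bool)]
    xa = xa.astype(np.float64).ravel() - xa.mean()
    xb = xb.astype(np.float64).ravel() - xb.mean()
    denom = np.linalg.norm(xa) * np.linalg.norm(xb)
    if denom == 0:
        return 0.0
    return float(xa @ xb / denom)


def nmi(a: Volume, b: Volume, bins: int = 64) -> float:
    """Normalised mutual information (H(A)+H(B)) / H(A,B), >= 1.

    The joint histogram uses ``bins`` equal-width bins per image over each
    image's own range, so the measure is invariant to separate monotone
    affine rescalings of either image.
    """
    require_same_grid(a, b)
    xa = a.data.astype(np.float64).ravel()
    xb = b.data.astype(np.float64).ravel()
    if xa.min() == xa.max() or xb.min() == xb.max():
        raise ValueError("NMI undefined for a constant image")
    joint, _, _ = np.histogram2d(xa, xb, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    return (ent(pa) + ent(pb)) / ent(p.ravel())
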