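"""Label fusion: majority voting, multi-label STAPLE, and STEPS.

STAPLE (simultaneous truth and performance level estimation) treats each
propagated segmentation as a rater with an unknown confusion matrix
theta_j, where theta_j[s', s] is the probability rater j reports label s'
where the hidden truth is s, and estimates truth and performance jointly
by expectation-maximisation:

  E-step:  W_s(x)  proportional to  p_s(x) * prod_j theta_j[d_j(x), s]
  M-step:  theta_j[s', s] = sum_{x : d_j(x)=s'} W_s(x) / sum_x W_s(x)

computed in log space, initialised with diagonal-0.95 confusion matrices,
with the stationary label prior p_s taken either from the initial majority
vote's label frequencies ("empirical") or uniform ("flat"). Iteration
stops when max |delta theta| < tol or at the iteration cap. With the prior
held fixed this is exact EM, so the observed-data log-likelihood is
non-decreasing (tracked in the result).

STEPS extends STAPLE with spatially variant atlas selection and a Markov
random field prior. Atlases are ranked per voxel by the locally normalised
cross-correlation between the target image and each (resampled) atlas
image; only the top-X ranked atlases contribute to that voxel's E-step
product and to their own M-step counts. The label prior becomes the
mean-field MRF

  p_s(x)  proportional to  p_s * exp(-beta * sum_{y in N6(x)} (1 - W_s(y)))

over the 6-neighbourhood, with W from the previous iteration; beta = 0
recovers the spatially uniform prior.

EM runs only on a region of interest: voxels where at least one input
proposes a nonzero label, dilated by 2 voxels (6-connected); outside, the
fused label is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, generate_binary_structure
from scipy.special import logsumexp

from .imageio import LabelMap, Volume, require_same_grid
from .metrics import LnccParams, lncc_map

__all__ = [
    "StepsParams",
    "FusionResult",
    "RankMap",
    "majority_vote",
    "staple",
    "rank_atlases",
    "steps",
]

_PRIOR_FLOOR = 1e-8
_STRUCT6 = generate_binary_structure(3, 1)


@dataclass(frozen=True)
class StepsParams:
    """STEPS knobs: LNCC kernel sigma (voxels), top-X count, MRF beta, EM stop."""

    sigma: float = 2.0
    top_x: int = 5
    beta: float = 0.5
    max_iters: int = 30
    tol: float = 1e-4
    prior: str = "empirical"
    roi_dilation: int = 2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.top_x < 1:
            raise ValueError("top-X must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.prior not in ("empirical", "flat"):
            raise ValueError("prior policy must be 'empirical' or 'flat'")


@dataclass
class FusionResult:
    """Fused labels, per-voxel posterior, rater confusions and the EM trace."""

    labels: LabelMap
    posterior: np.ndarray          # (K, *shape), rows follow label_ids
    label_ids: list[int]           # code -> label id; label_ids[0] == 0
    confusion: np.ndarray | None   # (J, K, K) or None for majority vote
    iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)
    roi: np.ndarray | None = None


@dataclass
class RankMap:
    """Per-voxel atlas ranking by LNCC; ties resolved by atlas input order."""

    ranks: np.ndarray  # (J, *shape) int16; ranks[j, x] = position of atlas j (0 best)

    def selection(self, top_x: int) -> np.ndarray:
        """(J, *shape) bool indicator: atlas within the top-X at each voxel."""
        if not 1 <= top_x <= self.ranks.shape[0]:
            raise ValueError(f"top-X must be in [1, {self.ranks.shape[0]}]")
        return self.ranks < top_x


# ---------------------------------------------------------------------------
# shared plumbing

def _check_inputs(propagated: Sequence[LabelMap]) -> None:
    if len(propagated) == 0:
        raise ValueError("need at least one propagated label map")
    for lab in propagated[1:]:
        require_same_grid(propagated[0], lab)


def _label_universe(propagated: Sequence[LabelMap],
                    label_ids: Sequence[int] | None) -> list[int]:
    if label_ids is None:
        present: set[int] = set()
        for lab in propagated:
            present.update(lab.present_ids())
        return [0] + sorted(present)
    ids = sorted(set(int(i) for i in label_ids) - {0})
    return [0] + ids


def _encode(propagated: Sequence[LabelMap], ids: list[int]) -> np.ndarray:
    """Stack label maps as label codes 0..K-1; unknown ids raise."""
    lut = np.full(max(ids) + 1, -1, dtype=np.int32)
    for c, lid in enumerate(ids):
        lut[lid] = c
    stack = np.empty((len(propagated),) + propagated[0].shape, dtype=np.int32)
    for j, lab in enumerate(propagated):
        if lab.data.max() > max(ids) or np.any(lut[lab.data] < 0):
            extra = sorted(set(lab.present_ids()) - set(ids))
            raise ValueError(f"input {j} contains label ids {extra} outside the "
                             f"fusion label set {ids}")
        stack[j] = lut[lab.data]
    return stack


def _fusion_roi(stack: np.ndarray, dilation: int) -> np.ndarray:
    roi = (stack > 0).any(axis=0)
    if dilation > 0 and roi.any():
        roi = binary_dilation(roi, structure=_STRUCT6, iterations=dilation)
    return roi


def _vote_fractions(codes: np.ndarray, n_labels: int) -> np.ndarray:
    """(n_vox, K) fraction of raters voting each code; codes is (J, n_vox)."""
    j, n = codes.shape
    counts = np.zeros((n, n_labels), dtype=np.float64)
    for r in range(j):
        np.add.at(counts, (np.arange(n), codes[r]), 1.0)
    return counts / j


def _prior_vector(codes: np.ndarray, n_labels: int, policy: str) -> np.ndarray:
    if policy == "flat":
        p = np.full(n_labels, 1.0 / n_labels)
    else:
        # mean vote fraction per label: the label frequency of the initial
        # voting, robust to labels that never win a tie outright
        p = _vote_fractions(codes, n_labels).mean(axis=0)
    p = np.maximum(p, _PRIOR_FLOOR)
    return p / p.sum()


def _init_theta(n_raters: int, n_labels: int, diag: float = 0.95) -> np.ndarray:
    off = (1.0 - diag) / max(n_labels - 1, 1)
    th = np.full((n_raters, n_labels, n_labels), off)
    for j in range(n_raters):
        np.fill_diagonal(th[j], diag)
    return th


def _neighbour_sum(w_vol: np.ndarray) -> np.ndarray:
    """Sum of W over the 6-neighbourhood; out-of-grid neighbours count as
    background (W_bg = 1)."""
    k = w_vol.shape[0]
    pad = np.zeros((k,) + tuple(s + 2 for s in w_vol.shape[1:]))
    pad[0] = 1.0
    pad[:, 1:-1, 1:-1, 1:-1] = w_vol
    c = pad[:, 1:-1, 1:-1, 1:-1]
    out = np.zeros_like(c)
    out += pad[:, :-2, 1:-1, 1:-1] + pad[:, 2:, 1:-1, 1:-1]
    out += pad[:, 1:-1, :-2, 1:-1] + pad[:, 1:-1, 2:, 1:-1]
    out += pad[:, 1:-1, 1:-1, :-2] + pad[:, 1:-1, 1:-1, 2:]
    return out


def _em_fusion(codes: np.ndarray, n_labels: int, prior: np.ndarray,
               selection: np.ndarray | None, beta: float, shape: tuple,
               roi: np.ndarray, max_iters: int, tol: float
               ) -> tuple[np.ndarray, np.ndarray, int, bool, list[float]]:
    """Run the (selective, MRF-regularised) STAPLE EM on ROI voxels.

    codes: (J, n_roi) observed label codes; selection: (J, n_roi) bool or
    None (all selected). Returns (W, theta, iterations, converged, ll).
    """
    n_raters, n_vox = codes.shape
    theta = _init_theta(n_raters, n_labels)
    log_p = np.log(prior)
    ll_trace: list[float] = []
    converged = False
    iterations = 0
    w = None

    # previous-iteration posterior for the mean-field MRF prior
    if beta > 0:
        votes = _vote_fractions(codes, n_labels)
        w_prev = votes
    else:
        w_prev = None

    roi_idx = np.where(roi)

    for it in range(max_iters):
        iterations = it + 1
        # E-step (log space)
        if beta > 0:
            w_vol = np.zeros((n_labels,) + shape)
            w_vol[0] = 1.0
            w_vol[0][roi_idx] = w_prev[:, 0]
            for s in range(1, n_labels):
                w_vol[s][roi_idx] = w_prev[:, s]
            neigh = _neighbour_sum(w_vol)
            neigh_roi = np.stack([neigh[s][roi_idx] for s in range(n_labels)], axis=1)
            logw = log_p[None, :] - beta * (6.0 - neigh_roi)
        else:
            logw = np.broadcast_to(log_p, (n_vox, n_labels)).copy()
        log_theta = np.log(np.maximum(theta, 1e-300))
        for j in range(n_raters):
            contrib = log_theta[j][codes[j], :]
            if selection is None:
                logw += contrib
            else:
                sel = selection[j]
                logw[sel] += contrib[sel]
        lse = logsumexp(logw, axis=1)
        ll_trace.append(float(lse.sum()))
        w = np.exp(logw - lse[:, None])

        # M-step
        theta_new = np.empty_like(theta)
        for j in range(n_raters):
            wj = w if selection is None else w * selection[j][:, None]
            denom = wj.sum(axis=0)  # (K,)
            num = np.zeros((n_labels, n_labels))
            cj = codes[j]
            for sp in range(n_labels):
                sel_sp = cj == sp
                if sel_sp.any():
                    num[sp] = wj[sel_sp].sum(axis=0)
            col_ok = denom > 1e-12
            theta_new[j] = theta[j]
            theta_new[j][:, col_ok] = num[:, col_ok] / denom[col_ok]
        delta = float(np.abs(theta_new - theta).max())
        theta = theta_new
        if beta > 0:
            w_prev = w
        if delta < tol:
            converged = True
            break
    return w, theta, iterations, converged, ll_trace


def _assemble_result(propagated: Sequence[LabelMap], ids: list[int],
                     w: np.ndarray, theta: np.ndarray | None, roi: np.ndarray,
                     iterations: int, converged: bool,
                     ll: list[float]) -> FusionResult:
    shape = propagated[0].shape
    n_labels = len(ids)
    posterior = np.zeros((n_labels,) + shape, dtype=np.float32)
    posterior[0] = 1.0
    roi_idx = np.where(roi)
    for s in range(n_labels):
        posterior[s][roi_idx] = w[:, s]
    fused_codes = np.zeros(shape, dtype=np.int64)
    fused_codes[roi_idx] = np.argmax(w, axis=1)  # first max -> smallest label id
    ids_arr = np.asarray(ids)
    fused = ids_arr[fused_codes]
    labels = propagated[0].with_data(fused)
    return FusionResult(labels=labels, posterior=posterior, label_ids=list(ids),
                        confusion=theta, iterations=iterations,
                        converged=converged, log_likelihood=ll, roi=roi)


# ---------------------------------------------------------------------------
# public fusion operations

def majority_vote(propagated: Sequence[LabelMap],
                  label_ids: Sequence[int] | None = None,
                  roi_dilation: int = 2) -> FusionResult:
    """Per-voxel modal label; ties go to the smallest label id.

    The posterior records plain vote fractions.
    """
    _check_inputs(propagated)
    ids = _label_universe(propagated, label_ids)
    stack = _encode(propagated, ids)
    roi = _fusion_roi(stack, roi_dilation)
    codes = stack[:, roi]
    votes = _vote_fractions(codes, len(ids))
    return _assemble_result(propagated, ids, votes, None, roi, 0, True, [])


def staple(propagated: Sequence[LabelMap], prior: str = "empirical",
           max_iters: int = 30, tol: float = 1e-4,
           label_ids: Sequence[int] | None = None,
           roi_dilation: int = 2) -> FusionResult:
    """Multi-label STAPLE fusion by EM (see module docstring for the model)."""
    _check_inputs(propagated)
    ids = _label_universe(propagated, label_ids)
    stack = _encode(propagated, ids)
    roi = _fusion_roi(stack, roi_dilation)
    codes = stack[:, roi]
    p = _prior_vector(codes, len(ids), prior)
    w, theta, iters, conv, ll = _em_fusion(
        codes, len(ids), p, selection=None, beta=0.0,
        shape=propagated[0].shape, roi=roi, max_iters=max_iters, tol=tol)
    return _assemble_result(propagated, ids, w, theta, roi, iters, conv, ll)


def rank_atlases(target: Volume, atlas_images: Sequence[Volume],
                 sigma: float, lncc_stack: np.ndarray | None = None) -> RankMap:
    """Rank atlases per voxel by LNCC against the target (descending).

    Ties are broken by atlas input order (stable sort). A precomputed
    ``lncc_stack`` of shape (J, *grid) may be supplied to reuse kernels
    across parameter-sweep cells.
    """
    if len(atlas_images) == 0:
        raise ValueError("need at least one atlas image")
    if lncc_stack is None:
        lncc_stack = compute_lncc_stack(target, atlas_images, sigma)
    order = np.argsort(-lncc_stack, axis=0, kind="stable")
    ranks = np.empty_like(order, dtype=np.int16)
    np.put_along_axis(ranks, order, np.arange(len(atlas_images),
                      dtype=np.int16).reshape(-1, 1, 1, 1), axis=0)
    return RankMap(ranks=ranks)


def compute_lncc_stack(target: Volume, atlas_images: Sequence[Volume],
                       sigma: float) -> np.ndarray:
    """(J, *grid) LNCC maps of each atlas image against the target."""
    p = LnccParams(sigma=sigma)
    return np.stack([lncc_map(target, img, p).data for img in atlas_images])


def steps(target: Volume, atlas_images: Sequence[Volume],
          propagated: Sequence[LabelMap], params: StepsParams = StepsParams(),
          label_ids: Sequence[int] | None = None,
          lncc_stack: np.ndarray | None = None) -> FusionResult:
    """STEPS fusion: top-X LNCC-ranked atlas selection + MRF-regularised EM."""
    _check_inputs(propagated)
    if len(atlas_images) != len(propagated):
        raise ValueError("one atlas image per propagated label map required")
    for img in atlas_images:
        require_same_grid(target, img)
    require_same_grid(target, propagated[0])
    if params.top_x > len(atlas_images):
        raise ValueError(f"top-X ({params.top_x}) exceeds the number of atlases "
                         f"({len(atlas_images)})")
    ids = _label_universe(propagated, label_ids)
    stack = _encode(propagated, ids)
    roi = _fusion_roi(stack, params.roi_dilation)
    codes = stack[:, roi]
    rank = rank_atlases(target, atlas_images, params.sigma, lncc_stack)
    selection = rank.selection(params.top_x)[:, roi]
    p = _prior_vector(codes, len(ids), params.prior)
    w, theta, iters, conv, ll = _em_fusion(
        codes, len(ids), p, selection=selection, beta=params.beta,
        shape=target.shape, roi=roi, max_iters=params.max_iters, tol=params.tol)
    return _assemble_result(propagated, ids, w, theta, roi, iters, conv, ll)
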