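"""Leave-one-out evaluation, the (sigma x top-X) parameter sweep, and the
three-way method comparison with FDR-corrected significance.

Averaging order for "mean Dice": mean over structures within a subject,
then over subjects, so every subject carries equal weight. Paired tests
pair observations by left-out subject — the only pairing the leave-one-out
design supports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fusion import compute_lncc_stack, staple, steps
from .imageio import AtlasDatabase
from .metrics import multilabel_dice
from .pipeline import (PipelineConfig, RegistrationBackend,
                       TranslationBackend, propagate)

__all__ = [
    "SweepGrid",
    "SweepResult",
    "default_sweep_grid",
    "loocv",
    "sweep",
    "compare_methods",
    "ComparisonResult",
    "fdr_bh",
]

#: lean defaults for phantom-cohort evaluation: the phantoms carry no bias
#: field worth correcting at fusion time and the truth masks make brain
#: extraction moot, so both stages are off unless the caller re-enables them
EVAL_CONFIG = PipelineConfig(brain_extraction=False, bias_correction=False)


@dataclass(frozen=True)
class SweepGrid:
    """Sorted grids of LNCC kernel SDs (voxels) and top-X atlas counts."""

    sigmas: tuple[float, ...]
    top_x: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sigmas or not self.top_x:
            raise ValueError("sweep grid must be non-empty")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigma values must be > 0")
        if any(x < 1 for x in self.top_x):
            raise ValueError("top-X values must be >= 1")
        if list(self.sigmas) != sorted(self.sigmas) or \
           list(self.top_x) != sorted(self.top_x):
            raise ValueError("grid values must be sorted ascending")

    def __len__(self) -> int:
        return len(self.sigmas) * len(self.top_x)


def default_sweep_grid() -> SweepGrid:
    """The reference sweep: sigma 1..6 voxels in 0.5 steps, X from 3 to 9
    atlases — 11 x 7 = 77 combinations."""
    return SweepGrid(sigmas=tuple(np.arange(1.0, 6.0 + 1e-9, 0.5).round(1)),
                     top_x=tuple(range(3, 10)))


@dataclass
class SweepResult:
    """Mean-Dice matrix over the grid plus the full per-cell Dice records."""

    grid: SweepGrid
    mean_dice: pd.DataFrame     # index sigma, columns top_x
    records: pd.DataFrame       # sigma, top_x, subject, structure, dice
    best_sigma: float
    best_top_x: int

    @property
    def best_mean_dice(self) -> float:
        return float(self.mean_dice.loc[self.best_sigma, self.best_top_x])


def _loocv_propagations(db: AtlasDatabase, backend: RegistrationBackend):
    """Yield (index, target subject, resampled atlas images, propagated labels)."""
    for i in range(len(db)):
        left_out, rest = db.leave_out(i)
        images, labels = [], []
        for atlas in rest:
            img, lab = propagate(atlas, left_out.image, backend)
            images.append(img)
            labels.append(lab)
        yield i, left_out, images, labels


def _dice_rows(fused, truth, subject: str, **extra) -> list[dict]:
    per_label, _ = multilabel_dice(fused, truth)
    return [dict(subject=subject, structure=lid, dice=d, **extra)
            for lid, d in per_label.items() if np.isfinite(d)]


def loocv(db: AtlasDatabase, cfg: PipelineConfig = EVAL_CONFIG,
          backend: RegistrationBackend | None = None) -> pd.DataFrame:
    """Leave-one-out cross-validation of the STEPS pipeline.

    Each subject in turn is the unlabelled target and the others the atlas
    database; returns tidy per-(subject, structure) Dice records of the
    fused segmentation against the left-out subject's own labels. The
    left-out labels play no part in the fusion (evaluation only).
    """
    if len(db) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    if cfg.steps_params.top_x > len(db) - 1:
        raise ValueError(f"top-X ({cfg.steps_params.top_x}) exceeds the "
                         f"atlas count in each fold ({len(db) - 1})")
    backend = backend or TranslationBackend()
    rows: list[dict] = []
    for _, left_out, images, labels in _loocv_propagations(db, backend):
        fused = steps(left_out.image, images, labels, cfg.steps_params,
                      label_ids=db.table.ids)
        rows.extend(_dice_rows(fused.labels, left_out.labels,
                               left_out.subject_id))
    return pd.DataFrame(rows)


def sweep(db: AtlasDatabase, grid: SweepGrid,
          cfg: PipelineConfig = EVAL_CONFIG,
          backend: RegistrationBackend | None = None) -> SweepResult:
    """Leave-one-out Dice over every (sigma, top-X) grid cell.

    Registrations and propagations are computed once per left-out subject
    and reused across cells; LNCC stacks are cached per sigma. Ties for the
    best cell resolve to the smallest X, then the smallest sigma.
    """
    if max(grid.top_x) > len(db) - 1:
        raise ValueError(f"top-X up to {max(grid.top_x)} requires at least "
                         f"{max(grid.top_x) + 1} subjects, got {len(db)}")
    backend = backend or TranslationBackend()
    rows: list[dict] = []
    for _, left_out, images, labels in _loocv_propagations(db, backend):
        for sigma in grid.sigmas:
            stack = compute_lncc_stack(left_out.image, images, sigma)
            for x in grid.top_x:
                params = dc_replace(cfg.steps_params, sigma=sigma, top_x=x)
                fused = steps(left_out.image, images, labels, params,
                              label_ids=db.table.ids, lncc_stack=stack)
                rows.extend(_dice_rows(fused.labels, left_out.labels,
                                       left_out.subject_id,
                                       sigma=sigma, top_x=x))
    records = pd.DataFrame(rows)
    mean = (records.groupby(["sigma", "top_x", "subject"])["dice"].mean()
            .groupby(["sigma", "top_x"]).mean()
            .unstack("top_x"))
    mean = mean.reindex(index=list(grid.sigmas), columns=list(grid.top_x))
    best_val = mean.to_numpy().max()
    best_sigma, best_x = None, None
    for x in grid.top_x:            # smallest X first, then smallest sigma
        for sigma in grid.sigmas:
            if mean.loc[sigma, x] >= best_val - 1e-12:
                best_sigma, best_x = sigma, x
                break
        if best_sigma is not None:
            break
    return SweepResult(grid=grid, mean_dice=mean, records=records,
                       best_sigma=float(best_sigma), best_top_x=int(best_x))


# ---------------------------------------------------------------------------
# method comparison

def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection flags at level q (NaNs never rejected)."""
    p = np.asarray(pvalues, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


@dataclass
class ComparisonResult:
    """Per-structure Dice of the three methods plus paired-test tables."""

    scores: pd.DataFrame    # subject, structure, method, dice
    tests: pd.DataFrame     # structure, comparison, t, p, significant
    q: float

    def method_means(self) -> pd.Series:
        return (self.scores.groupby(["method", "subject"])["dice"].mean()
                .groupby("method").mean())


def compare_methods(db: AtlasDatabase, cfg: PipelineConfig = EVAL_CONFIG,
                    backend: RegistrationBackend | None = None,
                    q: float = 0.05) -> ComparisonResult:
    """Leave-one-out comparison of single-atlas, STAPLE and STEPS.

    The single-atlas score for a fold is the mean Dice over the individual
    propagated atlases. Per structure, two-tailed paired t-tests (paired by
    left-out subject) contrast STEPS with each baseline;
    Benjamini-Hochberg correction at level ``q`` runs across structures
    within each contrast. Structures with fewer than 3 valid pairs or zero
    paired variance are flagged untestable and excluded from correction.
    """
    if len(db) < 4:
        raise ValueError("method comparison needs at least 4 subjects")
    backend = backend or TranslationBackend()
    params = cfg.steps_params
    if params.top_x > len(db) - 1:
        params = dc_replace(params, top_x=len(db) - 1)
    rows: list[dict] = []
    for _, left_out, images, labels in _loocv_propagations(db, backend):
        sid = left_out.subject_id
        # single-atlas: average the per-atlas propagation Dice
        singles: dict[int, list[float]] = {}
        for lab in labels:
            for r in _dice_rows(lab, left_out.labels, sid):
                singles.setdefault(r["structure"], []).append(r["dice"])
        rows.extend(dict(subject=sid, structure=lid, method="single",
                         dice=float(np.mean(v))) for lid, v in singles.items())
        fused_staple = staple(labels, label_ids=db.table.ids)
        rows.extend(_dice_rows(fused_staple.labels, left_out.labels, sid,
                               method="staple"))
        fused_steps = steps(left_out.image, images, labels, params,
                            label_ids=db.table.ids)
        rows.extend(_dice_rows(fused_steps.labels, left_out.labels, sid,
                               method="steps"))
    scores = pd.DataFrame(rows)

    wide = scores.pivot_table(index=["structure", "subject"], columns="method",
                              values="dice")
    test_rows: list[dict] = []
    for contrast, baseline in (("steps_vs_single", "single"),
                               ("steps_vs_staple", "staple")):
        for lid, grp in wide.groupby(level="structure"):
            pair = grp[["steps", baseline]].dropna()
            if len(pair) < 3:
                test_rows.append(dict(structure=lid, comparison=contrast,
                                      t=np.nan, p=np.nan, n=len(pair),
                                      untestable=True))
                continue
            diff = pair["steps"] - pair[baseline]
            if np.allclose(diff.std(ddof=1), 0):
                t, p = np.nan, np.nan
            else:
                t, p = sps.ttest_rel(pair["steps"], pair[baseline])
            test_rows.append(dict(structure=lid, comparison=contrast,
                                  t=float(t) if np.isfinite(t) else np.nan,
                                  p=float(p) if np.isfinite(p) else np.nan,
                                  n=len(pair), untestable=False))
    tests = pd.DataFrame(test_rows)
    tests["significant"] = False
    for contrast in tests["comparison"].unique():
        sel = tests["comparison"] == contrast
        tests.loc[sel, "significant"] = fdr_bh(tests.loc[sel, "p"].to_numpy(), q)
    return ComparisonResult(scores=scores, tests=tests, q=q)
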