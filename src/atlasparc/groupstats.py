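"""Structure volumetry and two-group comparison, with and without total
intracranial volume (TIV) normalisation.

TIV is defined operationally as the total volume of all nonzero labels in
a subject's parcellation, so when the labels tile the brain mask the
per-structure volumes partition the TIV exactly.

The group test defaults to Welch's two-sample two-tailed t-test: the
compared cohorts (e.g. transchromosomic vs wild-type animals) are
independent groups, so an unpaired test is the statistically coherent
choice; ``paired=True`` is available for matched designs with equal group
sizes. Multiple comparisons across structures are corrected with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evalopt import fdr_bh
from .imageio import AtlasDatabase, LabelMap

__all__ = ["structure_volumes", "cohort_volume_table", "group_compare"]


def structure_volumes(labels: LabelMap, subject: str = "",
                      group: str | None = None) -> pd.DataFrame:
    """Tidy rows (subject, group, structure, volume_mm3, tiv_mm3).

    Every id in the label table gets a row; empty structures score 0.
    volume(s) = voxel count of s x voxel volume; TIV = nonzero voxel count
    x voxel volume.
    """
    vv = labels.voxel_volume_mm3
    counts = np.bincount(np.asarray(labels.data).ravel())
    tiv = float((counts[1:].sum() if len(counts) > 1 else 0) * vv)
    rows = []
    for lid in labels.table.ids:
        n = int(counts[lid]) if lid < len(counts) else 0
        rows.append(dict(subject=subject, group=group, structure=lid,
                         volume_mm3=n * vv, tiv_mm3=tiv))
    return pd.DataFrame(rows)


def cohort_volume_table(db: AtlasDatabase) -> pd.DataFrame:
    """Volume table for a whole cohort (uses each subject's truth labels)."""
    return pd.concat(
        [structure_volumes(s.labels, s.subject_id, s.group) for s in db],
        ignore_index=True)


def group_compare(table: pd.DataFrame, normalise: bool = False,
                  q: float = 0.05, paired: bool = False) -> pd.DataFrame:
    """Per-structure two-group volume comparison with BH correction.

    If ``normalise``, each volume is divided by its subject's TIV first.
    Structures with undefined tests (zero variance in both groups, or too
    few subjects) are flagged untestable and excluded from the correction.
    Group order (hence sign of the difference) follows sorted group names.
    """
    t = table.copy()
    groups = sorted(g for g in t["group"].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g1, g2 = groups
    value = "volume_mm3"
    if normalise:
        t["volume_norm"] = t["volume_mm3"] / t["tiv_mm3"]
        value = "volume_norm"
    rows = []
    for lid, grp in t.groupby("structure"):
        a = grp.loc[grp["group"] == g1].sort_values("subject")[value].to_numpy()
        b = grp.loc[grp["group"] == g2].sort_values("subject")[value].to_numpy()
        row = dict(structure=lid, group_a=g1, group_b=g2,
                   mean_a=float(np.mean(a)) if len(a) else np.nan,
                   mean_b=float(np.mean(b)) if len(b) else np.nan,
                   n_a=len(a), n_b=len(b))
        row["difference"] = row["mean_b"] - row["mean_a"]
        untestable = len(a) < 2 or len(b) < 2
        if not untestable and np.var(a) == 0 and np.var(b) == 0:
            untestable = True
        if paired and len(a) != len(b):
            raise ValueError("paired comparison requires equal group sizes")
        if untestable:
            row.update(t_stat=np.nan, p=np.nan, untestable=True)
        else:
            if paired:
                stat, p = sps.ttest_rel(b, a)
            else:
                stat, p = sps.ttest_ind(b, a, equal_var=False)
            row.update(t_stat=float(stat) if np.isfinite(stat) else np.nan,
                       p=float(p) if np.isfinite(p) else np.nan,
                       untestable=not np.isfinite(p))
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("structure").reset_index(drop=True)
    out["significant"] = fdr_bh(out["p"].to_numpy(), q)
    out["direction"] = np.sign(out["difference"]).astype(int)
    return out
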