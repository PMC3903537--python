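"""Volumes, label maps, label tables and NIfTI-1 round-tripping.

All per-voxel processing in this package happens in index (voxel) space;
the voxel spacing and the voxel-to-world affine ride along as metadata and
are only consulted where physical units matter (volumetry, smoothing
kernels specified in mm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelEntry",
    "LabelTable",
    "LabelMap",
    "AtlasPair",
    "AtlasDatabase",
    "GridCheck",
    "check_same_grid",
    "load_volume",
    "save_volume",
    "load_labels",
    "save_labels",
    "load_label_table",
    "save_label_table",
]

HEMISPHERES = ("left", "right", "unassigned")

#: on-disk dtype for label maps; structure counts stay far below 65535
LABEL_DTYPE = np.uint16


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar field with voxel spacing (mm) and voxel→world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.spacing, self.affine.copy())


@dataclass(frozen=True)
class LabelEntry:
    name: str
    hemisphere: str = "unassigned"

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )


class LabelTable:
    """Mapping of integer structure ids (> 0) to names and hemisphere tags."""

    def __init__(self, entries: Mapping[int, LabelEntry] | None = None):
        self._entries: dict[int, LabelEntry] = {}
        for lid, entry in (entries or {}).items():
            self.add(lid, entry)

    def add(self, lid: int, entry: LabelEntry) -> None:
        lid = int(lid)
        if lid <= 0:
            raise ValueError("label id 0 is reserved for background; ids must be > 0")
        self._entries[lid] = entry

    def __contains__(self, lid: int) -> bool:
        return int(lid) in self._entries

    def __getitem__(self, lid: int) -> LabelEntry:
        return self._entries[int(lid)]

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self._entries))

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelTable) and self._entries == other._entries

    @property
    def ids(self) -> list[int]:
        return sorted(self._entries)

    def copy(self) -> "LabelTable":
        return LabelTable(dict(self._entries))

    def validate_array(self, data: np.ndarray) -> None:
        """Raise if *data* contains a nonzero id missing from the table."""
        present = np.unique(data)
        missing = [int(v) for v in present if v != 0 and int(v) not in self._entries]
        if missing:
            raise ValueError(
                f"label map contains ids {missing} absent from the label table"
            )


@dataclass
class LabelMap:
    """A 3D integer label field; 0 is background, every other id is tabled."""

    data: np.ndarray
    table: LabelTable
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int64)
        if self.data.min() < 0:
            raise ValueError("label ids must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        self.table.validate_array(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def present_ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.data) if v != 0]

    def with_data(self, data: np.ndarray, table: LabelTable | None = None) -> "LabelMap":
        return LabelMap(np.asarray(data), table or self.table, self.spacing, self.affine.copy())

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.float64), self.spacing, self.affine.copy())


@dataclass
class AtlasPair:
    """One atlas subject: intensity image, structural labels, brain mask."""

    image: Volume
    labels: LabelMap
    mask: LabelMap
    subject_id: str = ""
    group: str | None = None
    meta: dict = field(default_factory=dict)


class AtlasDatabase:
    """Ordered collection of atlas subjects sharing one label table."""

    def __init__(self, subjects: Sequence[AtlasPair], meta: dict | None = None):
        subjects = list(subjects)
        if not subjects:
            raise ValueError("atlas database cannot be empty")
        table = subjects[0].labels.table
        for s in subjects[1:]:
            if s.labels.table != table:
                raise ValueError("all atlas subjects must share one label table")
        self.subjects = subjects
        self.meta = dict(meta or {})

    @property
    def table(self) -> LabelTable:
        return self.subjects[0].labels.table

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[AtlasPair]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> AtlasPair:
        return self.subjects[i]

    def leave_out(self, i: int) -> tuple[AtlasPair, "AtlasDatabase"]:
        rest = [s for j, s in enumerate(self.subjects) if j != i]
        return self.subjects[i], AtlasDatabase(rest, dict(self.meta))

    def replace(self, subjects: Sequence[AtlasPair], **meta) -> "AtlasDatabase":
        m = dict(self.meta)
        m.update(meta)
        return AtlasDatabase(list(subjects), m)


# ---------------------------------------------------------------------------
# grid compatibility

@dataclass(frozen=True)
class GridCheck:
    ok: bool
    message: str

    def __bool__(self) -> bool:
        return self.ok


def check_same_grid(a: Volume | LabelMap, b: Volume | LabelMap,
                    rtol: float = 1e-6) -> GridCheck:
    """Shapes must match exactly; spacings within relative tolerance."""
    if a.shape != b.shape:
        bad = [ax for ax in range(3) if a.shape[ax] != b.shape[ax]]
        return GridCheck(False, f"shape mismatch {a.shape} vs {b.shape} on axis "
                                f"{', '.join(map(str, bad))}")
    sa, sb = np.asarray(a.spacing), np.asarray(b.spacing)
    if not np.allclose(sa, sb, rtol=rtol, atol=0):
        return GridCheck(False, f"spacing mismatch {a.spacing} vs {b.spacing}")
    return GridCheck(True, "grids match")


def require_same_grid(a: Volume | LabelMap, b: Volume | LabelMap) -> None:
    chk = check_same_grid(a, b)
    if not chk:
        raise ValueError(chk.message)


# ---------------------------------------------------------------------------
# NIfTI-1 and label-table IO

def load_volume(path: str | Path) -> Volume:
    """Load an intensity volume from a NIfTI-1 file.

    Non-finite voxels are rejected: downstream local statistics and EM
    weights silently propagate NaN, so the failure surfaces here instead.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite values")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, np.asarray(img.affine))


def save_volume(vol: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_labels(path: str | Path, table: LabelTable | str | Path) -> LabelMap:
    """Load a label map; *table* may be a LabelTable or a TSV path."""
    if not isinstance(table, LabelTable):
        table = load_label_table(table)
    img = nib.load(str(path))
    raw = np.asarray(img.dataobj)
    if raw.ndim == 4 and raw.shape[3] == 1:
        raw = raw[..., 0]
    if not np.issubdtype(raw.dtype, np.integer):
        if not np.all(raw == np.round(raw)):
            raise ValueError(f"{path}: label file contains non-integer data")
        raw = raw.astype(np.int64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(raw, table, spacing, np.asarray(img.affine))


def save_labels(lab: LabelMap, path: str | Path,
                table_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(lab.data.astype(LABEL_DTYPE), lab.affine)
    img.header.set_zooms(lab.spacing)
    nib.save(img, str(path))
    if table_path is not None:
        save_label_table(lab.table, table_path)


def load_label_table(path: str | Path) -> LabelTable:
    table = LabelTable()
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty label table")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:3]] != ["id", "name", "hemisphere"]:
        raise ValueError(f"{path}: expected header 'id\\tname\\themisphere'")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        lid, name, hemi = ln.rstrip("\n").split("\t")[:3]
        table.add(int(lid), LabelEntry(name, hemi.strip()))
    return table


def save_label_table(table: LabelTable, path: str | Path) -> None:
    rows = ["id\tname\themisphere"]
    for lid in table:
        e = table[lid]
        rows.append(f"{lid}\t{e.name}\t{e.hemisphere}")
    Path(path).write_text("\n".join(rows) + "\n")
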