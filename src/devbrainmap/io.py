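"""Containers and file formats for the mapping pipeline.

Conventions (enforced by tests):

* Arrays are rank-3 in ``(x, y, z)`` order; ``z`` is the sectioning axis.
* Coordinates are physical micrometres with the origin at the corner of
  voxel ``(0, 0, 0)``.  A point at coordinate ``c`` along an axis with
  spacing ``s`` lies in voxel ``floor(c / s)``; voxel intervals are
  half-open, so a point exactly on a boundary plane belongs to the
  higher-index voxel.
* Left-right mirroring is always about the mid-``x`` plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume",
    "LabelVolume",
    "Ontology",
    "OntologyNode",
    "CELL_COLUMNS",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_ontology",
    "write_ontology",
    "read_cells",
    "write_cells",
    "make_cell_table",
]

#: Required columns of a cell table, in canonical order.
CELL_COLUMNS = ("x_um", "y_um", "z_um", "section_index", "channel")


class FormatError(ValueError):
    """Raised when a file violates a format contract (e.g. missing spacing)."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image on an anisotropic voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in ``(x, y, z)`` axis order.
    spacing : tuple of float
        Voxel size in micrometres per axis; strictly positive.
    origin : tuple of float
        Physical position (um) of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume array must be rank 3, got rank {data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in cubic micrometres."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid, new voxel values."""
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def mirrored(self) -> "Volume":
        """Left-right mirror about the mid-x plane (axis 0 flipped)."""
        return self.with_data(self.data[::-1, :, :].copy())

    def point_to_voxel(self, points_um: np.ndarray) -> np.ndarray:
        """Map physical points (n, 3) to integer voxel indices (floor rule)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        rel = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        return np.floor(rel).astype(np.int64)


@dataclass(frozen=True)
class OntologyNode:
    id: int
    acronym: str
    name: str
    parent_id: int | None


class Ontology:
    """A rooted region hierarchy (single root, unique ids, acyclic).

    Nodes mirror the Allen-style ontology records: ``{id, acronym, name,
    parent_id}`` with ``parent_id`` null at the root.
    """

    def __init__(self, nodes: Iterable[OntologyNode]):
        nodes = list(nodes)
        ids = [n.id for n in nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ontology ids: {dupes}")
        if any(n.id == 0 for n in nodes):
            raise ValueError("id 0 is reserved for background and cannot be an ontology node")
        self._nodes: dict[int, OntologyNode] = {n.id: n for n in nodes}
        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is None:
                continue
            if n.parent_id not in self._nodes:
                raise ValueError(f"node {n.id} cites unknown parent {n.parent_id}")
            self._children[n.parent_id].append(n.id)
        # acyclicity + connectivity: every node must reach the root
        for n in nodes:
            seen = set()
            cur = n
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValueError(f"cycle in ontology involving node {cur.id}")
                seen.add(cur.id)
                cur = self._nodes[cur.parent_id]

    def __contains__(self, region_id: int) -> bool:
        return int(region_id) in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __getitem__(self, region_id: int) -> OntologyNode:
        return self._nodes[int(region_id)]

    @property
    def ids(self) -> list[int]:
        return sorted(self._nodes)

    def children(self, region_id: int) -> list[int]:
        return list(self._children[int(region_id)])

    def depth(self, region_id: int) -> int:
        d = 0
        cur = self._nodes[int(region_id)]
        while cur.parent_id is not None:
            cur = self._nodes[cur.parent_id]
            d += 1
        return d

    def descendants(self, region_id: int) -> list[int]:
        """All strict descendants of ``region_id`` (preorder)."""
        out: list[int] = []
        stack = list(self._children[int(region_id)])
        while stack:
            rid = stack.pop()
            out.append(rid)
            stack.extend(self._children[rid])
        return out

    def is_leaf(self, region_id: int) -> bool:
        return not self._children[int(region_id)]

    def to_records(self) -> list[dict]:
        return [
            {"id": n.id, "acronym": n.acronym, "name": n.name, "parent_id": n.parent_id}
            for n in self._nodes.values()
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "Ontology":
        nodes = []
        for r in records:
            pid = r.get("parent_id")
            nodes.append(
                OntologyNode(
                    id=int(r["id"]),
                    acronym=str(r["acronym"]),
                    name=str(r["name"]),
                    parent_id=None if pid is None else int(pid),
                )
            )
        return cls(nodes)


@dataclass(frozen=True)
class LabelVolume:
    """Integer region-id image aligned to a Volume grid; 0 is background."""

    volume: Volume
    ontology: Ontology | None = None

    def __post_init__(self):
        if not np.issubdtype(self.volume.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if self.ontology is not None:
            present = set(np.unique(self.volume.data).tolist()) - {0}
            missing = sorted(r for r in present if r not in self.ontology)
            if missing:
                raise ValueError(f"labels not present in ontology: {missing}")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volume.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape

    def label_set(self) -> set[int]:
        """Nonzero labels present in the image."""
        return set(np.unique(self.data).tolist()) - {0}

    def voxel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.data, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}


# ---------------------------------------------------------------------------
# Volumes: NIfTI-1 and multi-page TIFF (+ JSON sidecar)

_MICRON_CODE = "micron"


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or TIFF stack (.tif/.tiff).

    NIfTI stores spacing in the header zooms with micron units; TIFF gets a
    JSON sidecar ``<stem>.json`` carrying spacing and origin.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(np.asanyarray(volume.data), affine)
        img.header.set_zooms(volume.spacing)
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        # pages are z-sections; each page is (y, x)
        tifffile.imwrite(str(path), np.transpose(volume.data, (2, 1, 0)),
                         photometric="minisblack")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "spacing_um": list(volume.spacing),
                    "origin_um": list(volume.origin),
                    "axis_order": "xyz",
                }
            )
        )
    else:
        raise FormatError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI or TIFF-stack volume; spacing metadata is mandatory."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        xyz_unit, _ = img.header.get_xyzt_units()
        zooms = img.header.get_zooms()[:3]
        if xyz_unit == "micron":
            spacing = tuple(float(z) for z in zooms)
        elif xyz_unit == "mm":
            spacing = tuple(float(z) * 1000.0 for z in zooms)
        else:
            raise FormatError(
                f"{path.name}: NIfTI spatial units are '{xyz_unit}'; spacing would be "
                "ambiguous — set xyzt units to micron or mm"
            )
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume(np.asanyarray(img.dataobj), spacing, origin)
    if suffixes.endswith((".tif", ".tiff")):
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(
                f"{path.name}: no spacing sidecar {sidecar.name}; refusing to guess voxel size"
            )
        meta = json.loads(sidecar.read_text())
        if "spacing_um" not in meta:
            raise FormatError(f"{sidecar.name}: missing 'spacing_um'")
        data = np.transpose(tifffile.imread(str(path)), (2, 1, 0))
        return Volume(data, tuple(meta["spacing_um"]), tuple(meta.get("origin_um", (0, 0, 0))))
    raise FormatError(f"unsupported volume format: {path.name}")


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    return write_volume(labels.volume, path)


def read_labels(path: str | Path, ontology: Ontology | None = None) -> LabelVolume:
    vol = read_volume(path)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{Path(path).name}: label image has non-integer values")
        vol = vol.with_data(np.round(data).astype(np.int32))
    return LabelVolume(vol, ontology)


# ---------------------------------------------------------------------------
# Ontology: JSON node list

def write_ontology(ontology: Ontology, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ontology.to_records(), indent=1))
    return path


def read_ontology(path: str | Path) -> Ontology:
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise FormatError("ontology JSON must be a list of node objects")
    return Ontology.from_records(records)


# ---------------------------------------------------------------------------
# Cell tables: TSV with physical coordinates

def make_cell_table(
    x_um: np.ndarray,
    y_um: np.ndarray,
    z_um: np.ndarray,
    section_index: np.ndarray,
    channel: np.ndarray | int = 0,
) -> pd.DataFrame:
    """Assemble a validated cell table from coordinate arrays."""
    n = len(np.atleast_1d(x_um))
    df = pd.DataFrame(
        {
            "x_um": np.asarray(x_um, dtype=float),
            "y_um": np.asarray(y_um, dtype=float),
            "z_um": np.asarray(z_um, dtype=float),
            "section_index": np.asarray(section_index, dtype=np.int64),
            "channel": np.broadcast_to(np.asarray(channel), (n,)).astype(np.int64),
        }
    )
    validate_cells(df)
    return df


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    coords = cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("cell coordinates must be finite")
    if (cells["section_index"] < 0).any():
        raise ValueError("section_index must be >= 0")
    return cells


def write_cells(cells: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_cells(cells)
    cells.to_csv(path, sep="\t", index=False)
    return path


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty and list(df.columns) == []:
        df = pd.DataFrame(columns=list(CELL_COLUMNS))
    return validate_cells(df)
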