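"""Per-region counts, volumes, and densities from cell tables.

The arithmetic chain is the standard serial-section bookkeeping: cells are
detected on 2D sections (``n2d``), scaled to a 3D estimate with a
multiplicative conversion factor (``n3d = 1.4 × n2d`` by default), regional
volume comes from label voxel counts times the anatomical voxel volume
(20 × 20 × 50 μm³ = 20 000 μm³ at the working resolution), and density is
``n3d / volume`` in cells per mm³.  Parent regions in the ontology
aggregate summed counts and summed volumes of their descendants — never
averaged child densities — so that ``density × volume == n3d`` holds at
every node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabelVolume, Ontology, validate_cells

__all__ = ["QuantConfig", "assign_cells", "region_stats", "aggregate", "conservation_report"]

#: Column order of the per-region stats table.
STATS_COLUMNS = (
    "region_id", "acronym", "name", "n2d", "n3d",
    "voxel_count", "volume_mm3", "density_mm3",
)


@dataclass(frozen=True)
class QuantConfig:
    """Quantification constants.

    ``k3d``: dimensionless 2D→3D count conversion factor (default 1.4).
    ``voxel_volume_um3``: physical volume of one anatomical voxel (default
    20 × 20 × 50 = 20 000 μm³).  ``background_label`` is excluded from
    regional statistics.
    """

    k3d: float = 1.4
    voxel_volume_um3: float = 20.0 * 20.0 * 50.0
    background_label: int = 0

    def __post_init__(self):
        if self.k3d <= 0:
            raise ValueError("k3d must be > 0")
        if self.voxel_volume_um3 <= 0:
            raise ValueError("voxel_volume_um3 must be > 0")


def assign_cells(cells: pd.DataFrame, labels: LabelVolume) -> pd.DataFrame:
    """Assign each cell the region id of its containing voxel.

    Uses the half-open floor convention: a coordinate exactly on a voxel
    boundary plane belongs to the higher-index voxel.  Returns a copy of
    the table with ``region_id`` (−1 for out-of-grid cells), ``background``
    and ``out_of_domain`` flag columns; flagged cells are retained here and
    excluded from regional counts downstream.
    """
    validate_cells(cells)
    out = cells.copy()
    if len(out) == 0:
        out["region_id"] = pd.Series(dtype=np.int64)
        out["background"] = pd.Series(dtype=bool)
        out["out_of_domain"] = pd.Series(dtype=bool)
        return out
    idx = labels.volume.point_to_voxel(out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
    shape = np.asarray(labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    region = np.full(len(out), -1, dtype=np.int64)
    ii = idx[inside]
    region[inside] = labels.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    if "out_of_domain" in cells.columns:
        # cells already flagged by a point transform stay out of domain
        inside &= ~cells["out_of_domain"].to_numpy(dtype=bool)
        region[~inside] = -1
    out["region_id"] = region
    out["background"] = inside & (region == 0)
    out["out_of_domain"] = ~inside
    return out


def conservation_report(assigned: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping of where every cell went (regional/background/outside)."""
    n_out = int(assigned["out_of_domain"].sum())
    n_bg = int(assigned["background"].sum())
    return {
        "total": len(assigned),
        "regional": len(assigned) - n_out - n_bg,
        "background": n_bg,
        "out_of_domain": n_out,
    }


def region_stats(
    assigned: pd.DataFrame,
    labels: LabelVolume,
    config: QuantConfig | None = None,
    **metadata,
) -> pd.DataFrame:
    """Per-region 2D/3D counts, volume, and density.

    One row per region present in the label volume; zero-count regions are
    included with density 0 (group statistics need them).  The conversion
    factor is applied to the per-region summed 2D count.  Extra keyword
    arguments (age, sex, ...) are attached as constant metadata columns.
    """
    config = config or QuantConfig()
    voxel_counts = labels.voxel_counts()
    counted = assigned.loc[~assigned["out_of_domain"] & ~assigned["background"]]
    cell_counts = counted.groupby("region_id").size().to_dict()
    stray = sorted(set(cell_counts) - set(voxel_counts))
    if stray:
        raise ValueError(
            f"cells assigned to regions with zero voxels in the label volume: {stray}"
        )
    ontology = labels.ontology
    rows = []
    for region_id in sorted(voxel_counts):
        n2d = int(cell_counts.get(region_id, 0))
        n3d = config.k3d * n2d
        vox = voxel_counts[region_id]
        volume_mm3 = vox * config.voxel_volume_um3 * 1e-9
        node = ontology[region_id] if ontology is not None and region_id in ontology else None
        rows.append(
            {
                "region_id": region_id,
                "acronym": node.acronym if node else str(region_id),
                "name": node.name if node else str(region_id),
                "n2d": n2d,
                "n3d": n3d,
                "voxel_count": vox,
                "volume_mm3": volume_mm3,
                "density_mm3": n3d / volume_mm3 if volume_mm3 > 0 else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=list(STATS_COLUMNS))
    for k, v in metadata.items():
        df[k] = v
    return df


def aggregate(stats: pd.DataFrame, ontology: Ontology) -> pd.DataFrame:
    """Roll leaf statistics up to every ontology node.

    Parent ``n2d``/``n3d``/``voxel_count`` are sums over all descendants
    plus any voxels labelled directly at the parent; density is recomputed
    from the summed quantities.  Metadata columns (constant per table) are
    carried through.  Idempotent: aggregating an aggregate changes nothing.
    """
    unknown = sorted(r for r in stats["region_id"] if r not in ontology)
    if unknown:
        raise KeyError(f"stats contain region ids absent from the ontology: {unknown}")
    base = stats.drop_duplicates("region_id").set_index("region_id")
    meta_cols = [c for c in stats.columns if c not in STATS_COLUMNS and c != "is_aggregate"]
    qty = ["n2d", "n3d", "voxel_count", "volume_mm3"]
    # direct contribution of each node: its own labelled voxels/cells.  An
    # already-aggregated table satisfies parent = direct + sum(children), so
    # subtracting child rows recovers the direct table — this makes
    # aggregation idempotent.
    direct = base[qty].copy()
    if "is_aggregate" in stats.columns and stats["is_aggregate"].any():
        for region_id in base.index:
            for child in ontology.children(region_id):
                if child in base.index:
                    direct.loc[region_id, qty] = (
                        direct.loc[region_id, qty] - base.loc[child, qty]
                    )
    rows = []
    for region_id in ontology.ids:
        member_ids = [region_id] + ontology.descendants(region_id)
        present = direct.index.intersection(member_ids)
        if len(present) == 0:
            continue
        members = direct.loc[present]
        n2d = int(members["n2d"].sum())
        vox = int(members["voxel_count"].sum())
        n3d = float(members["n3d"].sum())
        volume_mm3 = float(members["volume_mm3"].sum())
        node = ontology[region_id]
        row = {
            "region_id": region_id,
            "acronym": node.acronym,
            "name": node.name,
            "n2d": n2d,
            "n3d": n3d,
            "voxel_count": vox,
            "volume_mm3": volume_mm3,
            "density_mm3": n3d / volume_mm3 if volume_mm3 > 0 else 0.0,
        }
        for c in meta_cols:
            row[c] = stats[c].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows, columns=list(STATS_COLUMNS) + meta_cols)
    out["is_aggregate"] = True
    return out
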