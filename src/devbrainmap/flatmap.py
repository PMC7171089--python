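"""Cortical flatmaps: evenly spaced bins, layer restriction, densities.

A flatmap partitions the isocortex into bins, each summarising a cortical
column segment on a 2D grid.  The bin geometry itself is an input artifact
(a bin-label volume aligned to the reference brain); this module restricts
it to superficial (layers 1–3) or deep (layers 5–6) laminae, quantifies
registered cells per bin, computes per-age bin volumes by warping the bin
volume through the reverse (reference → age template) registration, and
renders the result as a heat map.

Layer identity is resolved from the ontology by acronym suffix: a region
whose acronym ends in a layer token (``1`` … ``6``, ``2/3``, ``6a``,
``6b``) belongs to that layer; ``6a``/``6b`` count as layer 6.  Layer 4
belongs to neither the superficial nor the deep set and only appears in
the full-cortex map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import matplotlib
import numpy as np
import pandas as pd

from .io import LabelVolume, Ontology, Volume
from .quantify import QuantConfig
from .registration import Transform, apply_to_labels

__all__ = [
    "FlatmapBins",
    "SUPERFICIAL_LAYERS",
    "DEEP_LAYERS",
    "layer_of",
    "layer_region_ids",
    "layer_restrict",
    "bin_densities",
    "render_flatmap",
    "shell_bins",
]

SUPERFICIAL_LAYERS = frozenset({1, 2, 3})
DEEP_LAYERS = frozenset({5, 6})

_LAYER_RE = re.compile(r"(?:^|[^0-9/])([1-6])(/3|a|b)?$")


def layer_of(acronym: str) -> int | None:
    """Cortical layer encoded in a region acronym, or None.

    ``"SSp2/3" -> 2``, ``"VISp6b" -> 6``, ``"ISO4" -> 4``, ``"PVH" -> None``.
    """
    m = _LAYER_RE.search(acronym)
    return int(m.group(1)) if m else None


def layer_region_ids(ontology: Ontology, layers: frozenset[int] | set[int]) -> set[int]:
    """Region ids whose acronym places them in one of ``layers``."""
    return {rid for rid in ontology.ids if layer_of(ontology[rid].acronym) in layers}


@dataclass(frozen=True)
class FlatmapBins:
    """Bin-label volume plus the bin → 2D grid position table.

    ``bin_volume`` holds a positive bin id per binned cortical voxel
    (0 elsewhere) on the reference grid; ``positions`` has one row per bin:
    ``bin_id, grid_x, grid_y``.  Bin ids are contiguous positive integers.
    """

    bin_volume: LabelVolume
    positions: pd.DataFrame

    def __post_init__(self):
        ids = sorted(int(b) for b in self.positions["bin_id"])
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("bin ids must be the contiguous integers 1..n")
        present = set(np.unique(self.bin_volume.data).tolist()) - {0}
        if not present <= set(ids):
            raise ValueError("bin volume contains ids absent from the position table")

    @property
    def n_bins(self) -> int:
        return len(self.positions)

    def voxel_counts(self) -> pd.Series:
        """Voxels per bin, indexed by bin_id (zero-voxel bins included)."""
        ids, counts = np.unique(self.bin_volume.data, return_counts=True)
        s = pd.Series(0, index=self.positions["bin_id"].to_numpy(), dtype=np.int64)
        for i, c in zip(ids, counts):
            if i != 0:
                s.loc[int(i)] = int(c)
        return s


def layer_restrict(bins: FlatmapBins, labels: LabelVolume, which: str) -> FlatmapBins:
    """Restrict the bin volume to the superficial or deep laminae.

    ``which`` is ``"superficial"`` (layers 1–3) or ``"deep"`` (layers 5–6).
    Bins whose intersection with the layer mask is empty are retained with
    zero voxels; their density downstream is reported as missing, not zero.
    """
    try:
        layers = {"superficial": SUPERFICIAL_LAYERS, "deep": DEEP_LAYERS}[which]
    except KeyError:
        raise ValueError(f"which must be 'superficial' or 'deep', got {which!r}") from None
    if labels.ontology is None:
        raise ValueError("label volume needs an ontology to resolve layer identities")
    if not bins.bin_volume.volume.same_grid(labels.volume):
        raise ValueError("bin volume and label volume must share a grid")
    ids = layer_region_ids(labels.ontology, layers)
    mask = np.isin(labels.data, sorted(ids))
    restricted = np.where(mask, bins.bin_volume.data, 0).astype(bins.bin_volume.data.dtype)
    return replace(
        bins,
        bin_volume=LabelVolume(bins.bin_volume.volume.with_data(restricted)),
    )


def bin_densities(
    cells: pd.DataFrame,
    bins: FlatmapBins,
    age_transform: Transform,
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Per-bin counts and densities with age-specific bin volumes.

    ``cells`` must already be registered into the reference space carrying
    the bins.  Bin volumes come from warping the bin-label volume onto the
    age template through ``age_transform`` (the reverse, reference-to-age
    registration) and counting warped voxels — there is deliberately no
    silent fallback to reference-space volumes, so ``age_transform`` is
    required (use an identity transform for the reference age itself).

    Returns one row per bin: ``bin_id, grid_x, grid_y, n2d, n3d,
    volume_mm3, density_mm3`` (density NaN where the bin has no volume).
    """
    if age_transform is None:
        raise ValueError("age_transform is required; pass identity_transform(reference) "
                         "for the reference age")
    config = config or QuantConfig()
    # count cells per bin on the reference grid
    vol = bins.bin_volume.volume
    n = len(cells)
    bin_of_cell = np.zeros(n, dtype=np.int64)
    if n:
        idx = vol.point_to_voxel(cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
        inside = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
        ii = idx[inside]
        bin_of_cell[inside] = bins.bin_volume.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    counts = pd.Series(bin_of_cell[bin_of_cell > 0]).value_counts()

    # age-specific bin volumes via the reverse registration
    warped = apply_to_labels(age_transform, bins.bin_volume)
    wa_ids, wa_counts = np.unique(warped.data, return_counts=True)
    warped_vox = {int(i): int(c) for i, c in zip(wa_ids, wa_counts) if i != 0}
    warped_voxel_volume = float(np.prod(warped.spacing))

    rows = []
    for _, pos in bins.positions.iterrows():
        b = int(pos["bin_id"])
        n2d = int(counts.get(b, 0))
        n3d = config.k3d * n2d
        vol_mm3 = warped_vox.get(b, 0) * warped_voxel_volume * 1e-9
        rows.append(
            {
                "bin_id": b,
                "grid_x": int(pos["grid_x"]),
                "grid_y": int(pos["grid_y"]),
                "n2d": n2d,
                "n3d": n3d,
                "volume_mm3": vol_mm3,
                "density_mm3": n3d / vol_mm3 if vol_mm3 > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def render_flatmap(
    table: pd.DataFrame,
    bins: FlatmapBins,
    path=None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
):
    """Render a per-bin density table as a 2D heat-map image.

    Empty bins (NaN density) get a distinct "missing" colour, not zero.
    The TSV table is the source of truth; rendering the same table twice
    produces identical image bytes.  Returns the 2D density array; if
    ``path`` is given, also writes a PNG there.
    """
    nx = int(bins.positions["grid_x"].max()) + 1
    ny = int(bins.positions["grid_y"].max()) + 1
    grid = np.full((ny, nx), np.nan)
    for _, row in table.iterrows():
        grid[int(row["grid_y"]), int(row["grid_x"])] = row["density_mm3"]
    if path is not None:
        import matplotlib.pyplot as plt

        cm = matplotlib.colormaps[cmap].copy()
        cm.set_bad("lightgrey")
        fig, ax = plt.subplots(figsize=(max(nx / 4, 2), max(ny / 4, 2)))
        im = ax.imshow(grid, cmap=cm, vmin=vmin, vmax=vmax, origin="lower",
                       interpolation="nearest")
        fig.colorbar(im, ax=ax, label="cells per mm$^3$")
        ax.set_xlabel("flatmap x bin")
        ax.set_ylabel("flatmap y bin")
        fig.savefig(path, dpi=100, metadata={"Software": "devbrainmap"})
        plt.close(fig)
    return grid


def shell_bins(
    labels: LabelVolume,
    cortex_region_ids: set[int],
    n_theta: int = 8,
    n_phi: int = 6,
) -> FlatmapBins:
    """Toy flatmap bins for an ellipsoidal-shell phantom cortex.

    Parameterises the shell by azimuth (around the z axis) and polar angle
    from the volume centre and lays a regular ``n_theta × n_phi`` grid over
    those angles, so voxels along one radial column — across all layers —
    share a bin, mimicking cortical-column bins.  Real studies supply a
    measured bin volume instead.
    """
    data = labels.data
    mask = np.isin(data, sorted(cortex_region_ids))
    shape = np.asarray(labels.shape, dtype=float)
    centre = (shape - 1) / 2.0
    idx = np.argwhere(mask).astype(float)
    d = (idx - centre) / (shape / 2.0)  # normalised direction components
    theta = np.arctan2(d[:, 1], d[:, 0])  # (-pi, pi]
    r = np.linalg.norm(d, axis=1)
    phi = np.arccos(np.clip(d[:, 2] / np.maximum(r, 1e-12), -1.0, 1.0))  # [0, pi]
    ti = np.clip(((theta + np.pi) / (2 * np.pi) * n_theta).astype(int), 0, n_theta - 1)
    pi_ = np.clip((phi / np.pi * n_phi).astype(int), 0, n_phi - 1)
    flat = ti * n_phi + pi_ + 1
    bin_data = np.zeros(labels.shape, dtype=np.int32)
    bin_data[tuple(idx.astype(int).T)] = flat
    positions = pd.DataFrame(
        {
            "bin_id": np.arange(1, n_theta * n_phi + 1),
            "grid_x": np.repeat(np.arange(n_theta), n_phi),
            "grid_y": np.tile(np.arange(n_phi), n_theta),
        }
    )
    return FlatmapBins(LabelVolume(Volume(bin_data, labels.spacing, labels.volume.origin)),
                       positions)
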