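"""Minimal 2D-section blob detector (pipeline plumbing).

A deliberately simple threshold + connected-component detector so the
pipeline can run end to end from images.  Production mapping studies use a
trained classifier behind the same cell-table interface; this module is a
swappable stand-in, not that detector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage import measure

from .io import CELL_COLUMNS, Volume, make_cell_table

__all__ = ["detect_cells_2d", "detect_cells_stack"]


def detect_cells_2d(
    section: np.ndarray,
    threshold: float,
    min_area: int = 1,
    max_area: int = 10_000,
) -> pd.DataFrame:
    """Detect bright blobs on one 2D section (axes ``(x, y)``, pixel units).

    Pixels above ``threshold`` are grouped into connected components;
    components within ``[min_area, max_area]`` pixels are reported at their
    centroid as fractional pixel coordinates ``x``/``y``.  Deterministic.
    A threshold outside the image's dynamic range yields a warning and an
    empty result.
    """
    section = np.asarray(section)
    if section.ndim != 2:
        raise ValueError("section must be 2D")
    if section.size and (threshold > section.max() or threshold < section.min()):
        warnings.warn(
            f"threshold {threshold} outside image range "
            f"[{section.min()}, {section.max()}]; no cells detected",
            stacklevel=2,
        )
    mask = section > threshold
    labelled = measure.label(mask, connectivity=2)
    rows = []
    for prop in measure.regionprops(labelled):
        if min_area <= prop.area <= max_area:
            cx, cy = prop.centroid  # axis-0 = x, axis-1 = y in our convention
            rows.append((cx, cy, prop.area))
    return pd.DataFrame(rows, columns=["x_px", "y_px", "area_px"])


def detect_cells_stack(
    stack: Volume,
    threshold: float,
    min_area: int = 1,
    max_area: int = 10_000,
    channel: int = 0,
) -> pd.DataFrame:
    """Run the 2D detector on every z-section of a volume.

    Returns a standard cell table in physical coordinates: pixel centroids
    scaled by the section spacing, with ``z_um`` at the section's centre
    plane and ``section_index`` the z index.
    """
    sx, sy, sz = stack.spacing
    ox, oy, oz = stack.origin
    xs, ys, zs, sects = [], [], [], []
    for k in range(stack.shape[2]):
        found = detect_cells_2d(stack.data[:, :, k], threshold, min_area, max_area)
        if len(found) == 0:
            continue
        # centroid of pixel i is at (i + 0.5) * spacing in the corner convention
        xs.append((found["x_px"].to_numpy() + 0.5) * sx + ox)
        ys.append((found["y_px"].to_numpy() + 0.5) * sy + oy)
        zs.append(np.full(len(found), (k + 0.5) * sz + oz))
        sects.append(np.full(len(found), k, dtype=np.int64))
    if not xs:
        return pd.DataFrame(columns=list(CELL_COLUMNS))
    return make_cell_table(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
        np.concatenate(sects), channel=channel,
    )
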