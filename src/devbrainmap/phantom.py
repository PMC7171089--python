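"""Synthetic phantom brains with known ground truth.

The phantom emulates what the downstream pipeline consumes, not microscopy
physics: an ellipsoidal "brain" with a 6-shell cortex (one shell per
cytoarchitectonic layer) and nested interior regions, warped per subject by
a smooth random B-spline deformation plus a per-age global scale, with
NB-distributed per-region cell counts placed uniformly inside each region.

Cells counted on sparse 2D sections undercount the 3D truth; pipelines
correct this with a multiplicative 2D→3D factor (1.4 here).  The phantom
makes that correction exactly invertible: :func:`thin_cells` keeps each
simulated 3D cell with probability ``1/1.4``, so multiplying the thinned
("2D-detected") counts by 1.4 recovers the generating truth in expectation.

All randomness derives from the single seed in :class:`PhantomSpec` through
``numpy.random.SeedSequence`` spawning: stream ``(seed, age, subject)`` for
deformations, ``(seed, "cells", seed2)`` for cell placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .io import CELL_COLUMNS, LabelVolume, Ontology, OntologyNode, Volume, make_cell_table
from .registration import GridSpec, Transform, volume_to_sitk

__all__ = [
    "RegionPrimitive",
    "PhantomSpec",
    "PhantomSubject",
    "default_spec",
    "build_base",
    "make_phantom_series",
    "simulate_cells",
    "thin_cells",
    "K3D_DEFAULT",
]

#: 2D→3D count conversion factor the thinning emulation inverts.
K3D_DEFAULT = 1.4


@dataclass(frozen=True)
class RegionPrimitive:
    """One geometric region: an ellipsoid or a box, in fractional coordinates.

    ``center`` and ``size`` are fractions of the grid extent; ``size`` is
    the full width per axis (for ellipsoids, the full axis length).
    """

    region_id: int
    acronym: str
    name: str
    parent_id: int | None
    kind: Literal["ellipsoid", "box"]
    center: tuple[float, float, float]
    size: tuple[float, float, float]
    intensity: float = 100.0

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        # geometry in index space about the symmetric centre (N-1)/2 so a
        # mirror-symmetric layout is voxelwise mirror-symmetric
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        c = [self.center[a] * (shape[a] - 1) for a in range(3)]
        h = [max(self.size[a] * shape[a] / 2.0, 1e-9) for a in range(3)]
        if self.kind == "box":
            inside = np.ones(shape, dtype=bool)
            for a in range(3):
                inside &= np.abs(grids[a] - c[a]) <= h[a]
            return inside
        r2 = np.zeros(shape, dtype=float)
        for a in range(3):
            r2 += ((grids[a] - c[a]) / h[a]) ** 2
        return r2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate a phantom cohort.

    Densities are cells per mm³; ``dispersion`` is the NB size parameter
    theta (variance = mu + mu²/theta; theta → ∞ is the Poisson limit).
    ``deformation_um`` is the typical control-point displacement of the
    random subject warp; ``age_scales`` are global linear scale factors, one
    per age (younger = smaller).  ``asymmetry`` adds an intensity bump on
    the right hemisphere only; 0 keeps the base perfectly mirror-symmetric.
    """

    shape: tuple[int, int, int] = (64, 56, 40)
    spacing: tuple[float, float, float] = (20.0, 20.0, 50.0)
    regions: tuple[RegionPrimitive, ...] = ()
    densities: dict[int, float] = field(default_factory=dict)
    dispersion: float | dict[int, float] = 20.0
    deformation_um: float = 40.0
    age_scales: tuple[float, ...] = (1.0, 0.9, 0.8)
    asymmetry: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(d < 0 for d in self.densities.values()):
            raise ValueError("densities must be >= 0")
        disp = self.dispersion
        vals = disp.values() if isinstance(disp, dict) else [disp]
        if any(d <= 0 for d in vals):
            raise ValueError("dispersion must be > 0")
        ids = [r.region_id for r in self.regions]
        if 0 in ids:
            raise ValueError("region id 0 is reserved for background")
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")

    def theta(self, region_id: int) -> float:
        if isinstance(self.dispersion, dict):
            return float(self.dispersion[region_id])
        return float(self.dispersion)

    def ontology(self) -> Ontology:
        """Ontology covering the layout's regions plus a synthetic root."""
        nodes = [OntologyNode(id=997, acronym="root", name="phantom brain root", parent_id=None)]
        for r in self.regions:
            nodes.append(
                OntologyNode(
                    id=r.region_id,
                    acronym=r.acronym,
                    name=r.name,
                    parent_id=997 if r.parent_id is None else r.parent_id,
                )
            )
        return Ontology(nodes)


# region-id blocks of the default layout
BRAIN_ID = 8
CORTEX_ID = 100
LAYER_IDS = {1: 101, 2: 102, 3: 103, 4: 104, 5: 105, 6: 106}
NUCLEUS_IDS = (201, 202, 211, 212, 220)


def default_spec(**overrides) -> PhantomSpec:
    """The stock layout: ellipsoid brain, 6-shell cortex, nested nuclei.

    The cortex occupies the outer shells of the brain ellipsoid, split into
    six concentric sub-shells standing in for layers 1 (outermost) to 6
    (innermost).  Interior "nuclei" come in mirror-symmetric left/right
    pairs plus one midline region, giving the left-right symmetry and
    hierarchy the template/flatmap stages exercise.
    """
    # cortex shells: consecutive ellipsoids; later (smaller) primitives
    # overwrite earlier ones, so paint from layer 1 outermost inwards, then
    # the interior, then the nuclei
    regions = []
    shell_outer = [0.92, 0.84, 0.76, 0.68, 0.60, 0.52, 0.44]
    for layer in range(1, 7):
        s = shell_outer[layer - 1]
        regions.append(
            RegionPrimitive(
                LAYER_IDS[layer], f"ISO{layer}", f"isocortex layer {layer}", CORTEX_ID,
                "ellipsoid", (0.5, 0.5, 0.5), (s, s, s), intensity=200.0 - 15 * layer,
            )
        )
    # interior: mirror pairs about mid-x, plus one midline nucleus
    regions += [
        RegionPrimitive(BRAIN_ID, "BR", "deep interior", None, "ellipsoid",
                        (0.5, 0.5, 0.5), (0.44, 0.44, 0.44), intensity=60.0),
        RegionPrimitive(201, "NL1", "nucleus 1 left", None, "ellipsoid",
                        (0.38, 0.44, 0.5), (0.12, 0.12, 0.18), intensity=150.0),
        RegionPrimitive(202, "NR1", "nucleus 1 right", None, "ellipsoid",
                        (0.62, 0.44, 0.5), (0.12, 0.12, 0.18), intensity=150.0),
        RegionPrimitive(211, "NL2", "nucleus 2 left", None, "box",
                        (0.40, 0.58, 0.46), (0.09, 0.09, 0.14), intensity=120.0),
        RegionPrimitive(212, "NR2", "nucleus 2 right", None, "box",
                        (0.60, 0.58, 0.46), (0.09, 0.09, 0.14), intensity=120.0),
        RegionPrimitive(220, "MID", "midline nucleus", None, "ellipsoid",
                        (0.5, 0.52, 0.55), (0.1, 0.12, 0.18), intensity=170.0),
    ]
    base = PhantomSpec(
        regions=tuple(regions),
        densities={LAYER_IDS[l]: d for l, d in
                   zip(range(1, 7), (800.0, 1200.0, 1000.0, 600.0, 900.0, 700.0))}
        | {201: 1500.0, 202: 1500.0, 211: 1100.0, 212: 1100.0, 220: 2000.0},
    )
    return replace(base, **overrides)


def _ontology_with_cortex(spec: PhantomSpec) -> Ontology:
    """Stock-layout ontology including the synthetic cortex parent node."""
    nodes = [
        OntologyNode(997, "root", "phantom brain root", None),
        OntologyNode(CORTEX_ID, "ISO", "isocortex", 997),
    ]
    for r in spec.regions:
        if r.region_id in {n.id for n in nodes}:
            continue
        nodes.append(
            OntologyNode(r.region_id, r.acronym, r.name,
                         997 if r.parent_id is None else r.parent_id)
        )
    return Ontology(nodes)


def build_base(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Paint the base (undeformed) intensity and label volumes.

    Later primitives overwrite earlier ones, so nesting order in
    ``spec.regions`` is outermost-first.  With ``asymmetry == 0`` the
    result is exactly equal to its mid-x mirror.
    """
    for a, n in enumerate(spec.shape):
        if n < 8:
            raise ValueError(f"grid too small: axis {a} has {n} voxels (< 8)")
    intensity = np.zeros(spec.shape, dtype=np.float32)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for r in spec.regions:
        m = r.mask(spec.shape)
        intensity[m] = r.intensity
        labels[m] = r.region_id
    if spec.asymmetry > 0:
        # right-hemisphere-only smooth bump breaks mirror symmetry
        gx, gy, gz = np.meshgrid(*[np.arange(n, dtype=float) / max(n - 1, 1) for n in spec.shape],
                                 indexing="ij")
        bump = np.exp(-(((gx - 0.7) / 0.12) ** 2 + ((gy - 0.5) / 0.15) ** 2
                        + ((gz - 0.5) / 0.2) ** 2))
        intensity += spec.asymmetry * 100.0 * bump.astype(np.float32) * (labels > 0)
    ontology = _ontology_with_cortex(spec) if any(
        r.parent_id == CORTEX_ID for r in spec.regions) else spec.ontology()
    vol = Volume(intensity, spec.spacing)
    return vol, LabelVolume(Volume(labels, spec.spacing), ontology)


@dataclass
class PhantomSubject:
    """One simulated subject: warped image, labels, and the true transform.

    ``transform_to_base`` maps subject-grid points to base-space points
    (the resampling convention), i.e. it is what a perfect registration
    ``register(fixed=subject, moving=base)`` would recover.
    """

    age_index: int
    subject_index: int
    volume: Volume
    labels: LabelVolume
    transform_to_base: Transform


def _random_subject_transform(
    spec: PhantomSpec, base: Volume, age_index: int, subject_index: int
) -> Transform:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, age_index, subject_index]))
    scale = spec.age_scales[age_index] if age_index < len(spec.age_scales) else spec.age_scales[-1]
    centre = tuple(0.5 * n * s for n, s in zip(base.shape, base.spacing))
    # subject(x) = base(T(x)); T scales about the centre so the subject
    # looks like the base shrunk by `scale`
    affine = sitk.AffineTransform(3)
    affine.SetCenter(centre)
    affine.Scale(1.0 / scale)

    stages = [affine]
    if spec.deformation_um > 0:
        ref = volume_to_sitk(base)
        bspl = sitk.BSplineTransformInitializer(ref, [3, 3, 3], order=3)
        coeffs = rng.normal(0.0, spec.deformation_um, size=len(bspl.GetParameters()))
        bspl.SetParameters(tuple(coeffs))
        stages = [bspl, affine]  # bspline applied first: T = affine ∘ bspline

    g = GridSpec.of(base)
    return Transform(stages=stages, fixed_grid=g, moving_grid=g)


def make_phantom_series(
    spec: PhantomSpec, n_ages: int, n_subjects_per_age: int
) -> list[list[PhantomSubject]]:
    """Generate ``n_ages`` × ``n_subjects_per_age`` warped subjects.

    Each subject is the base geometry pushed through its own smooth random
    deformation composed with the age's global scale; the ground-truth
    labels and transform ride along.  Deterministic for a given seed.
    """
    if n_ages < 1 or n_subjects_per_age < 1:
        raise ValueError("need at least one age and one subject per age")
    base_vol, base_labels = build_base(spec)
    from .registration import apply_to_labels, apply_to_volume  # local: avoid cycle at import

    series: list[list[PhantomSubject]] = []
    for age in range(n_ages):
        cohort = []
        for subj in range(n_subjects_per_age):
            t = _random_subject_transform(spec, base_vol, age, subj)
            vol = apply_to_volume(t, base_vol, interpolation="linear")
            labs = apply_to_labels(t, base_labels)
            cohort.append(PhantomSubject(age, subj, vol, labs, t))
        series.append(cohort)
    return series


# ---------------------------------------------------------------------------
# Cell simulation

def _nb_draw(rng: np.random.Generator, mean: float, theta: float) -> int:
    """One NB(mean, size=theta) draw via the Gamma-Poisson mixture."""
    if mean <= 0:
        return 0
    if np.isinf(theta):
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return int(rng.poisson(lam))


def simulate_cells(label_volume: LabelVolume, spec: PhantomSpec, seed: int) -> pd.DataFrame:
    """Simulate a 3D cell table for one subject.

    Per region with nonzero density the total count is NB with mean
    ``density × region volume (mm³)`` and the spec'd dispersion; cells are
    placed uniformly over the region's voxels (uniform within each voxel).
    ``section_index`` is the z-plane of each cell, emulating the serial
    2D-section acquisition.
    """
    counts = label_volume.voxel_counts()
    missing = sorted(r for r, d in spec.densities.items() if d > 0 and r not in counts)
    if missing:
        raise KeyError(f"density specified for regions absent from the label volume: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCE11, seed]))
    spacing = np.asarray(label_volume.spacing)
    vox_mm3 = float(np.prod(spacing)) * 1e-9
    data = label_volume.data
    xs, ys, zs, sects = [], [], [], []
    for region_id in sorted(spec.densities):
        density = spec.densities[region_id]
        if density <= 0:
            continue
        vol_mm3 = counts[region_id] * vox_mm3
        n = _nb_draw(rng, density * vol_mm3, spec.theta(region_id))
        if n == 0:
            continue
        idx = np.argwhere(data == region_id)
        pick = idx[rng.integers(0, len(idx), size=n)]
        jitter = rng.random((n, 3))
        pos = (pick + jitter) * spacing  # corner-origin convention
        xs.append(pos[:, 0]); ys.append(pos[:, 1]); zs.append(pos[:, 2])
        sects.append(pick[:, 2])
    if not xs:
        return pd.DataFrame(columns=list(CELL_COLUMNS))
    return make_cell_table(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
        np.concatenate(sects), channel=0,
    )


def thin_cells(cells: pd.DataFrame, k3d: float = K3D_DEFAULT, seed: int = 0) -> pd.DataFrame:
    """Thin a 3D cell table to emulate 2D-section detection.

    Keeps each cell independently with probability ``1/k3d`` so that the
    downstream ``n3d = k3d × n2d`` correction is unbiased for the truth.
    """
    if k3d <= 0:
        raise ValueError("k3d must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([0x2D, seed]))
    keep = rng.random(len(cells)) < (1.0 / k3d)
    return cells.loc[keep].reset_index(drop=True)
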