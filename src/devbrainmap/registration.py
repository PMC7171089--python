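"""Intensity-based 3D registration: multi-resolution affine then B-spline.

The registration contract mirrors the classic whole-brain mapping recipe:
a 3D affine stage run over a 4-level image pyramid, followed by a free-form
B-spline stage over a 6-level schedule, optimising a similarity metric
(mutual information by default, mean squares for same-modality data).

Transform direction follows the resampling convention: a :class:`Transform`
returned by :func:`register` maps **fixed-space points to moving-space
points**, so that ``apply_to_volume`` pulls the moving image onto the fixed
grid.  Point sets live in the moving image's physical space and are pushed
*forward* into fixed space with the numerically inverted map (fixed-point
iteration for the B-spline stage, tolerance 0.1 voxel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .io import LabelVolume, Volume, validate_cells

__all__ = [
    "RegistrationConfig",
    "Transform",
    "RegistrationError",
    "register",
    "apply_to_volume",
    "apply_to_labels",
    "apply_to_points",
    "compose",
    "identity_transform",
    "save_transform",
    "load_transform",
]


class RegistrationError(RuntimeError):
    """Optimisation failed; carries the per-level metric trace."""

    def __init__(self, message: str, metric_trace: dict | None = None):
        super().__init__(message)
        self.metric_trace = metric_trace or {}


@dataclass
class RegistrationConfig:
    """Knobs for the two-stage registration.

    ``affine_levels``/``bspline_levels`` are image-pyramid depths (defaults
    4 and 6).  ``metric`` is ``"mi"`` (Mattes mutual information) or
    ``"mse"`` (mean squares).  ``sampling_fraction`` of 1.0 evaluates the
    metric on every voxel; smaller fractions use regular subsampling with
    the given ``seed``, so either way a run is deterministic.
    ``bspline_mesh_size`` is the free-form control-point mesh (held fixed
    across pyramid levels; the pyramid supplies the coarse-to-fine
    schedule).
    """

    affine_levels: int = 4
    bspline_levels: int = 6
    metric: str = "mi"
    mi_bins: int = 32
    affine_iterations: int = 100
    bspline_iterations: int = 12
    sampling_fraction: float = 0.25
    seed: int = 0
    bspline_mesh_size: tuple[int, int, int] = (6, 6, 6)
    run_bspline: bool = True

    def __post_init__(self):
        if self.affine_levels < 1 or self.bspline_levels < 1:
            raise ValueError("pyramid levels must be >= 1")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if self.metric not in ("mi", "mse"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid in physical space (um)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    @classmethod
    def of(cls, v: Volume | LabelVolume) -> "GridSpec":
        vol = v.volume if isinstance(v, LabelVolume) else v
        return cls(tuple(vol.shape), tuple(vol.spacing), tuple(vol.origin))

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class Transform:
    """Composable spatial map from fixed space to moving space.

    ``stages`` are SimpleITK transforms in application order: the composite
    map is ``stages[-1] ∘ ... ∘ stages[0]`` — i.e. ``stages[0]`` is applied
    to the input point first.
    """

    stages: list
    fixed_grid: GridSpec
    moving_grid: GridSpec
    metric_trace: dict = field(default_factory=dict)

    def as_sitk(self) -> sitk.Transform:
        # sitk.CompositeTransform applies the *last added* transform first
        comp = sitk.CompositeTransform(3)
        for t in reversed(self.stages):
            comp.AddTransform(t)
        return comp

    def transform_points(self, points_um: np.ndarray) -> np.ndarray:
        """Map fixed-space points (n, 3) to moving space."""
        comp = self.as_sitk()
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return np.array([comp.TransformPoint(tuple(p)) for p in pts])

    def inverse_transform_points(
        self, points_um: np.ndarray, tol_voxel: float = 0.1, max_iter: int = 100
    ) -> np.ndarray:
        """Map moving-space points to fixed space (numeric inverse).

        Solves ``T(x) = p`` by fixed-point iteration ``x <- x - (T(x) - p)``,
        which converges for deformations that do not fold.  Tolerance is
        ``tol_voxel`` of the smallest fixed-grid spacing.
        """
        comp = self.as_sitk()
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        tol = tol_voxel * min(self.fixed_grid.spacing)
        out = np.empty_like(pts)
        for i, p in enumerate(pts):
            x = p.copy()
            for _ in range(max_iter):
                resid = np.asarray(comp.TransformPoint(tuple(x))) - p
                if np.linalg.norm(resid) < tol:
                    break
                x = x - resid
            out[i] = x
        return out


def identity_transform(fixed: Volume | LabelVolume, moving: Volume | LabelVolume | None = None) -> Transform:
    """The identity map on ``fixed``'s grid."""
    g = GridSpec.of(fixed)
    return Transform(
        stages=[sitk.Transform(3, sitk.sitkIdentity)],
        fixed_grid=g,
        moving_grid=GridSpec.of(moving) if moving is not None else g,
    )


# ---------------------------------------------------------------------------
# Volume <-> SimpleITK conversion.  Our arrays are (x, y, z); SimpleITK's
# GetImageFromArray expects (z, y, x).

def volume_to_sitk(v: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(v.data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    # our origin is the voxel *corner*; ITK's is the first voxel *center*
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(v.origin, v.spacing)))
    return img


def sitk_to_volume(img: sitk.Image, like: Volume | None = None) -> Volume:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    spacing = tuple(img.GetSpacing())
    origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    return Volume(data, spacing, origin)


def _shrink_factors(levels: int, shape: tuple[int, int, int]) -> list[int]:
    """Power-of-two pyramid, capped so the coarsest image keeps >= 8 voxels."""
    max_factor = max(1, min(shape) // 8)
    factors = []
    for level in range(levels):
        f = 2 ** (levels - 1 - level)
        factors.append(max(1, min(f, max_factor)))
    return factors


def _setup_common(reg: sitk.ImageRegistrationMethod, config: RegistrationConfig, levels: int, shape):
    if config.metric == "mi":
        reg.SetMetricAsMattesMutualInformation(config.mi_bins)
    else:
        reg.SetMetricAsMeanSquares()
    if config.sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(config.sampling_fraction, config.seed)
    else:
        reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    factors = _shrink_factors(levels, shape)
    reg.SetShrinkFactorsPerLevel(factors)
    reg.SetSmoothingSigmasPerLevel([max(f // 2, 0) for f in factors])
    reg.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)


def _trace_observer(reg: sitk.ImageRegistrationMethod, trace: list):
    level_marks: list[int] = []

    def on_iteration():
        trace.append(float(reg.GetMetricValue()))

    def on_level():
        level_marks.append(len(trace))

    reg.AddCommand(sitk.sitkIterationEvent, on_iteration)
    reg.AddCommand(sitk.sitkMultiResolutionIterationEvent, on_level)
    return level_marks


def register(fixed: Volume, moving: Volume, config: RegistrationConfig | None = None) -> Transform:
    """Register ``moving`` onto ``fixed``: affine stage, then B-spline stage.

    Returns a :class:`Transform` mapping fixed-space points into moving
    space, with the per-level metric trace attached.  Deterministic for a
    given ``(fixed, moving, config)`` because metric sampling is either
    exhaustive or seeded.
    """
    config = config or RegistrationConfig()
    f_img = sitk.Cast(volume_to_sitk(fixed), sitk.sitkFloat64)
    m_img = sitk.Cast(volume_to_sitk(moving), sitk.sitkFloat64)
    trace: dict = {}

    # ---- stage 1: affine over a 4-level pyramid
    affine_trace: list[float] = []
    reg = sitk.ImageRegistrationMethod()
    _setup_common(reg, config, config.affine_levels, fixed.shape)
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg.SetInitialTransform(initial, inPlace=True)
    reg.SetOptimizerAsGradientDescentLineSearch(
        learningRate=1.0,
        numberOfIterations=config.affine_iterations,
        convergenceMinimumValue=1e-7,
        convergenceWindowSize=10,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    level_marks = _trace_observer(reg, affine_trace)
    affine = sitk.AffineTransform(reg.Execute(f_img, m_img))
    trace["affine"] = affine_trace
    trace["affine_levels"] = list(level_marks)
    trace["affine_stop"] = reg.GetOptimizerStopConditionDescription()
    # metric values are only comparable within a pyramid level; require the
    # finest level not to have ended worse than it started
    start = level_marks[-1] if level_marks else 0
    final = affine_trace[start:]
    if len(final) >= 2:
        span = max(final) - min(final)
        if final[-1] - final[0] > max(0.01 * (1.0 + abs(final[0])), 0.1 * span):
            raise RegistrationError(
                f"affine stage diverged at the finest level ({final[0]:.4g} -> {final[-1]:.4g})",
                trace,
            )
    det = np.linalg.det(np.asarray(affine.GetMatrix()).reshape(3, 3))
    if abs(det) < 1e-12:
        raise RegistrationError(f"affine stage produced a singular matrix (det={det:g})", trace)

    stages = [affine]

    # ---- stage 2: B-spline over a 6-level schedule with mesh refinement
    if config.run_bspline:
        bspline_trace: list[float] = []
        reg = sitk.ImageRegistrationMethod()
        _setup_common(reg, config, config.bspline_levels, fixed.shape)
        mesh = [int(m) for m in config.bspline_mesh_size]
        bspline = sitk.BSplineTransformInitializer(f_img, mesh, order=3)
        reg.SetInitialTransform(bspline, inPlace=True)
        reg.SetMovingInitialTransform(affine)
        reg.SetOptimizerAsLBFGSB(numberOfIterations=config.bspline_iterations)
        _trace_observer(reg, bspline_trace)
        bspline_result = reg.Execute(f_img, m_img)
        trace["bspline"] = bspline_trace
        trace["bspline_stop"] = reg.GetOptimizerStopConditionDescription()
        # total map: x_fixed -> affine(bspline(x_fixed))
        stages = [bspline_result, affine]

    return Transform(
        stages=stages,
        fixed_grid=GridSpec.of(fixed),
        moving_grid=GridSpec.of(moving),
        metric_trace=trace,
    )


# ---------------------------------------------------------------------------
# Applying transforms

def _resample(t: Transform, v: Volume, interpolator, default_value: float) -> Volume:
    ref = Volume(np.zeros(t.fixed_grid.shape, dtype=np.uint8), t.fixed_grid.spacing, t.fixed_grid.origin)
    out = sitk.Resample(
        volume_to_sitk(v),
        volume_to_sitk(ref),
        t.as_sitk(),
        interpolator,
        default_value,
    )
    res = sitk_to_volume(out)
    return Volume(res.data.astype(v.data.dtype, copy=False), res.spacing, res.origin)


def apply_to_volume(t: Transform, v: Volume, interpolation: str = "linear") -> Volume:
    """Warp ``v`` (moving space) onto the transform's fixed grid."""
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[interpolation]
    return _resample(t, v, interp, 0.0)


def apply_to_labels(t: Transform, lv: LabelVolume) -> LabelVolume:
    """Warp a label image with nearest-neighbour interpolation.

    Nearest-neighbour guarantees no label appears in the output that was
    absent from the input.
    """
    warped = _resample(t, lv.volume, sitk.sitkNearestNeighbor, 0.0)
    return LabelVolume(warped, lv.ontology)


def apply_to_points(t: Transform, cells: pd.DataFrame) -> pd.DataFrame:
    """Map a cell table from moving space into fixed space.

    Adds/overwrites an ``out_of_domain`` boolean column: points landing
    outside the fixed grid's bounding box are flagged but retained.
    """
    validate_cells(cells)
    out = cells.copy()
    if len(out) == 0:
        out["out_of_domain"] = pd.Series(dtype=bool)
        return out
    pts = out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    mapped = t.inverse_transform_points(pts)
    out[["x_um", "y_um", "z_um"]] = mapped
    lo = np.asarray(t.fixed_grid.origin)
    hi = lo + t.fixed_grid.extent
    out["out_of_domain"] = ~np.all((mapped >= lo) & (mapped < hi), axis=1)
    return out


def compose(t1: Transform, t2: Transform) -> Transform:
    """Compose two registrations: ``compose(t1, t2)(x) = t1(t2(x))``.

    With ``t1`` mapping B-space points to C-space (``register(fixed=B,
    moving=C)``) and ``t2`` mapping A to B, the composite maps A to C and
    can resample a C-space image onto A's grid.  Example — carrying adult
    labels to the youngest age through an intermediate template:
    ``compose(register(P14, adult), register(P7, P14))`` maps P7 → adult.
    Composition is associative.
    """
    return Transform(
        stages=list(t2.stages) + list(t1.stages),
        fixed_grid=t2.fixed_grid,
        moving_grid=t1.moving_grid,
        metric_trace={"first": t2.metric_trace, "second": t1.metric_trace},
    )


# ---------------------------------------------------------------------------
# Serialisation: JSON manifest + ITK text transform file

def save_transform(t: Transform, path_prefix: str | Path) -> Path:
    prefix = Path(path_prefix)
    tfm_path = prefix.with_suffix(".tfm")
    sitk.WriteTransform(t.as_sitk(), str(tfm_path))
    manifest = {
        "n_stages": len(t.stages),
        "fixed_grid": {
            "shape": list(t.fixed_grid.shape),
            "spacing": list(t.fixed_grid.spacing),
            "origin": list(t.fixed_grid.origin),
        },
        "moving_grid": {
            "shape": list(t.moving_grid.shape),
            "spacing": list(t.moving_grid.spacing),
            "origin": list(t.moving_grid.origin),
        },
        "transform_file": tfm_path.name,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(manifest, indent=1))
    return json_path


def load_transform(path_prefix: str | Path) -> Transform:
    prefix = Path(path_prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    comp = sitk.ReadTransform(str(prefix.parent / manifest["transform_file"]))
    fg = manifest["fixed_grid"]
    mg = manifest["moving_grid"]
    return Transform(
        stages=[comp],
        fixed_grid=GridSpec(tuple(fg["shape"]), tuple(fg["spacing"]), tuple(fg["origin"])),
        moving_grid=GridSpec(tuple(mg["shape"]), tuple(mg["spacing"]), tuple(mg["origin"])),
    )
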