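"""Phantom-based validation studies.

Self-contained experiments that exercise the pipeline against phantom
ground truth: NB test calibration, the planted sexual-dimorphism screen,
spatial density recovery, registration benchmarks, and flatmap uniformity.
Both the test suite and the reproduction script drive these; every study
is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import phantom, quantify, templates
from . import flatmap as flatmap_mod
from . import registration as reg
from . import stats as st
from .io import LabelVolume, Ontology, OntologyNode, Volume

__all__ = [
    "type_i_error",
    "grid_label_volume",
    "dimorphism_screen",
    "density_recovery",
    "registration_identity_dice",
    "landmark_error_um",
    "sequential_vs_direct_dice",
    "flatmap_uniformity",
]


def type_i_error(
    n_sim: int = 2000,
    mean: float = 500.0,
    theta: float = 20.0,
    n_per_group: int = 5,
    config: st.StatsConfig | None = None,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the NB group test under the null."""
    config = config or st.StatsConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x71]))
    rejections = 0
    for _ in range(n_sim):
        a = st._rnb(rng, mean, theta, n_per_group)
        b = st._rnb(rng, mean, theta, n_per_group)
        r = st.nb_group_test(a, b, config=config)
        rejections += r.p_value < config.alpha
    return rejections / n_sim


def grid_label_volume(
    n_regions: int = 50,
    box_voxels: tuple[int, int, int] = (10, 10, 5),
    spacing: tuple[float, float, float] = (20.0, 20.0, 50.0),
) -> LabelVolume:
    """A label volume of ``n_regions`` equal boxes tiled on a grid.

    Each box is 10x10x5 voxels = 0.01 mm^3 at the default spacing —
    convenient equal-volume regions for count-level studies.
    """
    nx = int(np.ceil(np.sqrt(n_regions)))
    ny = int(np.ceil(n_regions / nx))
    bx, by, bz = box_voxels
    arr = np.zeros((nx * bx, ny * by, bz), dtype=np.int32)
    rid = 0
    for i in range(nx):
        for j in range(ny):
            if rid >= n_regions:
                break
            rid += 1
            arr[i * bx:(i + 1) * bx, j * by:(j + 1) * by, :] = rid
    nodes = [OntologyNode(997, "root", "root", None)] + [
        OntologyNode(r, f"R{r}", f"region {r}", 997) for r in range(1, n_regions + 1)
    ]
    return LabelVolume(Volume(arr, spacing), Ontology(nodes))


def dimorphism_screen(
    n_regions: int = 50,
    planted: tuple[int, ...] = (7, 31),
    fold: float = 2.0,
    density: float = 100_000.0,
    theta: float = 20.0,
    n_per_group: int = 5,
    n_replicates: int = 100,
    config: st.StatsConfig | None = None,
    seed: int = 0,
) -> dict:
    """Planted-dimorphism detection study at the regional-count level.

    Counts are generated exactly as the phantom cell model produces them:
    the 3D count per region is NB(density x volume, theta) — doubled in the
    planted regions for the male group — and the observed 2D count is a
    1/1.4 binomial thinning.  Each replicate runs the full NB + BH-FDR
    screen; reported are the fractions of replicates where every planted
    region is flagged at q < 0.05, where no null region is flagged, and
    where both hold (an exact recovery of the planted set).
    """
    config = config or st.StatsConfig()
    labels = grid_label_volume(n_regions)
    vox_mm3 = np.prod(labels.spacing) * 1e-9
    volumes = {r: c * vox_mm3 for r, c in labels.voxel_counts().items()}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1]))
    k3d = quantify.QuantConfig().k3d
    planted_set = set(planted)
    n_detected = n_clean = n_exact = 0
    for _ in range(n_replicates):
        rows = []
        for sex, lift in (("M", fold), ("F", 1.0)):
            for s in range(n_per_group):
                for rid, vol in volumes.items():
                    mu = density * vol * (lift if rid in planted_set else 1.0)
                    n3d = st._rnb(rng, mu, theta, 1)[0]
                    n2d = rng.binomial(n3d, 1.0 / k3d)
                    rows.append({"region_id": rid, "sex": sex, "subject": s,
                                 "n2d": int(n2d), "volume_mm3": vol})
        res = st.compare_regions(pd.DataFrame(rows), "sex", config=config)
        sig = set(res.loc[res["significant"], "region_id"])
        detected = planted_set <= sig
        clean = sig <= planted_set
        n_detected += detected
        n_clean += clean
        n_exact += detected and clean
    return {
        "detection_rate": n_detected / n_replicates,
        "fp_free_rate": n_clean / n_replicates,
        "exact_rate": n_exact / n_replicates,
    }


def density_recovery(spec: phantom.PhantomSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Spatial end-to-end recovery of generating densities for one subject.

    Simulates 3D cells on a deformed subject's ground-truth labels, thins
    them to 2D counts, assigns and quantifies, and compares each region's
    recovered density against its generating value in units of the NB +
    thinning standard error: ``Var(n3d_hat) = 1.4 mu + mu^2 / theta``.
    """
    spec = spec or phantom.default_spec(seed=seed)
    subj = phantom.make_phantom_series(spec, 1, 1)[0][0]
    cells3d = phantom.simulate_cells(subj.labels, spec, seed=seed + 1)
    cells = phantom.thin_cells(cells3d, seed=seed + 2)
    assigned = quantify.assign_cells(cells, subj.labels)
    stats = quantify.region_stats(assigned, subj.labels)
    rows = []
    for _, row in stats.iterrows():
        rid = int(row["region_id"])
        d_true = spec.densities.get(rid, 0.0)
        if d_true <= 0:
            continue
        mu = d_true * row["volume_mm3"]
        theta = spec.theta(rid)
        var_n3d = 1.4 * mu + (0.0 if np.isinf(theta) else mu**2 / theta)
        se_density = np.sqrt(var_n3d) / row["volume_mm3"]
        rows.append({
            "region_id": rid,
            "true_density": d_true,
            "recovered_density": row["density_mm3"],
            "z": (row["density_mm3"] - d_true) / se_density,
        })
    return pd.DataFrame(rows)


def registration_identity_dice(
    base: tuple[Volume, LabelVolume], config: reg.RegistrationConfig
) -> float:
    """Min per-region Dice after registering a volume to itself."""
    vol, labels = base
    t = reg.register(vol, vol, config)
    warped = reg.apply_to_labels(t, labels)
    return min(
        _dice(warped.data, labels.data, rid)
        for rid, c in labels.voxel_counts().items()
        if c >= 100
    )


def landmark_error_um(
    spec: phantom.PhantomSpec, config: reg.RegistrationConfig, n_points: int = 40,
    seed: int = 0,
) -> dict:
    """Mean/max landmark error of registration vs the ground-truth warp."""
    base_vol, _ = phantom.build_base(spec)
    subj = phantom.make_phantom_series(spec, 1, 1)[0][0]
    t = reg.register(subj.volume, base_vol, config)
    rng = np.random.default_rng(seed)
    lo = 0.25 * np.asarray(base_vol.shape) * np.asarray(base_vol.spacing)
    hi = 0.75 * np.asarray(base_vol.shape) * np.asarray(base_vol.spacing)
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    est = t.transform_points(pts)
    tru = subj.transform_to_base.transform_points(pts)
    err = np.linalg.norm(est - tru, axis=1)
    return {"mean_um": float(err.mean()), "max_um": float(err.max())}


def _two_stage_phantom(spec: phantom.PhantomSpec, stage_deformation_um: float, seed: int):
    """Base, middle = warp1(base), young = warp2(middle): a large two-step
    morphing where the middle age is the natural registration stepping stone."""
    base_vol, base_labels = phantom.build_base(spec)

    def stage(vol, labels, scale, stage_seed):
        sub_spec = dataclasses.replace(spec, deformation_um=stage_deformation_um,
                                       age_scales=(scale,), seed=stage_seed)
        t = phantom._random_subject_transform(sub_spec, vol, 0, 0)
        return (reg.apply_to_volume(t, vol), reg.apply_to_labels(t, labels))

    middle_vol, middle_labels = stage(base_vol, base_labels, 0.92, seed)
    young_vol, young_labels = stage(middle_vol, middle_labels, 0.9, seed + 1)
    return (base_vol, base_labels), (middle_vol, middle_labels), (young_vol, young_labels)


def sequential_vs_direct_dice(
    spec: phantom.PhantomSpec,
    config: reg.RegistrationConfig,
    stage_deformation_um: float = 70.0,
    seed: int = 0,
) -> dict:
    """Label propagation to a strongly morphed young brain, two routes.

    Direct: one registration base -> young.  Sequential: base -> middle ->
    young with composed transforms.  Returns the mean per-region Dice of
    each route against the young ground-truth labels.
    """
    (base_vol, base_labels), (mid_vol, _), (young_vol, young_labels) = _two_stage_phantom(
        spec, stage_deformation_um, seed
    )
    direct = templates.propagate_labels(base_labels, base_vol, young_vol, config=config)
    seq = templates.propagate_labels(base_labels, base_vol, young_vol, via=mid_vol,
                                     config=config)
    regions = [r for r, c in young_labels.voxel_counts().items() if c >= 50]
    d_direct = float(np.mean([_dice(direct.data, young_labels.data, r) for r in regions]))
    d_seq = float(np.mean([_dice(seq.data, young_labels.data, r) for r in regions]))
    return {"direct": d_direct, "sequential": d_seq}


def flatmap_uniformity(density: float = 4000.0, seed: int = 0) -> dict:
    """Uniform cortical field recovery on the phantom shell.

    Returns exact count conservation over bins and the worst per-bin
    deviation from the generating density in Poisson-thinning sigmas.
    """
    spec = phantom.default_spec(
        densities={rid: density for rid in phantom.LAYER_IDS.values()},
        dispersion=np.inf, seed=seed,
    )
    _, labels = phantom.build_base(spec)
    cells3d = phantom.simulate_cells(labels, spec, seed=seed + 1)
    cells = phantom.thin_cells(cells3d, seed=seed + 2)
    bins = flatmap_mod.shell_bins(labels, set(phantom.LAYER_IDS.values()),
                                  n_theta=6, n_phi=4)
    ident = reg.identity_transform(labels.volume)
    table = flatmap_mod.bin_densities(cells, bins, ident)
    vol = bins.bin_volume
    idx = vol.volume.point_to_voxel(cells[["x_um", "y_um", "z_um"]].to_numpy())
    in_bin = vol.data[idx[:, 0], idx[:, 1], idx[:, 2]] > 0
    conserved = int(table["n2d"].sum()) == int(in_bin.sum())
    k3d = quantify.QuantConfig().k3d
    worst = 0.0
    for _, row in table.iterrows():
        if row["volume_mm3"] <= 0:
            continue
        lam = density * row["volume_mm3"] / k3d
        worst = max(worst, abs(row["n2d"] - lam) / np.sqrt(lam))
    return {"count_conserved": conserved, "worst_bin_sigma": float(worst)}


def _dice(a: np.ndarray, b: np.ndarray, label: int) -> float:
    ma, mb = a == label, b == label
    denom = ma.sum() + mb.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(ma, mb).sum() / denom
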