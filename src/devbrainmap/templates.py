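"""Age-specific average templates and cross-age label propagation.

A template at one age is built the classic way: pick the best-imaged,
most left-right-symmetric subject as the registration reference, register
every cohort member to it, intensity-normalise, and take the voxelwise
mean.  Anatomical labels travel from an adult(-like) reference down the
age series by registration — directly when the morphology is similar, or
through an intermediate age (adult → P14 → P7 in the motivating workflow)
when the youngest brains are too dissimilar for a single hop.
"""

from __future__ import annotations

import numpy as np

from .io import LabelVolume, Volume
from .registration import (
    RegistrationConfig,
    RegistrationError,
    Transform,
    apply_to_labels,
    apply_to_volume,
    compose,
    register,
)

__all__ = ["symmetry_score", "build_template", "propagate_labels", "normalize_intensity"]


def symmetry_score(v: Volume) -> float:
    """Left-right symmetry as Pearson correlation with the mid-x mirror.

    1.0 means the volume equals its own mirror voxelwise; a volume equal to
    the negation of its mirror scores −1.0.  Raises on constant-intensity
    input, where correlation is undefined.
    """
    a = v.data.astype(np.float64).ravel()
    b = v.mirrored().data.astype(np.float64).ravel()
    if np.ptp(a) == 0:
        raise ValueError("symmetry score undefined for a constant-intensity volume")
    return float(np.corrcoef(a, b)[0, 1])


def normalize_intensity(v: Volume, low: float = 1.0, high: float = 99.0) -> Volume:
    """Rescale so the ``low``–``high`` percentile range maps to [0, 1].

    Robust to acquisition gain differences between subjects; values outside
    the percentile window are clipped.
    """
    lo, hi = np.percentile(v.data, [low, high])
    if hi <= lo:
        raise ValueError("cannot normalize: percentile range is empty")
    return v.with_data(np.clip((v.data.astype(np.float32) - lo) / (hi - lo), 0.0, 1.0))


def build_template(
    subjects: list[Volume],
    reference: Volume,
    config: RegistrationConfig | None = None,
) -> Volume:
    """Average template: register each subject to ``reference``, then mean.

    Every subject is registered to the reference, intensity-normalised to a
    matched 1st–99th percentile range, and the voxelwise arithmetic mean is
    returned on the reference grid (so the result is invariant to subject
    order).  A failed registration aborts with the failing subject index.
    """
    if len(subjects) < 2:
        raise ValueError("template construction needs at least 2 subjects")
    config = config or RegistrationConfig()
    ref_norm = normalize_intensity(reference)
    acc = np.zeros(reference.shape, dtype=np.float64)
    for i, subj in enumerate(subjects):
        try:
            t = register(reference, subj, config)
        except RegistrationError as e:
            raise RegistrationError(
                f"registration of subject {i} to the reference failed: {e}", e.metric_trace
            ) from e
        warped = apply_to_volume(t, normalize_intensity(subj), interpolation="linear")
        acc += warped.data.astype(np.float64)
    mean = (acc / len(subjects)).astype(np.float32)
    return Volume(mean, reference.spacing, reference.origin)


def propagate_labels(
    labels: LabelVolume,
    source_template: Volume,
    target_template: Volume,
    via: Volume | None = None,
    config: RegistrationConfig | None = None,
) -> LabelVolume:
    """Carry labels from ``source_template``'s grid onto ``target_template``.

    One registration when ``via`` is None; otherwise two registrations
    composed through the intermediate template (the sequential route used
    when source and target morphologies are too dissimilar for a direct
    hop).  Nearest-neighbour throughout, so no region absent from the
    input can appear in the output.
    """
    config = config or RegistrationConfig()
    if via is None:
        t = register(target_template, source_template, config)
    else:
        t_mid = register(via, source_template, config)  # via -> source
        t_tgt = register(target_template, via, config)  # target -> via
        t = compose(t_mid, t_tgt)
    return apply_to_labels(t, labels)
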