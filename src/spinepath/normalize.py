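"""Two-step spine normalization.

Inter-patient comparison of 3D spinal curves requires removing trunk-size
variation and aligning vertebral levels.  This is done in two steps:

1. **Isotropic scaling** — every coordinate of a spine is divided by the
   vertical chord z(T1) − z(L5) and the z axis is shifted so z(L5) = 0.
   The scaled spine has unit height; because the factor is the same in all
   three directions, shape (every inter-landmark ratio) is preserved.
2. **Resampling at a control template** — the 17 per-vertebra z-levels of
   the averaged scaled control (non-scoliotic) spines define a common
   vertical grid; each patient's (x, y) is linearly interpolated along z at
   those levels.  Afterwards all patients share identical z coordinates, so
   the curve is fully described by the 34-vector (x1..x17, y1..y17) used
   for clustering.

The (x, y) coordinates are deliberately *not* re-centred: frontal and
sagittal offsets of T1 relative to L5 (trunk imbalance, lateral shift) are
part of the shape signal that distinguishes clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import CentroidSpine, Timepoint, ValidationError, N_VERTEBRAE, VERTEBRAE

__all__ = [
    "ScaledSpine",
    "ControlTemplate",
    "NormalizedCurve",
    "scale_isotropic",
    "build_control_template",
    "resample_at_template",
    "normalize_cohort",
]

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class ScaledSpine:
    """A spine after isotropic scaling: dimensionless, unit height, z(L5) = 0."""

    patient_id: str
    timepoint: Timepoint
    coords: np.ndarray  # (17, 3), z strictly decreasing from 1 to 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        z = coords[:, 2]
        if abs(z[0] - 1.0) > _UNIT_TOL or abs(z[-1]) > _UNIT_TOL:
            raise ValidationError(
                f"{self.patient_id}/{self.timepoint.value}: scaled spine must "
                f"have z(T1)=1 and z(L5)=0, got {z[0]!r}, {z[-1]!r}"
            )
        if not np.all(np.diff(z) < 0):
            raise ValidationError(
                f"{self.patient_id}/{self.timepoint.value}: z not strictly decreasing"
            )

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]


@dataclass(frozen=True)
class ControlTemplate:
    """Per-vertebra z-levels of the average scaled control spine.

    17 strictly decreasing levels with endpoints exactly 1 (T1) and 0 (L5);
    patients are resampled at these levels so that all share a z grid.
    """

    z_levels: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_levels, dtype=float)
        object.__setattr__(self, "z_levels", z)
        if z.shape != (N_VERTEBRAE,):
            raise ValidationError(f"template must have {N_VERTEBRAE} levels")
        if z[0] != 1.0 or z[-1] != 0.0:
            raise ValidationError("template endpoints must be exactly 1 and 0")
        if not np.all(np.diff(z) < 0):
            raise ValidationError("template z-levels must be strictly decreasing")

    def to_dict(self) -> dict[str, float]:
        return {v: float(z) for v, z in zip(VERTEBRAE, self.z_levels)}


@dataclass(frozen=True)
class NormalizedCurve:
    """(x, y) of one spine evaluated at the 17 template z-levels.

    ``feature`` flattens the curve into the 34-vector
    (x1..x17, y1..y17) consumed by clustering.
    """

    patient_id: str
    timepoint: Timepoint
    xy: np.ndarray  # (17, 2)

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        if xy.shape != (N_VERTEBRAE, 2):
            raise ValidationError(
                f"{self.patient_id}: expected ({N_VERTEBRAE}, 2) xy, got {xy.shape}"
            )
        if not np.all(np.isfinite(xy)):
            raise ValidationError(f"{self.patient_id}: non-finite normalized curve")

    @property
    def feature(self) -> np.ndarray:
        """34-element feature vector (all x, then all y)."""
        return np.concatenate([self.xy[:, 0], self.xy[:, 1]])


def scale_isotropic(spine: CentroidSpine | ScaledSpine) -> ScaledSpine:
    """Scale a spine isotropically to unit height and anchor z(L5) at 0.

    All three coordinates are divided by the same factor z(T1) − z(L5), so
    the operation preserves shape; x and y are not translated.  Idempotent:
    a unit-height spine with z(L5) = 0 is returned unchanged (up to exact
    float division).
    """
    coords = np.asarray(spine.coords, dtype=float)
    z = coords[:, 2]
    height = z[0] - z[-1]
    if height <= 0:
        raise ValidationError(
            f"{spine.patient_id}: non-positive spinal height {height:g}"
        )
    scaled = coords / height
    scaled[:, 2] -= scaled[-1, 2]  # z(L5) -> 0
    scaled[0, 2] = 1.0  # guard rounding; |error| < 1 ulp by construction
    scaled[-1, 2] = 0.0
    return ScaledSpine(
        patient_id=spine.patient_id, timepoint=spine.timepoint, coords=scaled
    )


def build_control_template(controls: Sequence[ScaledSpine]) -> ControlTemplate:
    """Average the z-levels of scaled control spines into a resampling template."""
    if len(controls) == 0:
        raise ValidationError("cannot build a template from zero control spines")
    z = np.mean([c.z for c in controls], axis=0)
    # endpoints are means of exact 1s and 0s
    z[0], z[-1] = 1.0, 0.0
    if not np.all(np.diff(z) < 0):
        raise ValidationError("mean control z-levels are not strictly decreasing")
    return ControlTemplate(z_levels=z)


def resample_at_template(
    spine: ScaledSpine, template: ControlTemplate
) -> NormalizedCurve:
    """Evaluate a scaled spine's (x, y) at the template z-levels.

    x(z) and y(z) are piecewise-linear between adjacent centroids (no
    smoothing), so a spine whose z-levels coincide with the template is
    returned exactly, and any coordinate linear in z is reproduced to
    machine precision.
    """
    z = spine.z
    if not np.all(np.diff(z) < 0):
        raise ValidationError(f"{spine.patient_id}: z not strictly decreasing")
    # np.interp wants increasing abscissae
    z_inc = z[::-1]
    x = np.interp(template.z_levels, z_inc, spine.x[::-1])
    y = np.interp(template.z_levels, z_inc, spine.y[::-1])
    return NormalizedCurve(
        patient_id=spine.patient_id,
        timepoint=spine.timepoint,
        xy=np.column_stack([x, y]),
    )


def normalize_cohort(
    patients: Iterable[CentroidSpine], controls: Iterable[CentroidSpine]
) -> tuple[list[NormalizedCurve], ControlTemplate]:
    """Full two-step normalization of a patient cohort against its controls."""
    scaled_controls = [scale_isotropic(c) for c in controls]
    template = build_control_template(scaled_controls)
    curves = [
        resample_at_template(scale_isotropic(p), template) for p in patients
    ]
    return curves, template
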