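"""Domain types and file I/O for 3D vertebral-centroid landmark data.

A spine is represented by the 3D centroids of the 17 vertebrae T1-L5,
recorded at up to three timepoints around posterior spinal fusion surgery:
pre-operative (PO), early post-operative (EP, within about a month) and
two-year follow-up (Y2).  Non-scoliotic reference spines carry the
CONTROL timepoint.

Coordinate convention (applied consistently throughout the package):

* x — frontal/lateral axis, millimetres, positive toward the patient's left
* y — sagittal axis, millimetres, positive anterior
* z — vertical axis, millimetres, positive cranial

so z decreases strictly from T1 down to L5.

Landmark files are long-format CSV with one row per vertebra
(``patient_id,timepoint,vertebra,x_mm,y_mm,z_mm``); fusion files carry one
row per patient (``patient_id,uiv,liv``) naming the upper and lower
instrumented vertebrae.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VERTEBRAE",
    "VERTEBRA_INDEX",
    "Timepoint",
    "ValidationError",
    "CentroidSpine",
    "FusionAssignment",
    "read_landmarks",
    "write_landmarks",
    "read_fusions",
    "write_fusions",
]

#: Anatomical order of the 17 landmark vertebrae, cranial to caudal.
VERTEBRAE: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)

#: Label -> position in the anatomical order (T1 = 0 ... L5 = 16).
VERTEBRA_INDEX: dict[str, int] = {v: i for i, v in enumerate(VERTEBRAE)}

N_VERTEBRAE = len(VERTEBRAE)


class Timepoint(str, Enum):
    """Acquisition timepoint of a spine."""

    PO = "PO"  # pre-operative
    EP = "EP"  # early post-operative
    Y2 = "Y2"  # two-year follow-up
    CONTROL = "CONTROL"  # non-scoliotic reference

    @classmethod
    def parse(cls, token: str) -> "Timepoint":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                f"unknown timepoint token {token!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


class ValidationError(ValueError):
    """An input record violates a structural invariant."""


@dataclass(frozen=True)
class CentroidSpine:
    """One patient/timepoint's 17 vertebral centroids in millimetres.

    ``coords`` is a (17, 3) array of (x, y, z) rows in the fixed anatomical
    order T1..L5; z must be strictly decreasing and all coordinates finite.
    """

    patient_id: str
    timepoint: Timepoint
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (N_VERTEBRAE, 3):
            raise ValidationError(
                f"{self.patient_id}/{self.timepoint.value}: expected "
                f"({N_VERTEBRAE}, 3) coordinates, got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(
                f"{self.patient_id}/{self.timepoint.value}: non-finite coordinates"
            )
        z = coords[:, 2]
        if not np.all(np.diff(z) < 0):
            bad = int(np.flatnonzero(np.diff(z) >= 0)[0])
            raise ValidationError(
                f"{self.patient_id}/{self.timepoint.value}: z not strictly "
                f"decreasing between {VERTEBRAE[bad]} (z={z[bad]:g}) and "
                f"{VERTEBRAE[bad + 1]} (z={z[bad + 1]:g})"
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

    @property
    def height(self) -> float:
        """Vertical chord z(T1) - z(L5)."""
        return float(self.z[0] - self.z[-1])


@dataclass(frozen=True)
class FusionAssignment:
    """The instrumented segment of one patient: (UIV, LIV) pair.

    UIV/LIV are the uppermost/lowermost instrumented vertebrae; the UIV must
    be strictly cranial to the LIV.  ``group_id`` is filled in by fusion
    grouping (see :mod:`spinepath.paths`); ``None`` means unassigned.
    """

    patient_id: str
    uiv: str
    liv: str
    group_id: int | None = None

    def __post_init__(self) -> None:
        for label in (self.uiv, self.liv):
            if label not in VERTEBRA_INDEX:
                raise ValidationError(
                    f"{self.patient_id}: unknown vertebral label {label!r}"
                )
        if VERTEBRA_INDEX[self.uiv] >= VERTEBRA_INDEX[self.liv]:
            raise ValidationError(
                f"{self.patient_id}: UIV {self.uiv} is not strictly cranial "
                f"to LIV {self.liv}"
            )

    @property
    def level(self) -> tuple[str, str]:
        return (self.uiv, self.liv)


LANDMARK_COLUMNS = ["patient_id", "timepoint", "vertebra", "x_mm", "y_mm", "z_mm"]
FUSION_COLUMNS = ["patient_id", "uiv", "liv"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_landmarks(path: str | Path) -> list[CentroidSpine]:
    """Read a long-format landmark CSV into validated :class:`CentroidSpine` objects.

    One spine is produced per (patient_id, timepoint) pair, in order of first
    appearance in the file.  Missing or duplicated vertebrae, unknown labels
    and non-monotone z all raise :class:`ValidationError` naming the
    offending record.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "timepoint": str, "vertebra": str},
        float_precision="round_trip",
    )
    _require_columns(df, LANDMARK_COLUMNS, path)

    spines: list[CentroidSpine] = []
    for (pid, tp_token), group in df.groupby(
        ["patient_id", "timepoint"], sort=False
    ):
        tp = Timepoint.parse(str(tp_token))
        seen = set(group["vertebra"])
        unknown = seen - set(VERTEBRAE)
        if unknown:
            raise ValidationError(
                f"{pid}/{tp.value}: unknown vertebra label(s) {sorted(unknown)}"
            )
        if len(group) != len(seen):
            dup = group["vertebra"][group["vertebra"].duplicated()].iloc[0]
            raise ValidationError(f"{pid}/{tp.value}: duplicate vertebra {dup}")
        missing = [v for v in VERTEBRAE if v not in seen]
        if missing:
            raise ValidationError(
                f"{pid}/{tp.value}: missing vertebra(e) {missing}"
            )
        ordered = group.set_index("vertebra").loc[list(VERTEBRAE)]
        coords = ordered[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        spines.append(CentroidSpine(patient_id=str(pid), timepoint=tp, coords=coords))
    return spines


def write_landmarks(spines: Iterable[CentroidSpine], path: str | Path) -> None:
    """Write spines to landmark CSV; floats use repr precision so that
    ``read_landmarks(write_landmarks(...))`` reproduces coordinates bit-exactly."""
    rows = []
    for spine in spines:
        for i, vertebra in enumerate(VERTEBRAE):
            x, y, z = spine.coords[i]
            rows.append(
                {
                    "patient_id": spine.patient_id,
                    "timepoint": spine.timepoint.value,
                    "vertebra": vertebra,
                    "x_mm": x,
                    "y_mm": y,
                    "z_mm": z,
                }
            )
    # %.17g guarantees float64 round-trips exactly through the text file
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_fusions(path: str | Path) -> list[FusionAssignment]:
    """Read a fusion CSV (``patient_id,uiv,liv``) into validated assignments."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, FUSION_COLUMNS, path)
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate fusion record for patient {dup}")
    return [
        FusionAssignment(patient_id=row.patient_id, uiv=row.uiv, liv=row.liv)
        for row in df.itertuples(index=False)
    ]


def write_fusions(fusions: Iterable[FusionAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": f.patient_id, "uiv": f.uiv, "liv": f.liv} for f in fusions],
        columns=FUSION_COLUMNS,
    ).to_csv(path, index=False)
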