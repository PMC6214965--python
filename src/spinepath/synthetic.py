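"""Parametric generator of synthetic scoliotic and control cohorts.

No public landmark dataset accompanies the clinical cohort this package is
designed around, so every pipeline stage is exercised on simulated spines
with *planted* structure:

* each timepoint has a small set of cluster templates — smooth frontal and
  sagittal curve shapes built from Gaussian lobes in the unit-height z
  coordinate, mimicking the qualitative cluster morphologies seen
  clinically (single thoracic lobe vs. S-shaped double lobe, lateral trunk
  shift, hypo-/hyper-kyphosis, proximal kyphosis; post-operative templates
  have strongly reduced frontal amplitude);
* patients are assigned a pre-operative (PO) cluster, an early
  post-operative (EP) cluster and a fusion level; isotropic size is
  re-introduced by sampling a spinal height and multiplying, and Gaussian
  noise (unit-height scale) perturbs x and y;
* the two-year (2Y) cluster is *planted* through a deterministic
  path -> outcome map followed with probability ``fidelity`` (otherwise a
  different 2Y cluster is drawn uniformly), so path concordance has a known
  expected value.

Defaults mirror the clinical study design: 67 surgical patients (three of
whom fall in under-sized fusion groups and are later excluded), 20
controls, 3 PO / 2 EP / 3 2Y clusters, fusion-level frequencies matching
the published cohort, within-cluster noise SD 0.02 (unit-height scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CentroidSpine,
    FusionAssignment,
    Timepoint,
    VERTEBRAE,
    N_VERTEBRAE,
    write_fusions,
    write_landmarks,
)

__all__ = [
    "Lobe",
    "ClusterTemplate",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_control",
    "generate_scoliotic",
    "generate_cohort",
    "default_outcome_map",
]

#: Equally spaced unit-height z grid, T1 = 1 down to L5 = 0.
_Z_GRID = np.linspace(1.0, 0.0, N_VERTEBRAE)


@dataclass(frozen=True)
class Lobe:
    """One Gaussian bump: amplitude * exp(-(z - center)^2 / (2 width^2))."""

    amplitude: float
    center: float
    width: float

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((z - self.center) ** 2) / (2.0 * self.width**2))


@dataclass(frozen=True)
class ClusterTemplate:
    """Noise-free curve shape of one cluster, in unit-height coordinates.

    ``x_lobes`` build the frontal curve (main thoracic lobe plus optional
    proximal/lumbar counter-lobes), ``x_offset`` adds a constant lateral
    trunk shift; ``y_lobes``/``y_offset`` build the sagittal profile
    (negative amplitudes = posterior/kyphotic, positive = anterior/lordotic).
    """

    name: str
    x_lobes: tuple[Lobe, ...] = ()
    y_lobes: tuple[Lobe, ...] = ()
    x_offset: float = 0.0
    y_offset: float = 0.0

    def evaluate(self, z: np.ndarray | None = None) -> np.ndarray:
        """(len(z), 3) noise-free unit-height curve."""
        z = _Z_GRID if z is None else np.asarray(z, dtype=float)
        x = np.full_like(z, self.x_offset)
        y = np.full_like(z, self.y_offset)
        for lobe in self.x_lobes:
            x = x + lobe(z)
        for lobe in self.y_lobes:
            y = y + lobe(z)
        return np.column_stack([x, y, z])

    @property
    def feature(self) -> np.ndarray:
        """Noise-free 34-vector (x1..x17, y1..y17) on the standard grid."""
        xyz = self.evaluate()
        return np.concatenate([xyz[:, 0], xyz[:, 1]])


# ---------------------------------------------------------------------------
# default templates
# ---------------------------------------------------------------------------

_CONTROL_TEMPLATE = ClusterTemplate(
    name="control",
    y_lobes=(Lobe(-0.060, 0.70, 0.16), Lobe(0.050, 0.14, 0.11)),
)

# Pre-operative morphologies: a single right-thoracic lobe (balanced,
# hypokyphotic), a laterally shifted thoracic curve, and an S-shaped
# thoracolumbar double curve with proximal kyphosis.
_PO_TEMPLATES = (
    ClusterTemplate(
        name="PO1",
        x_lobes=(Lobe(0.200, 0.55, 0.14), Lobe(-0.040, 0.14, 0.10)),
        y_lobes=(Lobe(-0.020, 0.70, 0.17), Lobe(0.045, 0.12, 0.10)),
    ),
    ClusterTemplate(
        name="PO2",
        x_lobes=(Lobe(0.160, 0.50, 0.15),),
        x_offset=0.110,
        y_lobes=(Lobe(-0.075, 0.72, 0.16), Lobe(0.055, 0.13, 0.10)),
    ),
    ClusterTemplate(
        name="PO3",
        x_lobes=(Lobe(0.110, 0.60, 0.11), Lobe(-0.170, 0.18, 0.11)),
        y_lobes=(
            Lobe(-0.095, 0.72, 0.15),
            Lobe(0.070, 0.14, 0.10),
            Lobe(-0.060, 0.95, 0.06),
        ),
    ),
)

# Early post-operative: corrected curves (much smaller frontal amplitude);
# one laterally shifted and sagittally flat, one balanced with restored
# kyphosis and proximal kyphosis.
_EP_TEMPLATES = (
    ClusterTemplate(
        name="EP1",
        x_lobes=(Lobe(0.050, 0.55, 0.15),),
        x_offset=0.090,
        y_lobes=(Lobe(-0.015, 0.70, 0.18),),
    ),
    ClusterTemplate(
        name="EP2",
        x_lobes=(Lobe(0.040, 0.55, 0.15),),
        y_lobes=(
            Lobe(-0.080, 0.70, 0.16),
            Lobe(0.060, 0.14, 0.10),
            Lobe(-0.035, 0.95, 0.06),
        ),
    ),
)

# Two-year outcomes: hyperkyphotic with backward shift, well-balanced, and
# sagittally flat with residual frontal deformity.
_Y2_TEMPLATES = (
    ClusterTemplate(
        name="2Y1",
        x_lobes=(Lobe(0.050, 0.55, 0.15),),
        x_offset=0.055,
        y_lobes=(Lobe(-0.115, 0.68, 0.17),),
        y_offset=-0.030,
    ),
    ClusterTemplate(
        name="2Y2",
        x_lobes=(Lobe(0.035, 0.55, 0.15),),
        y_lobes=(Lobe(-0.070, 0.70, 0.16), Lobe(0.055, 0.14, 0.10)),
    ),
    ClusterTemplate(
        name="2Y3",
        x_lobes=(Lobe(0.085, 0.55, 0.14), Lobe(-0.070, 0.16, 0.10)),
        x_offset=-0.075,
        y_lobes=(Lobe(-0.010, 0.70, 0.18),),
    ),
)

#: Fusion levels (UIV, LIV) with cohort frequencies; the two smallest
#: levels are the ones eliminated by the minimum-group-size filter.
DEFAULT_FUSION_LEVELS: tuple[tuple[tuple[str, str], int], ...] = (
    (("T2", "T12"), 8),
    (("T3", "T12"), 10),
    (("T4", "T12"), 14),
    (("T2", "L1"), 12),
    (("T3", "L1"), 8),
    (("T4", "L1"), 12),
    (("T3", "T11"), 2),
    (("T2", "T10"), 1),
)


def default_outcome_map(
    n_po: int = 3, n_ep: int = 2, n_fusion: int = 8, n_y2: int = 3
) -> dict[tuple[int, int, int], int]:
    """Deterministic planted path -> 2Y-cluster map over all triples.

    The outcome is an interval bucket of the additive score po + ep + f:
    the lowest-scoring paths end in cluster 1, intermediate ones in
    cluster 2, the highest in cluster 3.  An additive rule is used (rather
    than, say, a modular one) so the planted association has main-effect
    structure that a multinomial logit can express; the cut points spread
    the 2Y clusters over all outcome levels under the default cohort
    composition.
    """
    lo = 3  # minimum score: po = ep = f = 1
    hi = n_po + n_ep + n_fusion
    cuts = np.quantile(np.arange(lo, hi + 1), np.linspace(0, 1, n_y2 + 1)[1:-1])
    out = {}
    for po in range(1, n_po + 1):
        for ep in range(1, n_ep + 1):
            for f in range(1, n_fusion + 1):
                s = po + ep + f
                out[(po, ep, f)] = 1 + int(np.sum(s > cuts))
    return out


def _largest_remainder(weights: Sequence[float], total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """All parameters of a synthetic cohort; defaults mirror the study design."""

    seed: int = 0
    n_patients: int = 67
    n_controls: int = 20
    po_templates: tuple[ClusterTemplate, ...] = _PO_TEMPLATES
    ep_templates: tuple[ClusterTemplate, ...] = _EP_TEMPLATES
    y2_templates: tuple[ClusterTemplate, ...] = _Y2_TEMPLATES
    control_template: ClusterTemplate = _CONTROL_TEMPLATE
    po_weights: tuple[float, ...] = (24, 21, 19)
    ep_weights: tuple[float, ...] = (41, 23)
    fusion_levels: tuple[tuple[tuple[str, str], int], ...] = DEFAULT_FUSION_LEVELS
    outcome_map: Mapping[tuple[int, int, int], int] | None = None
    fidelity: float = 0.8
    noise_sd: float = 0.02
    control_noise_sd: float = 0.01
    height_range: tuple[float, float] = (380.0, 480.0)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 < self.fidelity <= 1.0:
            raise ValueError("fidelity must be in (0, 1]")
        if self.noise_sd < 0 or self.control_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if len(self.po_weights) != len(self.po_templates):
            raise ValueError("po_weights must match po_templates")
        if len(self.ep_weights) != len(self.ep_templates):
            raise ValueError("ep_weights must match ep_templates")
        for tmpl in (
            *self.po_templates,
            *self.ep_templates,
            *self.y2_templates,
            self.control_template,
        ):
            z = tmpl.evaluate()[:, 2]
            if not np.all(np.diff(z) < 0):
                raise ValueError(f"template {tmpl.name}: non-monotone z")

    def resolved_outcome_map(self) -> Mapping[tuple[int, int, int], int]:
        if self.outcome_map is not None:
            return self.outcome_map
        return default_outcome_map(
            len(self.po_templates),
            len(self.ep_templates),
            len(self.fusion_levels),
            len(self.y2_templates),
        )

    def template_separations(self) -> dict[str, float]:
        """Minimum pairwise center distance (34-D feature space) per timepoint."""
        out = {}
        for key, templates in (
            ("PO", self.po_templates),
            ("EP", self.ep_templates),
            ("2Y", self.y2_templates),
        ):
            feats = np.stack([t.feature for t in templates])
            dists = [
                float(np.linalg.norm(feats[i] - feats[j]))
                for i in range(len(feats))
                for j in range(i + 1, len(feats))
            ]
            out[key] = min(dists)
        return out


def _emit_spine(
    template: ClusterTemplate,
    patient_id: str,
    timepoint: Timepoint,
    noise_sd: float,
    height: float,
    rng: np.random.Generator,
) -> CentroidSpine:
    """Template + Gaussian x/y noise, scaled to the sampled height in mm."""
    coords = template.evaluate().copy()
    if noise_sd > 0:
        coords[:, :2] += rng.normal(0.0, noise_sd, size=(N_VERTEBRAE, 2))
    coords *= height
    return CentroidSpine(patient_id=patient_id, timepoint=timepoint, coords=coords)


def generate_control(
    spec: SyntheticCohortSpec, rng: np.random.Generator, patient_id: str = "ctrl"
) -> CentroidSpine:
    """One non-scoliotic spine: straight frontally, kyphosis/lordosis sagittally."""
    height = rng.uniform(*spec.height_range)
    return _emit_spine(
        spec.control_template,
        patient_id,
        Timepoint.CONTROL,
        spec.control_noise_sd,
        height,
        rng,
    )


def generate_scoliotic(
    spec: SyntheticCohortSpec,
    cluster_id: int,
    timepoint: Timepoint,
    rng: np.random.Generator,
    patient_id: str = "pt",
) -> CentroidSpine:
    """One scoliotic spine drawn from the given cluster's template."""
    templates = {
        Timepoint.PO: spec.po_templates,
        Timepoint.EP: spec.ep_templates,
        Timepoint.Y2: spec.y2_templates,
    }[timepoint]
    if not 1 <= cluster_id <= len(templates):
        raise ValueError(f"cluster_id {cluster_id} out of range for {timepoint}")
    height = rng.uniform(*spec.height_range)
    return _emit_spine(
        templates[cluster_id - 1], patient_id, timepoint, spec.noise_sd, height, rng
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: spines, fusion assignments and planted ground truth.

    ``ground_truth`` has one row per patient with the planted PO/EP/2Y
    clusters, the fusion level, the planted (map) outcome, and whether the
    emitted 2Y cluster followed the map (``followed_map``).
    ``passthrough`` carries simulated image-only attributes (apical
    rotations, pelvic parameters) keyed by patient for Table-1-style
    comparisons; they are not derived from the landmark geometry.
    """

    spec: SyntheticCohortSpec
    spines: tuple[CentroidSpine, ...]
    controls: tuple[CentroidSpine, ...]
    fusions: tuple[FusionAssignment, ...]
    ground_truth: pd.DataFrame
    passthrough: pd.DataFrame

    def patient_spines(self, timepoint: Timepoint) -> list[CentroidSpine]:
        return [s for s in self.spines if s.timepoint == timepoint]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write landmark/fusion CSVs and ground-truth JSON; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "landmarks": out / "landmarks.csv",
            "controls": out / "controls.csv",
            "fusions": out / "fusions.csv",
            "ground_truth": out / "ground_truth.json",
            "passthrough": out / "passthrough.csv",
        }
        write_landmarks(self.spines, files["landmarks"])
        write_landmarks(self.controls, files["controls"])
        write_fusions(self.fusions, files["fusions"])
        self.ground_truth.to_json(files["ground_truth"], orient="records", indent=2)
        self.passthrough.to_csv(files["passthrough"])
        return files


def generate_cohort(
    spec: SyntheticCohortSpec | None = None, seed: int | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort; byte-reproducible from the seed.

    Cluster and fusion-level *compositions* are deterministic (largest-
    remainder apportionment of the spec weights); which patient lands where
    is randomized.  The emitted 2Y cluster follows the planted outcome map
    with probability ``spec.fidelity``, otherwise a different cluster is
    drawn uniformly.
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    pids = [f"p{i + 1:03d}" for i in range(n)]

    po = np.repeat(
        np.arange(1, len(spec.po_weights) + 1),
        _largest_remainder(spec.po_weights, n),
    )
    ep = np.repeat(
        np.arange(1, len(spec.ep_weights) + 1),
        _largest_remainder(spec.ep_weights, n),
    )
    fusion_idx = np.repeat(
        np.arange(1, len(spec.fusion_levels) + 1),
        _largest_remainder([w for _, w in spec.fusion_levels], n),
    )
    rng.shuffle(po)
    rng.shuffle(ep)
    rng.shuffle(fusion_idx)

    outcome_map = spec.resolved_outcome_map()
    n_y2 = len(spec.y2_templates)
    planted = np.array([outcome_map[(p, e, f)] for p, e, f in zip(po, ep, fusion_idx)])
    follow = rng.random(n) < spec.fidelity
    y2 = planted.copy()
    for i in np.flatnonzero(~follow):
        others = [c for c in range(1, n_y2 + 1) if c != planted[i]]
        y2[i] = others[rng.integers(len(others))]

    spines: list[CentroidSpine] = []
    fusions: list[FusionAssignment] = []
    records = []
    for i, pid in enumerate(pids):
        spines.append(generate_scoliotic(spec, int(po[i]), Timepoint.PO, rng, pid))
        spines.append(generate_scoliotic(spec, int(ep[i]), Timepoint.EP, rng, pid))
        spines.append(generate_scoliotic(spec, int(y2[i]), Timepoint.Y2, rng, pid))
        (uiv, liv), _ = spec.fusion_levels[int(fusion_idx[i]) - 1]
        fusions.append(FusionAssignment(patient_id=pid, uiv=uiv, liv=liv))
        records.append(
            {
                "patient_id": pid,
                "po_cluster": int(po[i]),
                "ep_cluster": int(ep[i]),
                "y2_cluster": int(y2[i]),
                "fusion_level_idx": int(fusion_idx[i]),
                "uiv": uiv,
                "liv": liv,
                "planted_outcome": int(planted[i]),
                "followed_map": bool(follow[i]),
            }
        )
    controls = [
        generate_control(spec, rng, patient_id=f"c{i + 1:03d}")
        for i in range(spec.n_controls)
    ]

    # simulated image-only attributes, cluster-shifted so that Table-1-style
    # comparisons have signal to find
    passthrough = pd.DataFrame(
        {
            "PTR": rng.normal(-1.5 * po, 1.5),
            "MTR": rng.normal(-8.0 - 2.0 * po, 4.0),
            "LR": rng.normal(5.0 + 1.5 * po, 3.0),
            "PI": rng.normal(50.0, 12.0, size=n),
            "SS": rng.normal(42.0, 9.0, size=n),
            "PT": rng.normal(7.0, 7.0, size=n),
        },
        index=pd.Index(pids, name="patient_id"),
    )

    return SyntheticCohort(
        spec=spec,
        spines=tuple(spines),
        controls=tuple(controls),
        fusions=tuple(fusions),
        ground_truth=pd.DataFrame(records).set_index("patient_id"),
        passthrough=passthrough,
    )
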