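"""Centroid-curve surrogates of clinical spine measurements and the
between-cluster comparison pipeline.

Clinical practice quantifies a scoliotic spine on radiographs: Cobb angles
in the frontal plane (proximal thoracic, main thoracic, lumbar), kyphosis
and lordosis in the sagittal plane, and trunk balance offsets.  Those
definitions need vertebral endplates and pelvic landmarks that a centroid
curve does not carry, so this module computes *surrogates* from the
centroid polyline alone:

* angle surrogates — the spread of tangent directions of the curve
  projected onto a plane, over a vertebral span (a Cobb-like maximal
  tilt-difference, in degrees);
* balance offsets — the T1-minus-L5 offset in x (frontal balance) and
  y (sagittal balance), in input units.

Image-derived quantities (apical rotations, pelvic incidence/tilt, sacral
slope) cannot be computed from centroids and are accepted only as optional
pass-through columns so that the comparison pipeline can still exercise
them.  The lordosis surrogate spans L1-L5 because the landmark set ends at
L5 (no sacrum).

Cluster comparison follows the usual decision rule: Shapiro-Wilk normality
within every cluster; if all clusters pass at alpha, one-way ANOVA with
Tukey's HSD post-hoc, otherwise Kruskal-Wallis with Dunn's post-hoc
(uncorrected by default, Bonferroni optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CentroidSpine, ValidationError, VERTEBRA_INDEX
from .normalize import NormalizedCurve, ScaledSpine

__all__ = [
    "DEFAULT_SPANS",
    "tangent_angle_measure",
    "balance_offsets",
    "measure_spine",
    "VariableComparison",
    "ClusterComparison",
    "compare_clusters",
]

#: Vertebral spans of the standard angle surrogates.
DEFAULT_SPANS: dict[str, tuple[str, str, str]] = {
    # name: (plane, from, to)
    "PTC": ("frontal", "T1", "T5"),
    "MTC": ("frontal", "T5", "T12"),
    "LC": ("frontal", "T12", "L5"),
    "TK_T1_T12": ("sagittal", "T1", "T12"),
    "TK_T4_T12": ("sagittal", "T4", "T12"),
    "LL_L1_L5": ("sagittal", "L1", "L5"),
}

_PLANE_AXIS = {"frontal": 0, "sagittal": 1}


def _curve_arrays(curve: CentroidSpine | ScaledSpine | NormalizedCurve):
    if isinstance(curve, NormalizedCurve):
        xy = curve.xy
        z = np.linspace(1.0, 0.0, xy.shape[0])
        return xy[:, 0], xy[:, 1], z
    return curve.x, curve.y, curve.z


def tangent_angle_measure(
    curve: CentroidSpine | ScaledSpine | NormalizedCurve,
    plane: str,
    span: tuple[str, str],
) -> float:
    """Cobb-like angle surrogate: spread of tangent directions, in degrees.

    The curve is projected onto the requested plane (frontal: x-z,
    sagittal: y-z); the tangent direction at each vertebra is estimated by
    central differences along z (one-sided at the span ends) and expressed
    as the angle from the vertical axis.  The measure is the absolute
    difference between the maximal and minimal tangent angle within the
    span.  It is invariant to rigid translation and isotropic scaling.
    """
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be 'frontal' or 'sagittal', got {plane!r}")
    lo, hi = VERTEBRA_INDEX[span[0]], VERTEBRA_INDEX[span[1]]
    if lo > hi:
        lo, hi = hi, lo
    if hi - lo + 1 < 3:
        raise ValidationError(f"span {span} contains fewer than 3 vertebrae")
    x, y, z = _curve_arrays(curve)
    coord = (x, y)[_PLANE_AXIS[plane]][lo : hi + 1]
    zz = z[lo : hi + 1]
    slope = np.gradient(coord, zz, edge_order=2)  # d(coord)/dz, one-sided at ends
    angles = np.degrees(np.arctan(slope))
    return float(np.max(angles) - np.min(angles))


def balance_offsets(
    spine: CentroidSpine | ScaledSpine | NormalizedCurve,
) -> tuple[float, float]:
    """(frontal, sagittal) balance: T1 offset relative to L5, input units."""
    x, y, _ = _curve_arrays(spine)
    return float(x[0] - x[-1]), float(y[0] - y[-1])


def measure_spine(
    spine: CentroidSpine | ScaledSpine | NormalizedCurve,
    passthrough: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """All standard surrogate measurements of one spine as a flat dict.

    ``passthrough`` supplies image-derived attributes (e.g. apical
    rotations PTR/MTR/LR, pelvic PI/SS/PT) that are carried along untouched.
    """
    out = {
        name: tangent_angle_measure(spine, plane, (a, b))
        for name, (plane, a, b) in DEFAULT_SPANS.items()
    }
    fb, sb = balance_offsets(spine)
    out["FB"] = fb
    out["SB"] = sb
    if passthrough:
        for key, value in passthrough.items():
            if key in out:
                raise ValidationError(f"pass-through column {key!r} shadows a measure")
            out[key] = float(value)
    return out


@dataclass(frozen=True)
class VariableComparison:
    """Between-cluster comparison of one measured variable."""

    variable: str
    normal: bool  # every cluster passed Shapiro-Wilk at alpha
    test: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    significant: bool
    pairwise: pd.DataFrame  # columns: cluster_a, cluster_b, p_value, significant
    group_means: dict[int, float]
    group_sds: dict[int, float]


@dataclass(frozen=True)
class ClusterComparison:
    """Per-variable comparison results across clusters at one timepoint."""

    alpha: float
    variables: tuple[VariableComparison, ...]

    def __getitem__(self, name: str) -> VariableComparison:
        for v in self.variables:
            if v.variable == name:
                return v
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """Summary table: per cluster mean +/- SD, omnibus test and p-value."""
        rows = []
        for v in self.variables:
            row = {"variable": v.variable, "test": v.test, "p_value": v.p_value}
            for c in sorted(v.group_means):
                row[f"cluster{c}"] = f"{v.group_means[c]:.1f} ± {v.group_sds[c]:.1f}"
            rows.append(row)
        return pd.DataFrame(rows)


def _dunn_posthoc(
    values: Sequence[np.ndarray], labels: Sequence[int], correction: str | None
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z-tests with tie correction."""
    pooled = np.concatenate(values)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start : start + len(v)].mean())
        sizes.append(len(v))
        start += len(v)
    rows = []
    m = len(values)
    n_pairs = m * (m - 1) // 2
    for i in range(m):
        for j in range(i + 1, m):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            zstat = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(zstat))
            if correction == "bonferroni":
                p = min(1.0, p * n_pairs)
            rows.append(
                {"cluster_a": labels[i], "cluster_b": labels[j], "p_value": p}
            )
    return pd.DataFrame(rows)


def compare_clusters(
    measures: pd.DataFrame,
    labels: Mapping[str, int] | Sequence[int],
    alpha: float = 0.05,
    min_cluster_n: int = 3,
    posthoc_correction: str | None = None,
) -> ClusterComparison:
    """Compare every measured variable between clusters.

    Parameters
    ----------
    measures : DataFrame
        One row per patient (index = patient id), one numeric column per
        variable.
    labels : mapping or sequence
        Cluster label per patient (mapping keyed like the index, or a
        sequence aligned with it).
    alpha : float
        Significance level for normality, omnibus and pairwise tests.
    posthoc_correction : {None, "bonferroni"}
        Multiplicity correction of Dunn's pairwise p-values.

    For each variable: Shapiro-Wilk within every cluster; if all pass at
    ``alpha``, one-way ANOVA with Tukey HSD, otherwise Kruskal-Wallis with
    Dunn's test.
    """
    if isinstance(labels, Mapping):
        lab = np.asarray([labels[pid] for pid in measures.index])
    else:
        lab = np.asarray(list(labels))
        if len(lab) != len(measures):
            raise ValidationError("labels length does not match measures")
    clusters = sorted(np.unique(lab))
    if len(clusters) < 2:
        raise ValidationError("need at least two clusters to compare")
    sizes = {c: int(np.sum(lab == c)) for c in clusters}
    small = [c for c, s in sizes.items() if s < min_cluster_n]
    if small:
        raise ValidationError(
            f"cluster(s) {small} below the minimum size {min_cluster_n}"
        )

    comparisons = []
    for var in measures.columns:
        groups = [measures[var].to_numpy(dtype=float)[lab == c] for c in clusters]
        normal = all(stats.shapiro(g).pvalue > alpha for g in groups)
        if normal:
            stat, p = stats.f_oneway(*groups)
            tukey = stats.tukey_hsd(*groups)
            rows = []
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    rows.append(
                        {
                            "cluster_a": clusters[i],
                            "cluster_b": clusters[j],
                            "p_value": float(tukey.pvalue[i, j]),
                        }
                    )
            pairwise = pd.DataFrame(rows)
            test = "anova"
        else:
            stat, p = stats.kruskal(*groups)
            pairwise = _dunn_posthoc(groups, clusters, posthoc_correction)
            test = "kruskal"
        pairwise["significant"] = pairwise["p_value"] < alpha
        comparisons.append(
            VariableComparison(
                variable=str(var),
                normal=normal,
                test=test,
                statistic=float(stat),
                p_value=float(p),
                significant=bool(p < alpha),
                pairwise=pairwise,
                group_means={c: float(np.mean(g)) for c, g in zip(clusters, groups)},
                group_sds={c: float(np.std(g, ddof=1)) for c, g in zip(clusters, groups)},
            )
        )
    return ClusterComparison(alpha=alpha, variables=tuple(comparisons))
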