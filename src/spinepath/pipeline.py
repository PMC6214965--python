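"""End-to-end analysis pipeline: normalize -> cluster -> paths -> outcomes.

Chains the package's stages exactly as they are meant to be run on a real
cohort: two-step normalization against the controls, per-timepoint K-means
clustering with silhouette selection of k, fusion grouping with small-group
exclusion, treatment-path construction, and the empirical path-outcome
table with concordance/coverage plus the multinomial regression LR test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence



from .cluster import CurveClusterModel, CurveClusterResults
from .config import CohortConfig
from .io import CentroidSpine, FusionAssignment, Timepoint, ValidationError
from .normalize import ControlTemplate, NormalizedCurve, normalize_cohort
from .outcome import PathOutcomeModel, PathOutcomeResults, PathOutcomeTable
from .paths import FusionGroupTable, TreatmentPath, assign_fusion_groups, build_paths, filter_small_groups

__all__ = ["PipelineResults", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResults:
    """Everything the full pipeline produces for one cohort."""

    template: ControlTemplate
    curves: Mapping[Timepoint, tuple[NormalizedCurve, ...]]
    clusterings: Mapping[Timepoint, CurveClusterResults]
    fusion_groups: FusionGroupTable
    removed_patients: tuple[str, ...]
    paths: Mapping[str, TreatmentPath]
    outcome_table: PathOutcomeTable
    regression: PathOutcomeResults | None

    def labels(self, timepoint: Timepoint) -> dict[str, int]:
        res = self.clusterings[timepoint]
        assert res.patient_ids is not None
        return {pid: int(c) for pid, c in zip(res.patient_ids, res.labels)}

    def summary(self) -> str:
        parts = [self.clusterings[tp].summary() for tp in self.clusterings]
        conc = self.outcome_table.concordance()
        cov = self.outcome_table.coverage()
        parts.append(
            f"Fusion groups: {self.fusion_groups.n_groups} kept, "
            f"{len(self.removed_patients)} patient(s) removed"
        )
        parts.append(
            f"Paths: {self.outcome_table.n_paths} distinct, "
            f"{len(conc)} with >=3 patients covering "
            f"{int(round(cov * 100))}% of included patients"
        )
        if self.regression is not None:
            parts.append(str(self.regression.lr_test))
        return "\n".join(parts)


def run_pipeline(
    spines: Sequence[CentroidSpine],
    controls: Sequence[CentroidSpine],
    fusions: Sequence[FusionAssignment],
    config: CohortConfig | None = None,
    fit_regression: bool = True,
    regression_encoding: str = "main_effects",
) -> PipelineResults:
    """Run the full analysis on one cohort.

    ``spines`` must contain a PO, EP and Y2 spine for every patient with a
    fusion assignment; ``controls`` are the non-scoliotic spines defining
    the resampling template.
    """
    config = config or CohortConfig()

    curves: dict[Timepoint, tuple[NormalizedCurve, ...]] = {}
    template = None
    for tp in (Timepoint.PO, Timepoint.EP, Timepoint.Y2):
        tp_spines = [s for s in spines if s.timepoint == tp]
        if not tp_spines:
            raise ValidationError(f"no spines at timepoint {tp.value}")
        tp_curves, template = normalize_cohort(tp_spines, controls)
        curves[tp] = tuple(tp_curves)

    clusterings = {
        tp: CurveClusterModel.from_curves(list(curves[tp])).select_k(
            config.k_range, restarts=config.restarts, seed=config.seed
        )
        for tp in curves
    }

    groups_all = assign_fusion_groups(fusions)
    groups, removed = filter_small_groups(
        groups_all, min_n=config.min_fusion_group_size
    )
    paths = build_paths(
        self_labels(clusterings[Timepoint.PO]),
        self_labels(clusterings[Timepoint.EP]),
        groups,
    )
    y2_all = self_labels(clusterings[Timepoint.Y2])
    y2 = {pid: y2_all[pid] for pid in paths}
    table = PathOutcomeTable.from_labels(paths, y2)

    regression = None
    if fit_regression:
        regression = PathOutcomeModel.from_paths(paths, y2).fit(
            encoding=regression_encoding
        )

    return PipelineResults(
        template=template,
        curves=curves,
        clusterings=clusterings,
        fusion_groups=groups,
        removed_patients=tuple(removed),
        paths=paths,
        outcome_table=table,
        regression=regression,
    )


def self_labels(res: CurveClusterResults) -> dict[str, int]:
    """Patient-id -> cluster-label mapping of a clustering result."""
    if res.patient_ids is None:
        raise ValidationError("clustering result carries no patient ids")
    return {pid: int(c) for pid, c in zip(res.patient_ids, res.labels)}
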