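"""Fusion-level grouping and treatment-path construction.

The instrumented segment of each patient is summarized by the (UIV, LIV)
pair; every distinct pair defines a *fusion group*.  Groups with too few
patients (default fewer than 3) are excluded from the analysis.  A
patient's *treatment path* is the triple PO_i-EP_j-F_m combining the
pre-operative curve cluster, the early post-operative curve cluster and the
fusion group — the three quantities determinable no later than early after
surgery, from which the two-year outcome cluster is predicted.

Fusion groups are numbered deterministically by the anatomical order of
their (UIV, LIV) pair (uppermost instrumented vertebra first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

from .io import FusionAssignment, ValidationError, VERTEBRA_INDEX

if TYPE_CHECKING:  # pragma: no cover
    from .outcome import PathOutcomeTable

__all__ = [
    "FusionGroupTable",
    "TreatmentPath",
    "assign_fusion_groups",
    "filter_small_groups",
    "build_paths",
    "merge_equivalent_fusion_groups",
]


@dataclass(frozen=True)
class TreatmentPath:
    """PO cluster / EP cluster / fusion group triple.

    ``fusion_groups`` is a sorted tuple of group ids: a single id for a raw
    path, several after outcome-equivalent groups have been merged.  The
    canonical string is e.g. ``"PO3-EP1-F6"`` or ``"PO1-EP1-F2,6"``.
    """

    po_cluster: int
    ep_cluster: int
    fusion_groups: tuple[int, ...]

    def __post_init__(self) -> None:
        if isinstance(self.fusion_groups, int):
            object.__setattr__(self, "fusion_groups", (self.fusion_groups,))
        else:
            object.__setattr__(
                self, "fusion_groups", tuple(sorted(set(self.fusion_groups)))
            )
        if self.po_cluster < 1 or self.ep_cluster < 1 or not self.fusion_groups:
            raise ValidationError(f"invalid treatment path components: {self}")
        if any(g < 1 for g in self.fusion_groups):
            raise ValidationError(f"invalid fusion group in path: {self}")

    @property
    def fusion_group(self) -> int:
        """The single fusion group of an unmerged path."""
        if len(self.fusion_groups) != 1:
            raise ValueError(f"{self} is a merged path spanning several groups")
        return self.fusion_groups[0]

    def __str__(self) -> str:
        f = ",".join(str(g) for g in self.fusion_groups)
        return f"PO{self.po_cluster}-EP{self.ep_cluster}-F{f}"


@dataclass(frozen=True)
class FusionGroupTable:
    """Mapping from (UIV, LIV) levels to group ids plus per-patient assignment.

    ``group_of_level`` maps each distinct (uiv, liv) pair to its group id,
    ``counts`` the group id to its patient count, and ``assignments`` each
    patient to their group id.  Group sizes always sum to the cohort size.
    """

    group_of_level: Mapping[tuple[str, str], int]
    counts: Mapping[int, int]
    assignments: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.group_of_level.values())) != len(self.group_of_level):
            raise ValidationError("distinct fusion levels must map to distinct groups")
        if sum(self.counts.values()) != len(self.assignments):
            raise ValidationError("group counts do not sum to cohort size")

    @property
    def n_groups(self) -> int:
        return len(self.group_of_level)

    @property
    def n_patients(self) -> int:
        return len(self.assignments)

    def level_of_group(self, group_id: int) -> tuple[str, str]:
        for level, gid in self.group_of_level.items():
            if gid == group_id:
                return level
        raise KeyError(group_id)


def assign_fusion_groups(fusions: Sequence[FusionAssignment]) -> FusionGroupTable:
    """Group patients by identical (UIV, LIV) pair.

    Groups are numbered 1..G in anatomical order of (UIV, LIV): primarily by
    the UIV from cranial to caudal, then by the LIV.  Empty input produces
    an empty table.
    """
    levels = sorted(
        {f.level for f in fusions},
        key=lambda lv: (VERTEBRA_INDEX[lv[0]], VERTEBRA_INDEX[lv[1]]),
    )
    group_of_level = {level: i + 1 for i, level in enumerate(levels)}
    assignments: dict[str, int] = {}
    counts: dict[int, int] = {g: 0 for g in group_of_level.values()}
    for f in fusions:
        if f.patient_id in assignments:
            raise ValidationError(f"duplicate fusion assignment for {f.patient_id}")
        gid = group_of_level[f.level]
        assignments[f.patient_id] = gid
        counts[gid] += 1
    return FusionGroupTable(
        group_of_level=group_of_level, counts=counts, assignments=assignments
    )


def filter_small_groups(
    table: FusionGroupTable, min_n: int = 3
) -> tuple[FusionGroupTable, list[str]]:
    """Drop patients belonging to fusion groups with fewer than ``min_n`` members.

    Returns the filtered table — surviving groups renumbered contiguously
    1..G' preserving their original order — and the sorted ids of the
    removed patients.  Removing every group is an error.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept_groups = [g for g in sorted(table.counts) if table.counts[g] >= min_n]
    if not kept_groups:
        raise ValidationError(
            f"no fusion group has at least {min_n} patients; nothing to analyse"
        )
    renumber = {g: i + 1 for i, g in enumerate(kept_groups)}
    removed = sorted(
        pid for pid, g in table.assignments.items() if g not in renumber
    )
    group_of_level = {
        level: renumber[g]
        for level, g in table.group_of_level.items()
        if g in renumber
    }
    assignments = {
        pid: renumber[g] for pid, g in table.assignments.items() if g in renumber
    }
    counts = {renumber[g]: table.counts[g] for g in kept_groups}
    return (
        FusionGroupTable(
            group_of_level=group_of_level, counts=counts, assignments=assignments
        ),
        removed,
    )


def build_paths(
    po_labels: Mapping[str, int],
    ep_labels: Mapping[str, int],
    groups: FusionGroupTable | Mapping[str, int],
) -> dict[str, TreatmentPath]:
    """Assemble each included patient's treatment path PO_i-EP_j-F_m.

    The patients considered are those with a fusion-group assignment (i.e.
    those surviving the small-group filter); each must also carry PO and EP
    cluster labels, otherwise a :class:`ValidationError` names the patient.
    The result is a pure function of its inputs: input ordering is
    irrelevant.
    """
    group_map = groups.assignments if isinstance(groups, FusionGroupTable) else groups
    paths: dict[str, TreatmentPath] = {}
    for pid in sorted(group_map):
        if pid not in po_labels:
            raise ValidationError(f"patient {pid} has no PO cluster label")
        if pid not in ep_labels:
            raise ValidationError(f"patient {pid} has no EP cluster label")
        paths[pid] = TreatmentPath(
            po_cluster=int(po_labels[pid]),
            ep_cluster=int(ep_labels[pid]),
            fusion_groups=(int(group_map[pid]),),
        )
    return paths


def merge_equivalent_fusion_groups(table: "PathOutcomeTable") -> "PathOutcomeTable":
    """Merge fusion groups that lead to the same two-year outcome.

    Within each (PO, EP) stratum, paths whose modal two-year cluster is the
    same are unioned into a single path whose fusion-group set is the union
    and whose counts are the sums.  Modal ties are broken toward the lower
    cluster index.  The grand total is preserved.
    """
    from .outcome import PathOutcomeTable  # deferred: avoids a cycle

    merged: dict[tuple[int, int, int], tuple[set[int], list[int]]] = {}
    order: list[tuple[int, int, int]] = []
    for path, counts in table.rows():
        modal = int(min(
            (c for c in table.outcome_levels),
            key=lambda c: (-counts[table.outcome_levels.index(c)], c),
        ))
        key = (path.po_cluster, path.ep_cluster, modal)
        if key not in merged:
            merged[key] = (set(), [0] * len(counts))
            order.append(key)
        groups, acc = merged[key]
        groups.update(path.fusion_groups)
        for i, c in enumerate(counts):
            acc[i] += int(c)
    new_paths = [
        TreatmentPath(po_cluster=po, ep_cluster=ep, fusion_groups=tuple(merged[(po, ep, m)][0]))
        for (po, ep, m) in order
    ]
    new_counts = [merged[key][1] for key in order]
    return PathOutcomeTable.from_counts(
        new_paths, new_counts, outcome_levels=table.outcome_levels
    )
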