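"""Packaged fixture tables from the published surgical cohort.

Two small tables transcribed from the printed clinical results ship with
the package so that the fusion-grouping and path-outcome analytics can be
exercised against known numbers:

* ``table2`` — the 8 fusion levels (UIV, LIV) with their patient counts
  (67 patients in total; the two smallest levels, 3 patients, were excluded
  from the published analysis);
* ``table3`` — the 17 treatment paths with their two-year-outcome cluster
  counts for the 64 included patients.  Fusion-group entries like ``2;6``
  are merged groups that led to the same outcome.

The fusion-group numbers in these tables are the publication's own; the
package's :func:`spinepath.paths.assign_fusion_groups` numbers groups
anatomically instead, so the printed G-numbers live only here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import FusionAssignment
from .paths import TreatmentPath
from .outcome import PathOutcomeTable

__all__ = [
    "load_table2",
    "load_table3",
    "table2_fusion_assignments",
    "table3_outcome_table",
]


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("spinepath.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    """Fusion-level table: columns group, uiv, liv, n_patients."""
    return _read_fixture("table2.csv")


def load_table3() -> pd.DataFrame:
    """Treatment-path outcome table: path, po, ep, fusion_groups, y2_1..y2_3."""
    return _read_fixture("table3.csv")


def table2_fusion_assignments() -> list[FusionAssignment]:
    """Expand the fusion-level table into one assignment per patient."""
    rows = load_table2()
    fusions = []
    i = 0
    for row in rows.itertuples(index=False):
        for _ in range(int(row.n_patients)):
            i += 1
            fusions.append(
                FusionAssignment(patient_id=f"t2p{i:03d}", uiv=row.uiv, liv=row.liv)
            )
    return fusions


def table3_outcome_table() -> PathOutcomeTable:
    """The published path-by-outcome contingency table as a PathOutcomeTable."""
    rows = load_table3()
    paths = [
        TreatmentPath(
            po_cluster=int(r.po),
            ep_cluster=int(r.ep),
            fusion_groups=tuple(int(g) for g in str(r.fusion_groups).split(";")),
        )
        for r in rows.itertuples(index=False)
    ]
    counts = rows[["y2_1", "y2_2", "y2_3"]].to_numpy(dtype=int)
    return PathOutcomeTable.from_counts(paths, counts, outcome_levels=[1, 2, 3])
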