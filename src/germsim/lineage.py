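"""In-silico cell tracking and clonal labeling.

Every cell carries a lineage label inherited through divisions.  Labeling
a set of cells at some time (e.g. all cells at the start of L3, or one
distal / one mid / one proximal cell) partitions the later germ line into
clones; the clonality summary asks how many founder labels survive, the
question behind neutral-drift / monoclonality analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BACKGROUND_LABEL = 0


@dataclass
class LineageRecord:
    cell_id: int
    parent_id: int | None
    label: int
    birth_time: float
    end_time: float | None = None
    end_cause: str = "alive"  # division | apoptosis | ovulation | sperm_consumed
    trajectory: list = field(default_factory=list)  # (t, x, y, z, s)

    def close(self, t: float, cause: str):
        self.end_time = t
        self.end_cause = cause

    def alive_at(self, t: float) -> bool:
        return self.birth_time <= t and (self.end_time is None
                                         or t < self.end_time)


def label_cells_at(state, selection="all", fractions=(0.1, 0.5, 0.9)):
    """Assign clone labels to cells of the running simulation.

    ``selection="all"`` gives every live cell its own label;
    ``selection="positions"`` labels one cell nearest each requested
    fraction of the current occupied distal-proximal extent (distal
    fraction 0 = at the DTC) and everything else the background label.
    Labels propagate to daughters automatically.  Idempotent for a fixed
    time and selection.
    """
    cells = state.cells
    if not cells:
        raise ValueError("no cells to label")
    if selection == "all":
        for i, c in enumerate(sorted(cells, key=lambda c: c.id)):
            _set_label(state, c, i + 1)
        return state
    if selection == "positions":
        d = np.array([c.dtc_distance for c in cells])
        span = d.max() - d.min()
        for i, frac in enumerate(fractions):
            target = d.min() + frac * span
            chosen = min(cells, key=lambda c: abs(c.dtc_distance - target))
            _set_label(state, chosen, i + 1)
        return state
    raise ValueError(f"unknown selection {selection!r}")


def _set_label(state, cell, label):
    cell.label = label
    state.records[cell.id].label = label


def clonality_summary(records: dict, t: float, exclude_sperm_ids=()):
    """(surviving label count, monoclonal flag, per-label census) among
    cells alive at ``t``.  Sperm are excluded from the monoclonality
    question by passing their ids (the maintained germ line is what
    drifts); the background label never counts as a clone."""
    census: dict[int, int] = {}
    for rec in records.values():
        if rec.cell_id in exclude_sperm_ids:
            continue
        if rec.alive_at(t) and rec.label != BACKGROUND_LABEL:
            census[rec.label] = census.get(rec.label, 0) + 1
    n = len(census)
    return n, n == 1, census


def ancestry_forest(records: dict) -> dict:
    """parent map (cell id -> parent id), validating that every
    non-founder's parent record exists."""
    parents = {}
    for rec in records.values():
        if rec.parent_id is not None and rec.parent_id not in records:
            raise ValueError(f"dangling parent {rec.parent_id} "
                             f"for cell {rec.cell_id}")
        parents[rec.cell_id] = rec.parent_id
    return parents


def trajectory_table(records: dict) -> pd.DataFrame:
    """Long-format trajectories (cell id, label, t, x, y, z, s); tracks of
    removed cells end at their removal time."""
    rows = []
    for rec in records.values():
        for (t, x, y, z, s) in rec.trajectory:
            rows.append({"cell_id": rec.cell_id, "label": rec.label,
                         "t_hph": t, "x": x, "y": y, "z": z,
                         "arclength_um": s})
    if not rows:
        return pd.DataFrame(columns=["cell_id", "label", "t_hph",
                                     "x", "y", "z", "arclength_um"])
    return pd.DataFrame(rows).sort_values(
        ["cell_id", "t_hph"]).reset_index(drop=True)


def lineage_table(records: dict) -> pd.DataFrame:
    rows = [{
        "cell_id": r.cell_id,
        "parent_id": -1 if r.parent_id is None else r.parent_id,
        "label": r.label, "birth_time_hph": r.birth_time,
        "end_time_hph": np.nan if r.end_time is None else r.end_time,
        "end_cause": r.end_cause,
    } for r in records.values()]
    return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
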