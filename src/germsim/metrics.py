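"""Quantitative germline readouts.

Distances are measured from the DTC along the gonad path.  Two row
conventions coexist, mirroring how the measurements are made:

* zone metrics (proliferative-zone length, proximal-most proliferative
  row) bin cells into rows of one cell diameter (CD) of arclength, the
  unit of the standard distal-to-proximal row counts;
* the internuclear distance index uses *rank* rows (cells sorted by DTC
  distance, grouped by the ring capacity of the tube), because it reports
  microns per row of nuclei and must shrink when the same cells pack
  more tightly.

The proliferative zone (mitotic region) is everything distal to the first
row containing two or more meiotic cells; "meiotic" starts at commitment
(NonProliferative onward), the stage at which meiotic nuclear morphology
appears in vivo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .germline import MEIOTIC_STATES, MITOTIC_PHASES

MEIOTIC_FOR_ZONE = frozenset(MEIOTIC_STATES)


class MetricsError(Exception):
    pass


def assign_rows(dtc_distance_um: np.ndarray, cd_um: float) -> np.ndarray:
    """Row index = floor(distance / CD); row 0 abuts the DTC."""
    if cd_um <= 0:
        raise ValueError("CD must be positive")
    return np.floor(np.asarray(dtc_distance_um, float) / cd_um).astype(int)


def _is_meiotic(cycle_states) -> np.ndarray:
    return np.isin(np.asarray(cycle_states), list(MEIOTIC_FOR_ZONE))


def _is_proliferative(cycle_states) -> np.ndarray:
    return np.isin(np.asarray(cycle_states), list(MITOTIC_PHASES))


def prolif_zone_length(rows: np.ndarray, cycle_states) -> int:
    """Smallest row index holding >= 2 meiotic cells; if no such row, the
    last occupied row + 1 (the zone spans everything)."""
    rows = np.asarray(rows)
    if len(rows) == 0:
        raise MetricsError("empty snapshot")
    meiotic_rows = rows[_is_meiotic(cycle_states)]
    if len(meiotic_rows):
        counts = np.bincount(meiotic_rows)
        qualifying = np.flatnonzero(counts >= 2)
        if len(qualifying):
            return int(qualifying[0])
    return int(rows.max()) + 1


def proximal_most_prolif_row(rows: np.ndarray, cycle_states) -> int:
    """Largest row index holding at least one mitotically cycling cell."""
    prolif_rows = np.asarray(rows)[_is_proliferative(cycle_states)]
    if not len(prolif_rows):
        raise MetricsError("no proliferative cells (zone lost)")
    return int(prolif_rows.max())


def mitotic_index(cycle_states, in_zone: np.ndarray) -> float:
    """Fraction of proliferative-zone cells currently in M phase."""
    in_zone = np.asarray(in_zone, bool)
    if not in_zone.any():
        raise MetricsError("empty proliferative zone")
    states = np.asarray(cycle_states)[in_zone]
    return float(np.mean(states == "M"))


def ring_capacity(tube_radius_um: float, cell_radius_um: float) -> int:
    """Cells per row of nuclei: how many cells of the given radius line
    the tube wall in one ring."""
    shell = max(tube_radius_um - cell_radius_um, cell_radius_um)
    return max(1, int(round(np.pi * 2 * shell / (2 * cell_radius_um))))


def internuclear_distance_index(dtc_distance_um, cycle_states,
                                cells_per_row: int) -> float:
    """Microns per row of nuclei from the distal tip to meiotic entry.

    Cells are sorted by DTC distance and grouped into rank rows of
    ``cells_per_row``; the boundary is the first rank row with >= 2
    meiotic cells, and the index is its mean distance in microns divided
    by its row number.  Axially compressing a snapshot by a factor scales
    the index by exactly that factor.
    """
    d = np.asarray(dtc_distance_um, float)
    meiotic = _is_meiotic(cycle_states)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    m_sorted = meiotic[order]
    n_rows = int(np.ceil(len(d) / cells_per_row))
    for row in range(n_rows):
        sl = slice(row * cells_per_row, (row + 1) * cells_per_row)
        if m_sorted[sl].sum() >= 2:
            if row == 0:
                raise MetricsError(
                    "meiotic boundary in the distal-most row; index undefined")
            return float(d_sorted[sl].mean() / row)
    raise MetricsError("no meiotic boundary in snapshot")


def metrics_report(state) -> dict:
    """One metrics row for the current simulation state."""
    cd = state.config.run.cell_diameter_um
    counts = state.census()
    geom = state.geometry
    span = geom.turn_span()
    row = {"t_hph": state.clock_hph,
           "gonad_length_um": geom.total_length_um,
           "tube_radius_um": geom.radius_at(state.clock_hph),
           "turn_start_um": np.nan if span is None else span[0],
           "stretch_offset_um": geom.stretch_offset_um}
    for k, v in counts.items():
        row[f"count_{k}"] = v
    if not state.cells:
        return row
    d = np.array([c.dtc_distance for c in state.cells])
    states = np.array([c.cycle_state for c in state.cells])
    rows_cd = assign_rows(d, cd)
    zone = prolif_zone_length(rows_cd, states)
    row["prolif_zone_rows_CD"] = zone
    row["prolif_zone_um"] = zone * cd
    try:
        row["proximal_most_prolif_row_CD"] = proximal_most_prolif_row(
            rows_cd, states)
    except MetricsError:
        row["proximal_most_prolif_row_CD"] = np.nan
    in_zone = rows_cd < max(zone, 1)
    try:
        row["mitotic_index"] = mitotic_index(states, in_zone)
    except MetricsError:
        row["mitotic_index"] = np.nan
    g = ring_capacity(state.geometry.radius_at(state.clock_hph),
                      state.config.run.base_radius_um)
    try:
        row["internuclear_distance_index_um_per_CD"] = \
            internuclear_distance_index(d, states, g)
    except MetricsError:
        row["internuclear_distance_index_um_per_CD"] = np.nan
    return row


def metrics_frame(state) -> pd.DataFrame:
    return pd.DataFrame(state.metrics_rows)
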