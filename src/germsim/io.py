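"""Snapshot, event, metric and lineage writers.

CSV is the primary interchange format (fixed header, 9 significant digits
so outputs diff cleanly across platforms); snapshots can additionally be
written as VTK-legacy POLYDATA point clouds viewable in ParaView, with
radius and a state-class integer as point data.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .lineage import lineage_table, trajectory_table
from .metrics import metrics_frame

FLOAT_FORMAT = "%.9g"

SNAPSHOT_COLUMNS = ["cell_id", "x", "y", "z", "radius_um", "arclength_um",
                    "rho_um", "dtc_distance_um", "cycle_state", "sex_state",
                    "glp1_state", "label", "class"]

CLASS_CODES = {"proliferative": 0, "meiotic": 1, "sperm_fated": 2,
               "sperm": 3, "oocyte_fated": 4, "mature_oocyte": 5}


def write_snapshot(state, path, vtk: bool = False):
    """Write the current population to ``path`` (CSV).  With ``vtk=True``
    an additional legacy-VTK point cloud is written next to it."""
    df = state.snapshot()
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if vtk:
        write_vtk_points(df, os.path.splitext(str(path))[0] + ".vtk",
                         title=f"germsim t={state.clock_hph:.3f} hph")
    return path


def write_vtk_points(snapshot: pd.DataFrame, path, title="germsim snapshot"):
    """Legacy-VTK POLYDATA writer: points + radius + state-class scalars."""
    n = len(snapshot)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET POLYDATA", f"POINTS {n} float"]
    for _, row in snapshot.iterrows():
        lines.append(f"{row.x:.9g} {row.y:.9g} {row.z:.9g}")
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS radius float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{r:.9g}" for r in snapshot.radius_um]
    lines.append("SCALARS state_class int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(CLASS_CODES.get(c, -1)) for c in snapshot["class"]]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def events_frame(state) -> pd.DataFrame:
    cols = ["t_hph", "cell_id", "kind", "x", "y", "z", "dtc_distance_um"]
    if not state.event_log:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(state.event_log, columns=cols)


def write_run_outputs(state, out_dir, vtk: bool = False):
    """events.csv, metrics.csv, lineage.csv (+ trajectories.csv when
    tracking was enabled) and the resolved configuration."""
    from . import config as config_mod

    os.makedirs(out_dir, exist_ok=True)
    events_frame(state).to_csv(os.path.join(out_dir, "events.csv"),
                               index=False, float_format=FLOAT_FORMAT)
    metrics_frame(state).to_csv(os.path.join(out_dir, "metrics.csv"),
                                index=False, float_format=FLOAT_FORMAT)
    lineage_table(state.records).to_csv(os.path.join(out_dir, "lineage.csv"),
                                        index=False, float_format=FLOAT_FORMAT)
    if state.config.run.track_trajectories:
        trajectory_table(state.records).to_csv(
            os.path.join(out_dir, "trajectories.csv"), index=False,
            float_format=FLOAT_FORMAT)
    config_mod.save(state.config, os.path.join(out_dir,
                                               "config_resolved.cfg"))
    return out_dir


def snapshot_writer(out_dir, vtk: bool = False):
    """Callback for :func:`germsim.simulation.run_simulation` that writes
    ``snap_<t>.csv`` at every observation time."""
    os.makedirs(out_dir, exist_ok=True)

    def callback(state):
        name = f"snap_{state.clock_hph:08.3f}.csv"
        write_snapshot(state, os.path.join(out_dir, name), vtk=vtk)

    return callback
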