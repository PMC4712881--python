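"""Simulation orchestration.

One step advances the tissue by ``dt`` hours in a fixed sub-step order:

1. build a frozen :class:`CellContext` per cell (arclength distance to the
   DTC, compressed-volume fraction, life stage);
2. step every cell's statechart (cells in id order, one RNG stream);
3. process emitted events: divisions, apoptosis, oocyte maturation,
   growth, ovulation;
4. integrate the overdamped mechanics (several substeps per dt);
5. enforce the tube, tip and rachis constraints;
6. advance the DTC (with pausing) and apply late-L4 stretching;
7. advance the clock.

Statecharts run before mechanics so that guards read positions from the
previous step's settled configuration, making the per-cell update order
irrelevant.  All randomness flows through a single generator consumed in
cell-id order, so runs are bitwise reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import germline, lineage as lineage_mod
from .config import SimulationConfig
from .geometry import GonadGeometry
from .germline import (MEIOTIC_STATES, MITOTIC_PHASES, build_germline_chart,
                       grow_cell, randomize_cycle_phase)
from .mechanics import (compute_forces, find_neighbors, integrate_positions,
                        volume_fractions)
from .statechart import CellContext, fork_on_division, step_statechart

CYCLE = germline.CYCLE_REGION
SEX = germline.SEX_REGION


@dataclass
class Cell:
    id: int
    position: np.ndarray
    radius: float
    drag: float
    label: int
    inst: object  # StatechartInstance
    # per-step cached fields
    s: float = 0.0
    rho: float = 0.0
    dtc_distance: float = 0.0
    volume_fraction: float = 1.0

    @property
    def cycle_state(self):
        return self.inst.active[CYCLE]

    @property
    def sex_state(self):
        return self.inst.active[SEX]


def classify(cycle_state: str, sex_state: str) -> str:
    """Census class of a cell; the classes partition the population."""
    if sex_state == "Sperm":
        return "sperm"
    if sex_state == "MatureOocyte":
        return "mature_oocyte"
    if sex_state == "OocyteFated":
        return "oocyte_fated"
    if sex_state in ("SpermFated1", "SpermFated2"):
        return "sperm_fated"
    if cycle_state in MITOTIC_PHASES:
        return "proliferative"
    return "meiotic"


class SimulationState:
    def __init__(self, config: SimulationConfig):
        self.config = config
        self.clock_hph = config.run.t_start_hph
        self.rng = np.random.default_rng(config.run.seed)
        self.chart = build_germline_chart(
            config.cell_cycle, config.signaling, config.fate,
            contact_inhibition_enabled=config.run.contact_inhibition)
        self.geometry = GonadGeometry(config.path)
        self.cells: list[Cell] = []
        self.next_id = 0
        self.event_log: list[dict] = []
        self.records: dict[int, lineage_mod.LineageRecord] = {}
        self.metrics_rows: list[dict] = []
        self._next_traj_t = self.clock_hph

    # ------------------------------------------------------------------
    def log_event(self, cell: Cell, kind: str, **extra):
        rec = {"t_hph": self.clock_hph, "cell_id": cell.id, "kind": kind,
               "x": cell.position[0], "y": cell.position[1],
               "z": cell.position[2], "dtc_distance_um": cell.dtc_distance}
        rec.update(extra)
        self.event_log.append(rec)

    def new_cell(self, position, radius, label, inst, parent_id=None) -> Cell:
        cell = Cell(id=self.next_id, position=np.asarray(position, float),
                    radius=radius, drag=self.config.run.drag, label=label,
                    inst=inst)
        self.next_id += 1
        self.cells.append(cell)
        self.records[cell.id] = lineage_mod.LineageRecord(
            cell_id=cell.id, parent_id=parent_id, label=label,
            birth_time=self.clock_hph)
        return cell

    def end_cell(self, cell: Cell, cause: str):
        self.records[cell.id].close(self.clock_hph, cause)

    def snapshot(self) -> pd.DataFrame:
        """Current population as a flat table (one row per live cell)."""
        rows = []
        for c in self.cells:
            rows.append({
                "cell_id": c.id, "x": c.position[0], "y": c.position[1],
                "z": c.position[2], "radius_um": c.radius,
                "arclength_um": c.s, "rho_um": c.rho,
                "dtc_distance_um": c.dtc_distance,
                "cycle_state": c.cycle_state, "sex_state": c.sex_state,
                "glp1_state": c.inst.active[germline.GLP1_REGION],
                "label": c.label,
                "class": classify(c.cycle_state, c.sex_state),
            })
        return pd.DataFrame(rows, columns=[
            "cell_id", "x", "y", "z", "radius_um", "arclength_um", "rho_um",
            "dtc_distance_um", "cycle_state", "sex_state", "glp1_state",
            "label", "class"])

    def census(self) -> dict:
        counts = {"total": len(self.cells), "proliferative": 0, "meiotic": 0,
                  "sperm_fated": 0, "sperm": 0, "oocyte_fated": 0,
                  "mature_oocyte": 0}
        for c in self.cells:
            counts[classify(c.cycle_state, c.sex_state)] += 1
        return counts


# ----------------------------------------------------------------------
def initialize(config: SimulationConfig) -> SimulationState:
    """Founder population: 16 germ cells packed at the distal end of the
    initial path, each in a random point of the mitotic cycle, signaling
    regions in their distal (GLP-1 bound) states."""
    state = SimulationState(config)
    run = config.run
    geom = state.geometry
    t0 = run.t_start_hph
    r_tube = geom.radius_at(t0)
    arc0 = geom.dtc_arclength
    shell = max(0.0, r_tube - 2.0 * run.base_radius_um)
    n = run.n_founders
    per_ring = max(1, int(np.floor(np.pi * 2 * max(shell, 1.0)
                                   / run.cell_diameter_um)))
    ctx = CellContext(time_hph=t0, dtc_distance_um=0.0, life_stage="larval",
                      rng=state.rng)
    for i in range(n):
        ring, slot = divmod(i, per_ring)
        s = max(0.5, arc0 - run.base_radius_um - ring * run.cell_diameter_um)
        angle = 2 * np.pi * (slot / per_ring + 0.13 * ring) \
            + 0.1 * state.rng.random()
        foot = geom.path_point(s)[0]
        offset = shell * np.array([0.0, np.cos(angle), np.sin(angle)])
        inst = state.chart.initial_instance()
        randomize_cycle_phase(inst, state.chart, ctx, state.rng)
        state.new_cell(foot + offset, run.base_radius_um, label=0, inst=inst)
    _refresh_projection(state)
    return state


def _refresh_projection(state: SimulationState):
    if not state.cells:
        return
    X = np.array([c.position for c in state.cells])
    s, rho, _ = state.geometry.project(X)
    arc = state.geometry.dtc_arclength
    for c, si, ri in zip(state.cells, s, rho):
        c.s = float(si)
        c.rho = float(ri)
        c.dtc_distance = float(arc - si)


def divide(state: SimulationState, parent: Cell, ctx: CellContext):
    """Replace a dividing cell by two daughters of the base mitotic radius
    at parent position +/- 0.5*radius along a uniformly random axis; both
    inherit the parent's statechart configuration and lineage label."""
    run = state.config.run
    u = state.rng.normal(size=3)
    u /= np.linalg.norm(u)
    # spermatogenic divisions yield small sperm-sized daughters
    if parent.sex_state in ("SpermFated2", "Sperm"):
        r = state.config.fate.sperm_radius_um
    else:
        r = run.base_radius_um
    d1_inst, d2_inst = fork_on_division(parent.inst, state.chart, ctx,
                                        state.rng)
    state.log_event(parent, "division")
    state.end_cell(parent, "division")
    state.cells.remove(parent)
    for inst, sign in ((d1_inst, 1.0), (d2_inst, -1.0)):
        daughter = state.new_cell(parent.position + sign * 0.5 * r * u,
                                  radius=r, label=parent.label, inst=inst,
                                  parent_id=parent.id)
        daughter.s, daughter.rho = parent.s, parent.rho
        daughter.dtc_distance = parent.dtc_distance
        daughter.volume_fraction = parent.volume_fraction


def ovulate(state: SimulationState):
    """Remove mature oocytes that reached the proximal end of the oviduct,
    consuming one sperm each; without sperm, oocytes accumulate."""
    run = state.config.run
    window = (run.ovulation_window_oocyte_diameters
              * 2.0 * state.config.fate.oocyte_mature_radius_um)
    while True:
        sperm = [c for c in state.cells if c.sex_state == "Sperm"]
        if not sperm:
            return
        ready = [c for c in state.cells
                 if c.sex_state == "MatureOocyte" and c.s <= window]
        if not ready:
            return
        oocyte = min(ready, key=lambda c: c.s)
        used_sperm = min(sperm, key=lambda c: c.s)
        state.log_event(oocyte, "ovulation")
        state.log_event(used_sperm, "sperm_consumed")
        state.end_cell(oocyte, "ovulation")
        state.end_cell(used_sperm, "sperm_consumed")
        state.cells.remove(oocyte)
        state.cells.remove(used_sperm)


def step(state: SimulationState):
    """Advance the whole simulation by one dt."""
    config = state.config
    run = config.run
    dt = run.dt_h
    geom = state.geometry
    t = state.clock_hph
    stage = run.life_stage(t, config.cell_cycle.ramp_start_hph)

    # (1) contexts: projection was refreshed at the end of the previous
    # step; compute compression from the current packing
    cells = state.cells
    if cells:
        X = np.array([c.position for c in cells])
        radii = np.array([c.radius for c in cells])
        cutoff = 2.0 * float(radii.max())
        pairs = find_neighbors(X, cutoff)
        vf = volume_fractions(X, radii, pairs)
        for c, v in zip(cells, vf):
            c.volume_fraction = float(v)

    # (2) statecharts, cells in id order, single RNG stream
    emitted = []
    for c in cells:
        ctx = CellContext(time_hph=t, dtc_distance_um=c.dtc_distance,
                          volume_fraction=c.volume_fraction,
                          radius_um=c.radius, life_stage=stage,
                          rng=state.rng, dt_h=dt)
        events = step_statechart(c.inst, state.chart, ctx, dt)
        if events:
            emitted.append((c, ctx, events))

    # (3) events: deaths first, then divisions, then growth and ovulation
    for c, ctx, events in emitted:
        kinds = [e[0] for e in events]
        for kind in kinds:
            if kind in ("meiotic_entry", "fate_sperm", "fate_oocyte",
                        "mature_oocyte"):
                state.log_event(c, kind)
        if "death" in kinds:
            state.log_event(c, "death")
            state.end_cell(c, "apoptosis")
            state.cells.remove(c)
            continue
        if "division" in kinds:
            divide(state, c, ctx)

    fate = config.fate
    for c in state.cells:
        c.radius = grow_cell(c.radius, c.cycle_state, c.sex_state, fate, dt)
    ovulate(state)

    # (4) mechanics substeps
    cells = state.cells
    if cells:
        X = np.array([c.position for c in cells])
        radii = np.array([c.radius for c in cells])
        ids = np.array([c.id for c in cells])
        drags = np.array([c.drag for c in cells])
        p = config.force
        nsub = max(1, int(round(dt / p.dt_mech_h)))
        cutoff = 2.0 * float(radii.max())
        s = rho = None
        for _ in range(nsub):
            pairs = find_neighbors(X, cutoff)
            forces = compute_forces(X, radii, ids, p, pairs=pairs)
            X = integrate_positions(X, forces, drags, radii, p)
            # (5) boundary after every substep: tube + tip, then rachis
            proj = geom.project(X)
            X, s, rho = geom.enforce_tube(X, radii, t, proj=proj)
            feet = geom.path_point(s)
            X, s, rho = geom.enforce_rachis(X, radii, t,
                                            proj=(s, rho, feet))
        for c, x, si, ri in zip(cells, X, s, rho):
            c.position = x
            c.s = float(si)
            c.rho = float(ri)

    # (6) DTC migration, turn fixing, stretching
    geom.maybe_fix_turn(t)
    rate = config.path.stage_migration_rates.get(run.stage_name(t), 0.0)
    max_s = max((c.s for c in state.cells), default=geom.dtc_arclength)
    geom.update_dtc(rate, dt, max_s, run.dtc_gap_cell_diameters
                    * run.cell_diameter_um)
    # stretching: capture the pre-stretch frame before the path moves
    feet_old = old_s = None
    if state.cells:
        old_s = np.array([c.s for c in state.cells])
        feet_old = geom.path_point(old_s)
    remap = geom.apply_stretch(t, dt)
    if remap is not None and state.cells:
        new_s = remap(old_s)
        feet_new = geom.path_point(new_s)
        X = np.array([c.position for c in state.cells])
        X = feet_new + (X - feet_old)
        for c, x, si in zip(state.cells, X, new_s):
            c.position = x
            c.s = float(si)

    # distances against the moved DTC
    arc = geom.dtc_arclength
    for c in state.cells:
        c.dtc_distance = float(arc - c.s)

    # (7) clock and trajectory sampling
    state.clock_hph = t + dt
    if run.track_trajectories and state.clock_hph >= state._next_traj_t:
        for c in state.cells:
            state.records[c.id].trajectory.append(
                (state.clock_hph, float(c.position[0]), float(c.position[1]),
                 float(c.position[2]), float(c.s)))
        state._next_traj_t += run.trajectory_dt_h
    return state


def run_simulation(config: SimulationConfig, until: float | None = None,
                   metrics_every: float | None = None,
                   snapshot_callback=None, state: SimulationState | None = None,
                   progress: bool = False):
    """Run (or continue) a simulation to ``until`` (default t_end).

    ``metrics_every`` appends a census/metrics row at that cadence;
    ``snapshot_callback(state)`` fires on the same schedule.
    """
    from .metrics import metrics_report  # local import to avoid a cycle

    if state is None:
        state = initialize(config)
    t_end = config.run.t_end_hph if until is None else until
    cadence = metrics_every if metrics_every is not None \
        else config.run.snapshot_every_h
    next_obs = state.clock_hph
    while state.clock_hph < t_end - 1e-9:
        if state.clock_hph >= next_obs - 1e-9:
            state.metrics_rows.append(metrics_report(state))
            if snapshot_callback is not None:
                snapshot_callback(state)
            next_obs += cadence
        step(state)
    state.metrics_rows.append(metrics_report(state))
    if snapshot_callback is not None:
        snapshot_callback(state)
    return state
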