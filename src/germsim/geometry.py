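"""The growing U-shaped gonad boundary.

The domain is a tube of radius r(t) around the path traced by the distal
tip cell (DTC).  The DTC starts at the proximal origin (center of the
animal), migrates along the distal axis, turns through a semicircle at a
prescribed time, and returns antiparallel.  Cells live at arclengths
s in [0, dtc_arclength]; all statechart distances are arclength distances
to the DTC (dtc_arclength - s), which is what "cell diameters from the
distal tip" measures in vivo and behaves correctly around the turn.

Three boundary rules act on cells:

* the tube: a cell's radial offset rho must satisfy rho + radius <= r(t);
* the rachis: in the distal arm and turn, cells are kept lining the tube
  wall (rho >= r(t) - 2*radius), leaving a hollow core for the rachis;
* the tip: no cell may sit distal of the DTC (s <= dtc_arclength); the
  proximal end is capped the same way at s = 0.

Late-L4 "stretching" translates the turn away from the center: both limbs
lengthen, cells are advected with the stretching frame, and the total path
length grows by twice the turn displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])


class GeometryError(Exception):
    pass


@dataclass
class DTCPathSpec:
    """Configuration of the DTC path and its schedules."""

    origin: tuple = (0.0, 0.0, 0.0)
    turn_radius_um: float = 13.0
    turn_time_hph: float = 24.0
    initial_arclength_um: float = 20.0
    #: prescribed migration rate per life stage (um/h)
    stage_migration_rates: dict = field(
        default_factory=lambda: {"L3": 16.0, "L4": 20.0, "adult": 0.0})
    #: total migratory travel allowed beyond the initial arclength; sets
    #: the unobstructed adult path length together with stretching
    migration_budget_um: float = 210.0
    #: piecewise-linear tube radius r(t): list of (hph, um) knots
    radius_schedule: tuple = ((16.0, 9.0), (25.0, 11.0), (34.0, 12.5))
    stretch_window: tuple = (29.0, 33.0)
    stretch_rate_um_per_h: float = 15.0
    stretch_enabled: bool = True
    dtc_pausing: bool = True

    def __post_init__(self):
        if self.turn_radius_um <= 0:
            raise ValueError("turn radius must be positive")
        if any(r < 0 for r in self.stage_migration_rates.values()):
            raise ValueError("migration rates must be >= 0")


class GonadGeometry:
    """Mutable geometry state for one simulation run."""

    def __init__(self, spec: DTCPathSpec):
        self.spec = spec
        self.origin = np.asarray(spec.origin, dtype=float)
        self.turn_radius = float(spec.turn_radius_um)
        self.dtc_arclength = float(spec.initial_arclength_um)
        self.migrated_um = 0.0
        self.stretch_offset_um = 0.0
        #: arclength of the turn start; None until the turn time fixes it
        self.pre_turn_len: float | None = None
        sched = sorted(spec.radius_schedule)
        self._rt = np.array([p[0] for p in sched])
        self._rr = np.array([p[1] for p in sched])

    # ------------------------------------------------------------------
    def radius_at(self, t: float) -> float:
        """Tube radius r(t), piecewise linear in time and flat beyond the
        schedule knots."""
        return float(np.interp(t, self._rt, self._rr))

    @property
    def total_length_um(self) -> float:
        return self.dtc_arclength

    def turn_span(self):
        """(turn start, turn end) arclengths, or None before the turn."""
        if self.pre_turn_len is None:
            return None
        return self.pre_turn_len, self.pre_turn_len + np.pi * self.turn_radius

    # ------------------------------------------------------------------
    def path_point(self, s):
        """Vectorized map arclength -> 3D point on the DTC path."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        pts = np.empty((len(s), 3))
        P = self.pre_turn_len
        if P is None:
            pts[:] = self.origin + s[:, None] * EX
            return pts
        Rt = self.turn_radius
        turn_end = P + np.pi * Rt
        center = self.origin + P * EX + Rt * EY
        seg1 = s <= P
        turn = (s > P) & (s <= turn_end)
        seg2 = s > turn_end
        pts[seg1] = self.origin + s[seg1, None] * EX
        theta = (s[turn] - P) / Rt
        pts[turn] = (center
                     + np.outer(np.sin(theta), Rt * EX)
                     - np.outer(np.cos(theta), Rt * EY))
        u = s[seg2] - turn_end
        pts[seg2] = self.origin + 2 * Rt * EY + np.outer(P - u, EX)
        return pts

    def dtc_position(self) -> np.ndarray:
        return self.path_point(self.dtc_arclength)[0]

    # ------------------------------------------------------------------
    def project(self, X: np.ndarray):
        """Closest-path-point projection for an (n, 3) array of positions.

        Returns ``(s, rho, feet)``: arclengths of the nearest path points
        (ties at the turn resolved to the smaller s), radial distances and
        the foot points themselves.  Only the laid-down part of the path
        (s <= dtc_arclength) is a valid target, which caps both tube ends
        with hemispheres.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        arc = self.dtc_arclength
        P = self.pre_turn_len
        w = X - self.origin
        cand_s = []
        cand_d2 = []

        s1_hi = arc if P is None else min(P, arc)
        s1 = np.clip(w @ EX, 0.0, s1_hi)
        f1 = self.origin + s1[:, None] * EX
        cand_s.append(s1)
        cand_d2.append(np.einsum("ij,ij->i", X - f1, X - f1))

        if P is not None and arc > P:
            Rt = self.turn_radius
            theta_max = min(np.pi, (arc - P) / Rt)
            center = self.origin + P * EX + Rt * EY
            wc = X - center
            a = wc @ EX
            b = wc @ EY
            phi = np.arctan2(a, -b)
            for theta in (np.clip(phi, 0.0, theta_max),
                          np.zeros(n),
                          np.full(n, theta_max)):
                s2 = P + theta * Rt
                f2 = (center + np.outer(np.sin(theta), Rt * EX)
                      - np.outer(np.cos(theta), Rt * EY))
                cand_s.append(s2)
                cand_d2.append(np.einsum("ij,ij->i", X - f2, X - f2))

            turn_end = P + np.pi * Rt
            if arc > turn_end:
                u = np.clip(P - (w @ EX - 0.0), 0.0, arc - turn_end)
                # foot on the return limb at height 2*Rt in y
                f3 = self.origin + 2 * Rt * EY + np.outer(P - u, EX)
                s3 = turn_end + u
                cand_s.append(s3)
                cand_d2.append(np.einsum("ij,ij->i", X - f3, X - f3))

        S = np.stack(cand_s)
        D2 = np.stack(cand_d2)
        # minimal distance; ties go to the smallest s
        order = np.lexsort((S, np.round(D2, 9)), axis=0)[0]
        idx = np.arange(n)
        s = S[order, idx]
        rho = np.sqrt(D2[order, idx])
        feet = self.path_point(s)
        return s, rho, feet

    def project_to_path(self, x):
        """Scalar convenience wrapper around :meth:`project`."""
        s, rho, _ = self.project(np.asarray(x, float)[None, :])
        return float(s[0]), float(rho[0])

    # ------------------------------------------------------------------
    def _radial_units(self, X, s, rho, feet):
        v = X - feet
        units = np.where(rho[:, None] > 1e-12, v / np.maximum(rho, 1e-12)[:, None],
                         EZ[None, :])
        return units

    def enforce_tube(self, X: np.ndarray, radii: np.ndarray, t: float,
                     proj=None):
        """Clamp every cell inside the tube (rho + radius <= r(t)) over the
        laid path; the s-clamp of :meth:`project` already caps the tip."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s, rho, feet = proj if proj is not None else self.project(X)
        r = self.radius_at(t)
        if np.any(radii > r):
            raise GeometryError("gonad radius smaller than a cell radius")
        target = r - radii
        mask = rho > target
        if mask.any():
            units = self._radial_units(X[mask], s[mask], rho[mask], feet[mask])
            X = X.copy()
            X[mask] = feet[mask] + units * target[mask][:, None]
            rho = rho.copy()
            rho[mask] = target[mask]
        return X, s, rho

    def rachis_mask(self, s: np.ndarray) -> np.ndarray:
        """Cells subject to the rachis (hollow-core) constraint: the
        distal arm and turn; before the turn exists the whole (distal)
        tube qualifies."""
        if self.pre_turn_len is None:
            return np.ones(len(s), dtype=bool)
        return s >= self.pre_turn_len

    def enforce_rachis(self, X: np.ndarray, radii: np.ndarray, t: float,
                       proj=None):
        """Push distal-arm cells outward to line the tube wall, leaving a
        hollow core of radius r(t) - 2*radius.  Skipped (per cell) when the
        tube is thinner than two cell radii."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s, rho, feet = proj if proj is not None else self.project(X)
        r = self.radius_at(t)
        target = r - 2.0 * radii
        mask = self.rachis_mask(s) & (rho < target) & (target > 0)
        if mask.any():
            units = self._radial_units(X[mask], s[mask], rho[mask], feet[mask])
            X = X.copy()
            X[mask] = feet[mask] + units * target[mask][:, None]
            rho = rho.copy()
            rho[mask] = target[mask]
        return X, s, rho

    # ------------------------------------------------------------------
    def maybe_fix_turn(self, t: float):
        """At the prescribed turn time, freeze the pre-turn length at the
        DTC's current arclength (a paused DTC therefore turns closer to
        the center of the animal)."""
        if self.pre_turn_len is None and t >= self.spec.turn_time_hph:
            self.pre_turn_len = self.dtc_arclength

    def update_dtc(self, rate_um_per_h: float, dt: float,
                   max_cell_arclength: float, cell_diameter_um: float):
        """Advance the DTC by rate*dt, truncated so the gap to the
        distal-most germ cell never exceeds one cell diameter (migration
        pauses until proliferation catches up), and capped by the total
        migration budget."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        advance = rate_um_per_h * dt
        advance = min(advance,
                      self.spec.migration_budget_um - self.migrated_um)
        advance = max(0.0, advance)
        if self.spec.dtc_pausing:
            gap = self.dtc_arclength - max_cell_arclength
            advance = min(advance, max(0.0, cell_diameter_um - gap))
        self.dtc_arclength += advance
        self.migrated_um += advance
        return advance

    # ------------------------------------------------------------------
    def apply_stretch(self, t: float, dt: float):
        """Grow the path by moving the turn distally within the stretch
        window.  Returns a remap function s -> s' (identity outside the
        window) that the simulation uses to advect cells with the frame;
        the DTC arclength is remapped here.

        Both limbs lengthen by the turn displacement d_sigma, so the total
        path length grows by exactly 2*d_sigma.  Cells proximal of the
        turn advect with the stretching frame (they spread out as the
        proximal region lengthens); cells in the turn translate with it;
        cells on the distal limb keep their distance from the DTC, so
        they do not move in space at all and the new room opens just
        distal of the turn, where cells then flow to fill it.
        """
        spec = self.spec
        t0, t1 = spec.stretch_window
        if (not spec.stretch_enabled or self.pre_turn_len is None
                or not (t0 <= t < t1)):
            return None
        dsig = spec.stretch_rate_um_per_h * dt
        if dsig <= 0:
            return None
        P_old = self.pre_turn_len
        turn_end_old = P_old + np.pi * self.turn_radius
        arc_old = self.dtc_arclength
        P_new = P_old + dsig

        def remap(s):
            s = np.asarray(s, dtype=float)
            out = np.empty_like(s)
            prox = s <= P_old
            turn = (s > P_old) & (s <= turn_end_old)
            dist = s > turn_end_old
            out[prox] = s[prox] * (P_new / P_old) if P_old > 0 else s[prox]
            out[turn] = s[turn] + dsig
            # distal limb: pinned to the DTC frame (spatially unmoved)
            out[dist] = s[dist] + 2 * dsig
            return out

        self.pre_turn_len = P_new
        # the DTC rides the stretching frame exactly like the germ cells
        self.dtc_arclength = float(remap(np.array([arc_old]))[0])
        self.stretch_offset_um += dsig
        return remap
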