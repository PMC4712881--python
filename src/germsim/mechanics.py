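"""Center-based sphere mechanics.

Cells are deformable spheres; overlapping pairs repel along the line of
centers with a linear overlap spring (force magnitude k*delta).  Motion is
overdamped: positions integrate forward-Euler with x <- x + (F/drag)*dt.
Compression for the contact-inhibition feedback is measured by cutting a
spherical cap from the cell at the radical plane of each overlapping
neighbor and subtracting the cap volumes from the rest volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


class MechanicsError(Exception):
    """Unstable or degenerate mechanics configuration."""


@dataclass
class CellBody:
    id: int
    position: np.ndarray  # (3,) um
    radius: float  # um
    drag: float = 1.0  # force*hour/um

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0 or self.drag <= 0:
            raise ValueError("radius and drag must be positive")

    @property
    def rest_volume(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius ** 3


@dataclass
class ForceParams:
    stiffness_k: float = 60.0  # force/um
    dt_mech_h: float = 0.0025  # hours per mechanics substep
    neighbor_cutoff_um: float = 22.0  # >= 2 * max cell radius

    def __post_init__(self):
        if self.stiffness_k <= 0 or self.dt_mech_h <= 0:
            raise ValueError("stiffness and dt must be positive")


def _tie_break_direction(id_a: int, id_b: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector for coincident centers,
    derived from the id pair so both cells agree on the (opposite) axes."""
    rng = np.random.default_rng(np.uint64(1315423911) ^ np.uint64(
        (min(id_a, id_b) << 20) + max(id_a, id_b)))
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def pairwise_repulsion(a: CellBody, b: CellBody, p: ForceParams) -> np.ndarray:
    """Linear overlap spring: force on ``a`` (force on ``b`` is its exact
    negation)."""
    if a is b:
        raise ValueError("a and b must be distinct cells")
    sep = a.position - b.position
    dist = float(np.linalg.norm(sep))
    if dist == 0.0:
        u = _tie_break_direction(a.id, b.id)
        if a.id > b.id:
            u = -u
        return p.stiffness_k * (a.radius + b.radius) * u
    delta = a.radius + b.radius - dist
    if delta <= 0:
        return np.zeros(3)
    return p.stiffness_k * delta * (sep / dist)


def find_neighbors(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """All unordered index pairs with center distance < cutoff, as an
    (m, 2) int array.  Backed by a k-d tree; equivalent as a set to the
    all-pairs scan."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = np.asarray(positions, float)
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.int64)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    # query_pairs uses <=; the contract is strict <
    if len(pairs):
        d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]],
                           axis=1)
        pairs = pairs[d < cutoff]
    return pairs


def compute_forces(positions: np.ndarray, radii: np.ndarray,
                   ids: np.ndarray, p: ForceParams,
                   pairs: np.ndarray | None = None) -> np.ndarray:
    """Net repulsion force on every cell (vectorized over overlap pairs)."""
    n = len(positions)
    forces = np.zeros((n, 3))
    if n < 2:
        return forces
    if pairs is None:
        pairs = find_neighbors(positions, p.neighbor_cutoff_um)
    if not len(pairs):
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    sep = positions[i] - positions[j]
    dist = np.linalg.norm(sep, axis=1)
    overlap = radii[i] + radii[j] - dist
    mask = overlap > 0
    if not mask.any():
        return forces
    i, j, sep, dist, overlap = i[mask], j[mask], sep[mask], dist[mask], overlap[mask]
    zero = dist == 0.0
    if zero.any():
        for k in np.flatnonzero(zero):
            u = _tie_break_direction(int(ids[i[k]]), int(ids[j[k]]))
            if ids[i[k]] > ids[j[k]]:
                u = -u
            sep[k] = u
            dist[k] = 1.0
            overlap[k] = radii[i[k]] + radii[j[k]]
    f = (p.stiffness_k * overlap / dist)[:, None] * sep
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def integrate_positions(positions: np.ndarray, forces: np.ndarray,
                        drags: np.ndarray, radii: np.ndarray,
                        p: ForceParams) -> np.ndarray:
    """One overdamped forward-Euler substep.  Aborts if any cell would move
    further than half its own radius in one substep (time step too large
    for the current force scale; risks tunneling through neighbors)."""
    disp = forces / drags[:, None] * p.dt_mech_h
    if len(disp):
        norms = np.linalg.norm(disp, axis=1)
        bad = norms > 0.5 * radii
        if bad.any():
            k = int(np.argmax(norms / radii))
            raise MechanicsError(
                f"mechanics step displacement {norms[k]:.3f} um exceeds "
                f"half the cell radius {radii[k]:.3f} um; reduce dt_mech "
                f"or stiffness")
    return positions + disp


def _cap_heights(r_a: np.ndarray, r_b: np.ndarray,
                 dist: np.ndarray) -> np.ndarray:
    """Height of the spherical cap cut from sphere A by the radical plane
    of an overlapping sphere B (zero when not overlapping)."""
    h = np.zeros_like(dist)
    mask = (dist > 0) & (dist < r_a + r_b)
    if mask.any():
        d = dist[mask]
        x = (d * d + r_a[mask] ** 2 - r_b[mask] ** 2) / (2.0 * d)
        h[mask] = np.clip(r_a[mask] - x, 0.0, 2.0 * r_a[mask])
    # coincident centers: the whole sphere is contested; take a half cap
    coincident = (dist == 0)
    if coincident.any():
        h[coincident] = r_a[coincident]
    return h


def spherical_cap_volume(radius, height):
    radius = np.asarray(radius, float)
    height = np.asarray(height, float)
    return np.pi * height ** 2 * (3.0 * radius - height) / 3.0


def compressed_volume(cell: CellBody, neighbors) -> float:
    """Rest volume minus the radical-plane cap cut by each overlapping
    neighbor, clamped below at 5% of the rest volume."""
    rest = cell.rest_volume
    if not neighbors:
        return rest
    pos = np.array([n.position for n in neighbors])
    r_b = np.array([n.radius for n in neighbors])
    dist = np.linalg.norm(pos - cell.position, axis=1)
    r_a = np.full(len(neighbors), cell.radius)
    h = _cap_heights(r_a, r_b, dist)
    caps = spherical_cap_volume(r_a, h).sum()
    return max(0.05 * rest, rest - caps)


def volume_fractions(positions: np.ndarray, radii: np.ndarray,
                     pairs: np.ndarray) -> np.ndarray:
    """Compressed-volume fraction (compressed / rest) for every cell, from
    a precomputed overlap pair list.  Vectorized version of
    :func:`compressed_volume`."""
    n = len(positions)
    rest = (4.0 / 3.0) * np.pi * radii ** 3
    caps = np.zeros(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dist = np.linalg.norm(positions[i] - positions[j], axis=1)
        h_i = _cap_heights(radii[i], radii[j], dist)
        h_j = _cap_heights(radii[j], radii[i], dist)
        np.add.at(caps, i, spherical_cap_volume(radii[i], h_i))
        np.add.at(caps, j, spherical_cap_volume(radii[j], h_j))
    compressed = np.maximum(0.05 * rest, rest - caps)
    return compressed / rest
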