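"""Center-based sphere mechanics for the simulated cortical column.

Cells are spheres with a position, diameter, mass, adherence and an
interobject-force coefficient (overdamped, Cx3D-style conventions: the
"mass" divides the applied force, so heavy cells barely move).  Pair
interactions are piecewise linear in the surface gap: linear repulsion
in overlap, constant adhesion over a short range beyond contact, zero
further out.  The interobject-force coefficient of the less responsive
partner (the pair minimum) scales the interaction, which keeps the pair
force antisymmetric while letting migrating cells (coefficient 1e-4)
push settled marginal-zone cells by virtue of the mass asymmetry rather
than force asymmetry.

The neighbor index is a thin wrapper over a k-d tree with the exact
contract "all bodies with center distance <= r, excluding the querying
body"; a brute-force oracle in the test-suite pins that contract down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Body",
    "Bond",
    "Domain",
    "ForceConstants",
    "SpatialIndex",
    "neighbors_within",
    "pairwise_force",
    "pairwise_forces",
    "bond_forces",
    "integrate_step",
    "divide_body",
    "SimulationAbort",
]


class SimulationAbort(RuntimeError):
    """Raised when the mechanical state becomes non-finite."""


@dataclass
class Domain:
    """Simulated column; z is the radial (ventricle-to-pia) axis."""

    lx: float = 300.0
    ly: float = 300.0
    lz: float = 1400.0

    def contains(self, p) -> bool:
        p = np.asarray(p, dtype=float)
        return bool(
            (0.0 <= p[..., 0]) & (p[..., 0] <= self.lx)
            & (0.0 <= p[..., 1]) & (p[..., 1] <= self.ly)
            & (0.0 <= p[..., 2]) & (p[..., 2] <= self.lz)
        )


@dataclass
class Body:
    """Spherical cell body (positions in um, other attributes unitless)."""

    position: np.ndarray
    diameter: float
    mass: float = 1.0
    adherence: float = 1.0
    force_coefficient: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class Bond:
    """Hookean bond (spring constant 1, no damping) that breaks for good
    at 500% strain."""

    i: int
    j: int
    rest_length: float
    spring_constant: float = 1.0
    breaking_strain: float = 5.0
    broken: bool = False


@dataclass(frozen=True)
class ForceConstants:
    """Piecewise-linear pair-force law.

    ``k_rep`` scales the repulsion per um of overlap, ``k_adh`` is the
    constant adhesion magnitude inside the adhesion range ``g_max``
    (um beyond surface contact).  Values are chosen so a settled
    monolayer at the model's masses is mechanically stable.
    """

    k_rep: float = 2.0
    k_adh: float = 1.0
    g_max: float = 1.0


class SpatialIndex:
    """Neighbor queries over a set of body centers (k-d tree backed)."""

    def __init__(self, positions: np.ndarray):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self._tree = cKDTree(self.positions) if len(self.positions) else None

    def __len__(self) -> int:
        return len(self.positions)

    def neighbors_within(self, p, r: float, exclude: int | None = None) -> np.ndarray:
        """Sorted indices of bodies with center distance <= r from ``p``.

        ``exclude`` drops the querying body's own index.
        """
        if r <= 0:
            raise ValueError("radius must be positive")
        if self._tree is None:
            return np.empty(0, dtype=int)
        idx = np.asarray(sorted(self._tree.query_ball_point(np.asarray(p, float), r)), dtype=int)
        if exclude is not None:
            idx = idx[idx != exclude]
        return idx

    def neighbors_within_many(self, points: np.ndarray, r: float) -> list[np.ndarray]:
        if r <= 0:
            raise ValueError("radius must be positive")
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if self._tree is None:
            return [np.empty(0, dtype=int) for _ in range(len(points))]
        hits = self._tree.query_ball_point(points, r)
        return [np.asarray(sorted(h), dtype=int) for h in hits]

    def pairs_within(self, r: float) -> np.ndarray:
        """All index pairs (i < j) with center distance <= r, shape (m, 2)."""
        if self._tree is None:
            return np.empty((0, 2), dtype=int)
        pairs = self._tree.query_pairs(r, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty((0, 2), dtype=int)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        return pairs[order]


def neighbors_within(index: SpatialIndex, p, r: float, exclude: int | None = None) -> np.ndarray:
    """Functional alias of :meth:`SpatialIndex.neighbors_within`."""
    return index.neighbors_within(p, r, exclude=exclude)


def _separation_axis(delta: np.ndarray, i: int = 0, j: int = 1) -> np.ndarray:
    """Unit axis for a pair; deterministic fallback for coincident centers."""
    dist = float(np.linalg.norm(delta))
    if dist > 1e-12:
        return delta / dist
    logger.warning("coincident body centers (pair %d-%d); using deterministic jitter axis", i, j)
    k = (i * 2654435761 + j * 40503) % 360
    a = np.deg2rad(float(k))
    return np.array([np.cos(a) * 0.1, np.sin(a) * 0.1, 1.0]) / np.sqrt(1.01)


def pairwise_force(a: Body, b: Body, consts: ForceConstants = ForceConstants()) -> np.ndarray:
    """Force on body ``a`` from body ``b`` (antisymmetric)."""
    delta = a.position - b.position
    axis = _separation_axis(delta)
    dist = float(np.linalg.norm(delta))
    gap = dist - 0.5 * (a.diameter + b.diameter)
    fc = min(a.force_coefficient, b.force_coefficient)
    if gap < 0.0:
        return consts.k_rep * (-gap) * fc * axis
    if gap <= consts.g_max:
        adh = min(a.adherence, b.adherence)
        return -consts.k_adh * adh * fc * axis
    return np.zeros(3)


def pairwise_forces(positions: np.ndarray, diameters: np.ndarray, adherence: np.ndarray,
                    force_coeff: np.ndarray, pairs: np.ndarray,
                    consts: ForceConstants = ForceConstants()) -> np.ndarray:
    """Accumulated interaction forces for a list of candidate pairs.

    Vectorised population counterpart of :func:`pairwise_force`; pairs
    outside interaction range contribute nothing.
    """
    forces = np.zeros_like(positions)
    if len(pairs) == 0:
        return forces
    i, j = pairs[:, 0], pairs[:, 1]
    delta = positions[i] - positions[j]
    dist = np.linalg.norm(delta, axis=1)
    coincident = dist <= 1e-12
    if np.any(coincident):
        for k in np.flatnonzero(coincident):
            delta[k] = _separation_axis(delta[k], int(i[k]), int(j[k]))
        dist = np.where(coincident, 1.0, dist)
    axis = delta / dist[:, None]
    gap = dist - 0.5 * (diameters[i] + diameters[j])
    fc = np.minimum(force_coeff[i], force_coeff[j])
    mag = np.zeros_like(gap)
    overlap = gap < 0.0
    mag[overlap] = consts.k_rep * (-gap[overlap]) * fc[overlap]
    adhere = (gap >= 0.0) & (gap <= consts.g_max)
    mag[adhere] = -consts.k_adh * np.minimum(adherence[i], adherence[j])[adhere] * fc[adhere]
    fvec = mag[:, None] * axis
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    return forces


def bond_forces(positions: np.ndarray, bonds: list[Bond]) -> np.ndarray:
    """Spring forces from intact bonds; over-strained bonds break for good."""
    forces = np.zeros_like(positions)
    for bond in bonds:
        if bond.broken:
            continue
        delta = positions[bond.j] - positions[bond.i]
        length = float(np.linalg.norm(delta))
        if length > bond.breaking_strain * bond.rest_length:
            bond.broken = True
            continue
        if length <= 1e-12:
            continue
        f = bond.spring_constant * (length - bond.rest_length) * (delta / length)
        forces[bond.i] += f
        forces[bond.j] -= f
    return forces


def integrate_step(positions: np.ndarray, masses: np.ndarray, forces: np.ndarray,
                   dt: float, domain: Domain, max_displacement: float = 3.0) -> np.ndarray:
    """Overdamped update ``dx = (F / mass) dt`` with displacement capping.

    Lateral walls reflect; the ventricular floor (z=0) and the pial top
    (z=lz) clamp.
    """
    disp = forces / np.asarray(masses, dtype=float)[:, None] * dt
    if not np.all(np.isfinite(disp)):
        bad = np.flatnonzero(~np.all(np.isfinite(disp), axis=1))
        raise SimulationAbort(f"non-finite displacement for bodies {bad[:10].tolist()}")
    norms = np.linalg.norm(disp, axis=1)
    too_fast = norms > max_displacement
    if np.any(too_fast):
        disp[too_fast] *= (max_displacement / norms[too_fast])[:, None]
    new = positions + disp
    for ax, hi in ((0, domain.lx), (1, domain.ly)):
        new[:, ax] = np.abs(new[:, ax])              # reflect at 0
        over = new[:, ax] > hi
        new[over, ax] = 2.0 * hi - new[over, ax]     # reflect at wall
        np.clip(new[:, ax], 0.0, hi, out=new[:, ax])  # guard pathological speeds
    np.clip(new[:, 2], 0.0, domain.lz, out=new[:, 2])
    return new


def divide_body(b: Body, rng: np.random.Generator, domain: Domain | None = None,
                offset_fraction: float = 0.25) -> tuple[Body, Body]:
    """Volume-conserving division into two daughters.

    Daughter diameter is ``d / 2**(1/3)``; centers are displaced by
    ``+/- offset_fraction * daughter_radius`` along a uniformly random
    axis.  All other physical attributes are copied.
    """
    d_new = b.diameter / 2.0 ** (1.0 / 3.0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    offset = offset_fraction * 0.5 * d_new * axis
    p1, p2 = b.position + offset, b.position - offset
    if domain is not None:
        for p in (p1, p2):
            np.clip(p[:1], 0.0, domain.lx, out=p[:1])
            np.clip(p[1:2], 0.0, domain.ly, out=p[1:2])
            np.clip(p[2:], 0.0, domain.lz, out=p[2:])
    mk = lambda p: replace(b, position=p, diameter=d_new)
    return mk(p1), mk(p2)
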