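"""Conformational Gibbs free-energy functional on union-of-balls models.

A conformation is a CPK model: the union of van der Waals spheres.  The
functional is the sum of a volume term, a thin water-layer area term, a
hydrophobicity-class-weighted area term, and a pairwise Coulomb term.  Its
negative gradient decomposes into packing, aqueous and expansion forces.

Geometry is estimated numerically: boundary area by quasi-uniform sphere
point sampling (a point on one sphere is surface iff it lies outside every
other ball), volume by voxel counting.  Exact union-of-balls computational
geometry is deliberately out of proportion here; a closed-form two-sphere
oracle lives in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BallAtom",
    "BallModel",
    "GibbsParams",
    "SurfaceEstimate",
    "ForceDecomposition",
    "RelaxResult",
    "validate_omega_ordering",
    "estimate_geometry",
    "gibbs_terms",
    "gibbs_free_energy",
    "intrinsic_forces",
    "relax",
]


@dataclass(frozen=True)
class BallAtom:
    """One van der Waals ball: center (A), radius (A), hydrophobicity class
    index (1-based) and proton count."""

    center: Tuple[float, float, float]
    radius: float
    hclass: int = 1
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ball radius must be positive")
        if self.z < 0:
            raise ValueError("proton count must be >= 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class BallModel:
    """A union-of-balls conformation with ``class_count`` hydrophobicity classes."""

    atoms: Tuple[BallAtom, ...]
    class_count: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if not self.atoms:
            raise ValueError("model must contain at least one atom")
        if self.class_count < 1:
            raise ValueError("class_count must be >= 1")
        for a in self.atoms:
            if not (1 <= a.hclass <= self.class_count):
                raise ValueError(
                    f"hclass {a.hclass} outside 1..{self.class_count}"
                )

    @property
    def centers(self) -> np.ndarray:
        return np.array([a.center for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def with_centers(self, centers: np.ndarray) -> "BallModel":
        atoms = tuple(
            replace(a, center=tuple(c)) for a, c in zip(self.atoms, centers)
        )
        return BallModel(atoms=atoms, class_count=self.class_count)


@dataclass(frozen=True)
class GibbsParams:
    """Parameters of the functional.

    ``omega`` holds one per-class surface chemical potential per
    hydrophobicity class (energy/A^2), positive for hydrophobic classes and
    negative for hydrophilic ones.  None of these values are tabulated
    anywhere authoritative; the defaults are documented toy values.
    """

    omega_e: float = 0.01  # per-volume chemical potential of an electron
    d_w: float = 2.8  # water-molecule diameter, A
    omega: Tuple[float, ...] = (0.05, -0.05)
    coulomb_k: float = 0.0  # e^2/(4 pi eps) folded into one scalar
    n_surface_points: int = 960
    voxel_edge: float = 0.15  # A

    def __post_init__(self) -> None:
        if self.omega_e <= 0:
            raise ValueError("omega_e must be positive")
        if self.d_w < 0:
            raise ValueError("d_w must be >= 0")
        if self.n_surface_points < 8:
            raise ValueError("n_surface_points too small")
        if self.voxel_edge <= 0:
            raise ValueError("voxel_edge must be positive")
        object.__setattr__(self, "omega", tuple(float(w) for w in self.omega))


def validate_omega_ordering(omega: Sequence[float]) -> None:
    """Check the strict ordering omega_1 > ... > 0 > ... > omega_l.

    Classes are ordered most hydrophobic first; at least the sequence must be
    strictly decreasing and contain no exact zero.
    """
    omega = list(omega)
    for a, b in zip(omega, omega[1:]):
        if not a > b:
            raise ValueError(f"omega not strictly decreasing: {a} !> {b}")
    if any(w == 0 for w in omega):
        raise ValueError("omega values must be nonzero (sign encodes class)")


@dataclass(frozen=True)
class SurfaceEstimate:
    volume: float
    area_total: float
    area_by_class: Tuple[float, ...]
    n_surface_points: int
    voxel_edge: float
    n_ball_components: int


@dataclass(frozen=True)
class ForceDecomposition:
    """Per-atom 3-vectors (energy/A); total is the gradient of the full sum."""

    total: np.ndarray
    packing: np.ndarray
    aqueous: np.ndarray
    expansion: np.ndarray


@lru_cache(maxsize=16)
def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    theta = phi * k
    return np.column_stack((np.cos(theta) * r, y, np.sin(theta) * r))


def _ball_components(centers: np.ndarray, radii: np.ndarray) -> int:
    """Connected components of the ball-overlap graph (union-find)."""
    n = len(radii)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})


def exposed_fractions(m: BallModel, n_points: int) -> np.ndarray:
    """Fraction of each atom's sphere lying outside all other balls."""
    centers = m.centers
    radii = m.radii
    unit = _fibonacci_sphere(n_points)
    n = len(m.atoms)
    fractions = np.empty(n)
    for i in range(n):
        pts = centers[i] + radii[i] * unit
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            exposed &= d2 >= radii[j] ** 2
        fractions[i] = exposed.mean()
    return fractions


def _union_volume(m: BallModel, voxel_edge: float) -> float:
    centers = m.centers
    radii = m.radii
    lo = np.min(centers - radii[:, None], axis=0)
    hi = np.max(centers + radii[:, None], axis=0)
    counts = np.maximum(1, np.ceil((hi - lo) / voxel_edge).astype(int))
    axes = [lo[d] + (np.arange(counts[d]) + 0.5) * voxel_edge for d in range(3)]
    xs, ys = np.meshgrid(axes[0], axes[1], indexing="ij")
    inside_total = 0
    # slab over z to bound memory
    for z in axes[2]:
        inside = np.zeros(xs.shape, dtype=bool)
        for c, r in zip(centers, radii):
            d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (z - c[2]) ** 2
            inside |= d2 <= r * r
        inside_total += int(inside.sum())
    return inside_total * voxel_edge**3


def estimate_geometry(
    m: BallModel, p: GibbsParams | None = None
) -> SurfaceEstimate:
    """Numerical union volume, boundary area and per-class boundary areas.

    A sample point on atom i's sphere that survives all other balls belongs
    to the boundary, and is assigned to atom i's class (it lies on that
    ball's surface, distance zero - the nearest-set rule).  The per-class
    areas therefore partition the total exactly.
    """
    p = p or GibbsParams()
    fractions = exposed_fractions(m, p.n_surface_points)
    area_by_class = np.zeros(m.class_count)
    for atom, frac in zip(m.atoms, fractions):
        area_by_class[atom.hclass - 1] += frac * 4.0 * math.pi * atom.radius**2
    volume = _union_volume(m, p.voxel_edge)
    return SurfaceEstimate(
        volume=volume,
        area_total=float(area_by_class.sum()),
        area_by_class=tuple(area_by_class),
        n_surface_points=p.n_surface_points,
        voxel_edge=p.voxel_edge,
        n_ball_components=_ball_components(m.centers, m.radii),
    )


def _coulomb_energy(m: BallModel, p: GibbsParams) -> float:
    if p.coulomb_k == 0.0:
        return 0.0
    centers = m.centers
    zs = np.array([a.z for a in m.atoms])
    total = 0.0
    n = len(m.atoms)
    for i in range(n):
        for j in range(i + 1, n):
            if zs[i] == 0.0 or zs[j] == 0.0:
                continue
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d < 1e-9:
                raise ValueError(
                    f"coincident charged atoms {i} and {j}: Coulomb term singular"
                )
            total += zs[i] * zs[j] * p.coulomb_k / d
    return total


def gibbs_terms(
    m: BallModel,
    p: GibbsParams | None = None,
    geometry: Optional[SurfaceEstimate] = None,
) -> dict[str, float]:
    """The three term groups of the functional: packing, aqueous, expansion."""
    p = p or GibbsParams()
    if len(p.omega) < m.class_count:
        raise ValueError(
            f"params provide {len(p.omega)} omega values for "
            f"{m.class_count} classes"
        )
    geo = geometry or estimate_geometry(m, p)
    packing = p.omega_e * geo.volume + p.omega_e * p.d_w * geo.area_total
    aqueous = sum(
        w * a for w, a in zip(p.omega[: m.class_count], geo.area_by_class)
    )
    expansion = _coulomb_energy(m, p)
    return {"packing": packing, "aqueous": aqueous, "expansion": expansion}


def gibbs_free_energy(m: BallModel, p: GibbsParams | None = None) -> float:
    """G = omega_e V + omega_e d_w A + sum_i omega_i A_i + Coulomb."""
    terms = gibbs_terms(m, p)
    return terms["packing"] + terms["aqueous"] + terms["expansion"]


def hydrophobic_area(
    m: BallModel,
    p: GibbsParams | None = None,
    geometry: Optional[SurfaceEstimate] = None,
) -> float:
    """Total area of classes with positive surface chemical potential."""
    p = p or GibbsParams()
    geo = geometry or estimate_geometry(m, p)
    return sum(
        a
        for w, a in zip(p.omega[: m.class_count], geo.area_by_class)
        if w > 0
    )


def intrinsic_forces(
    m: BallModel, p: GibbsParams | None = None, h: float = 0.01
) -> ForceDecomposition:
    """Central-difference negative gradients of each term group.

    The ``total`` force is the finite difference of the summed functional at
    the same displaced configurations, so total = packing + aqueous +
    expansion holds to floating-point rounding by construction.
    """
    p = p or GibbsParams()
    if h <= 0:
        raise ValueError("finite-difference step must be positive")
    n = len(m.atoms)
    packing = np.zeros((n, 3))
    aqueous = np.zeros((n, 3))
    expansion = np.zeros((n, 3))
    total = np.zeros((n, 3))
    base_centers = m.centers
    for k in range(n):
        for d in range(3):
            plus = base_centers.copy()
            plus[k, d] += h
            minus = base_centers.copy()
            minus[k, d] -= h
            t_plus = gibbs_terms(m.with_centers(plus), p)
            t_minus = gibbs_terms(m.with_centers(minus), p)
            packing[k, d] = -(t_plus["packing"] - t_minus["packing"]) / (2 * h)
            aqueous[k, d] = -(t_plus["aqueous"] - t_minus["aqueous"]) / (2 * h)
            expansion[k, d] = -(t_plus["expansion"] - t_minus["expansion"]) / (2 * h)
            g_plus = t_plus["packing"] + t_plus["aqueous"] + t_plus["expansion"]
            g_minus = t_minus["packing"] + t_minus["aqueous"] + t_minus["expansion"]
            total[k, d] = -(g_plus - g_minus) / (2 * h)
    return ForceDecomposition(
        total=total, packing=packing, aqueous=aqueous, expansion=expansion
    )


@dataclass
class RelaxResult:
    models: List[BallModel]
    g_values: List[float]
    converged: bool
    stop_reason: str
    diverged: bool = False

    @property
    def initial(self) -> BallModel:
        return self.models[0]

    @property
    def final(self) -> BallModel:
        return self.models[-1]


def relax(
    m: BallModel,
    p: GibbsParams | None = None,
    step: float = 0.25,
    max_iters: int = 50,
    force_tol: float = 1e-3,
    h: float = 0.01,
    backtrack: bool = True,
    max_backtracks: int = 8,
) -> RelaxResult:
    """Gradient descent on atom centers using the intrinsic forces.

    ``step`` is the displacement (A) of the fastest-moving atom per accepted
    iteration; backtracking halves it until G does not increase.  With
    backtracking enabled the G sequence is nonincreasing by construction.
    Without it, five consecutive G increases are reported as divergence.
    """
    p = p or GibbsParams()
    if step <= 0:
        raise ValueError("step must be positive")
    current = m
    g_values = [gibbs_free_energy(current, p)]
    models = [current]
    increases = 0
    for _ in range(max_iters):
        forces = intrinsic_forces(current, p, h=h).total
        max_norm = float(np.max(np.linalg.norm(forces, axis=1)))
        if max_norm < force_tol:
            return RelaxResult(models, g_values, True, "force tolerance reached")
        direction = forces * (step / max_norm)
        if backtrack:
            scale = 1.0
            accepted = None
            for _ in range(max_backtracks):
                cand = current.with_centers(current.centers + scale * direction)
                g_cand = gibbs_free_energy(cand, p)
                if g_cand <= g_values[-1]:
                    accepted = (cand, g_cand)
                    break
                scale *= 0.5
            if accepted is None:
                return RelaxResult(
                    models, g_values, True, "no descent direction left"
                )
            current, g_new = accepted
        else:
            current = current.with_centers(current.centers + direction)
            g_new = gibbs_free_energy(current, p)
            if g_new > g_values[-1]:
                increases += 1
                if increases >= 5:
                    result = RelaxResult(
                        models + [current],
                        g_values + [g_new],
                        False,
                        "diverged: G increased 5 consecutive steps",
                    )
                    result.diverged = True
                    return result
            else:
                increases = 0
        models.append(current)
        g_values.append(g_new)
    return RelaxResult(models, g_values, False, "iteration cap reached")
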