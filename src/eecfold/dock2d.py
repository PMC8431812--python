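"""Two-rule 2D hydrophobic-patch docking.

Subunit binding surfaces are represented as labelled pixel grids.  Docking
searches rotations and integer translations of one (internally mirrored)
patch over the other; a placement's score is the number of pixels
hydrophobic in both images (rule 1), and it is feasible when enough
donor/acceptor pixel pairs sit within a small Chebyshev radius of each
other (rule 2).  Placement only, in two dimensions; no 3D rigid bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .gibbs_surface import BallModel
from .gibbs_surface import exposed_fractions as _exposed_fractions

__all__ = [
    "EMPTY",
    "HYDROPHOBIC",
    "DONOR",
    "ACCEPTOR",
    "HYDROPHILIC",
    "LABELS",
    "PatchImage",
    "DockingPlacement",
    "DockResult",
    "project_patch",
    "dock_images",
    "principal_axis",
]

EMPTY, HYDROPHOBIC, DONOR, ACCEPTOR, HYDROPHILIC = 0, 1, 2, 3, 4
LABELS = {
    EMPTY: "EMPTY",
    HYDROPHOBIC: "HYDROPHOBIC",
    DONOR: "DONOR",
    ACCEPTOR: "ACCEPTOR",
    HYDROPHILIC: "HYDROPHILIC",
}


@dataclass(frozen=True)
class PatchImage:
    """H x W grid of surface labels at a fixed spacing (A per pixel)."""

    grid: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.int8)
        if grid.ndim != 2:
            raise ValueError("patch grid must be 2-D")
        if not np.isin(grid, list(LABELS)).all():
            raise ValueError("patch grid contains labels outside 0..4")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "grid", grid)

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.grid != EMPTY))


@dataclass(frozen=True)
class DockingPlacement:
    """One evaluated placement of patch b onto patch a.

    ``rotation`` is CCW degrees applied to the mirrored b; (dx, dy) place
    the rotated grid's origin at column dx, row dy of a's grid.
    """

    rotation: float
    flipped: bool
    dx: int
    dy: int
    hydrophobic_overlap: int
    hb_contacts: int
    feasible: bool


@dataclass
class DockResult:
    """Ranked feasible placements plus diagnostics.

    Zero feasible placements (``n_feasible == 0``) is distinct from zero
    hydrophobic overlap: ``best_score_any`` reports the best score over the
    whole search space regardless of the donor/acceptor constraint.
    """

    placements: List[DockingPlacement]
    n_evaluated: int
    n_feasible: int
    best_score_any: int

    @property
    def best(self) -> Optional[DockingPlacement]:
        return self.placements[0] if self.placements else None


def principal_axis(m: BallModel) -> np.ndarray:
    """Smallest-variance principal axis of the atom centers (auto projection
    axis helper; the projection axis is normally user-supplied)."""
    centers = m.centers
    if len(centers) < 2:
        return np.array([0.0, 0.0, 1.0])
    cov = np.cov((centers - centers.mean(axis=0)).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    return eigvecs[:, 0]


def _orthonormal_basis(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def project_patch(
    m: BallModel,
    axis: Sequence[float],
    spacing: float = 1.0,
    donors: Set[int] = frozenset(),
    acceptors: Set[int] = frozenset(),
    hydrophobic_classes: Set[int] = frozenset({1}),
    n_exposure_points: int = 240,
) -> PatchImage:
    """Orthographic projection of a ball model along ``axis``.

    Every pixel takes the label of the frontmost surface-exposed atom whose
    projected disc covers it (z-buffer, larger depth = closer to viewer).
    Hydrophobic-class atoms label HYDROPHOBIC; atoms flagged as hydrogen-bond
    donors or acceptors label DONOR/ACCEPTOR; everything else HYDROPHILIC.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("projection axis must be nonzero")
    axis = axis / norm
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    u, v = _orthonormal_basis(axis)
    centers = m.centers
    radii = m.radii
    exposed = _exposed_fractions(m, n_exposure_points) > 0
    us = centers @ u
    vs = centers @ v
    depth = centers @ axis
    lo_u = np.min(us - radii)
    hi_u = np.max(us + radii)
    lo_v = np.min(vs - radii)
    hi_v = np.max(vs + radii)
    width = max(1, int(math.ceil((hi_u - lo_u) / spacing)))
    height = max(1, int(math.ceil((hi_v - lo_v) / spacing)))
    grid = np.full((height, width), EMPTY, dtype=np.int8)
    zbuf = np.full((height, width), -np.inf)
    for idx in range(len(m.atoms)):
        if not exposed[idx]:
            continue
        atom = m.atoms[idx]
        if atom.hclass in hydrophobic_classes:
            label = HYDROPHOBIC
        elif idx in donors:
            label = DONOR
        elif idx in acceptors:
            label = ACCEPTOR
        else:
            label = HYDROPHILIC
        r_px = atom.radius / spacing
        cu = (us[idx] - lo_u) / spacing
        cv = (vs[idx] - lo_v) / spacing
        row_lo = max(0, int(math.floor(cv - r_px)))
        row_hi = min(height, int(math.ceil(cv + r_px)) + 1)
        col_lo = max(0, int(math.floor(cu - r_px)))
        col_hi = min(width, int(math.ceil(cu + r_px)) + 1)
        for row in range(row_lo, row_hi):
            for col in range(col_lo, col_hi):
                du = col + 0.5 - cu
                dv = row + 0.5 - cv
                rho2 = du * du + dv * dv
                if rho2 > r_px * r_px:
                    continue
                z = depth[idx] + atom.radius * math.sqrt(
                    max(0.0, 1.0 - rho2 / (r_px * r_px))
                )
                if z > zbuf[row, col]:
                    zbuf[row, col] = z
                    grid[row, col] = label
    return PatchImage(grid=grid, spacing=spacing)


def rotate_grid(grid: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate CCW; exact for multiples of 90, nearest-neighbour otherwise."""
    degrees = degrees % 360.0
    if abs(degrees - round(degrees / 90.0) * 90.0) < 1e-9:
        return np.rot90(grid, k=int(round(degrees / 90.0)) % 4)
    theta = math.radians(degrees)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    h, w = grid.shape
    # rows grow downward: CCW in conventional axes is CW in array indices
    corners = []
    for r in (0.0, h):
        for c in (0.0, w):
            corners.append(
                (c * cos_t + r * sin_t, -c * sin_t + r * cos_t)
            )
    xs = [p[0] for p in corners]
    ys = [p[1] for p in corners]
    out_w = max(1, int(math.ceil(max(xs) - min(xs))))
    out_h = max(1, int(math.ceil(max(ys) - min(ys))))
    x0, y0 = min(xs), min(ys)
    out = np.full((out_h, out_w), EMPTY, dtype=grid.dtype)
    rows, cols = np.meshgrid(
        np.arange(out_h) + 0.5, np.arange(out_w) + 0.5, indexing="ij"
    )
    x = cols + x0
    y = rows + y0
    src_c = x * cos_t - y * sin_t
    src_r = x * sin_t + y * cos_t
    src_ci = np.floor(src_c).astype(int)
    src_ri = np.floor(src_r).astype(int)
    ok = (src_ri >= 0) & (src_ri < h) & (src_ci >= 0) & (src_ci < w)
    out[ok] = grid[src_ri[ok], src_ci[ok]]
    return out


def _window_counts_fast(mask: np.ndarray, radius: int) -> np.ndarray:
    """Padded sliding-window counts: entry [i+r, j+r] is the number of true
    cells of ``mask`` within Chebyshev distance ``radius`` of cell (i, j),
    defined for i in [-r, h-1+r] and j in [-r, w-1+r]."""
    h, w = mask.shape
    pad = 2 * radius
    padded = np.zeros((h + 2 * pad, w + 2 * pad), dtype=np.int32)
    padded[pad : pad + h, pad : pad + w] = mask
    csum = np.pad(padded.cumsum(axis=0).cumsum(axis=1), ((1, 0), (1, 0)))
    size = 2 * radius + 1
    oh, ow = h + pad, w + pad
    r0 = np.arange(oh)
    c0 = np.arange(ow)
    # window at output (i, j) covers padded rows i..i+size-1, cols j..j+size-1
    top = csum[r0[:, None] + size, c0[None, :] + size]
    out = (
        top
        - csum[r0[:, None], c0[None, :] + size]
        - csum[r0[:, None] + size, c0[None, :]]
        + csum[r0[:, None], c0[None, :]]
    )
    return out.astype(np.int32)


def dock_images(
    a: PatchImage,
    b: PatchImage,
    rotation_step: float = 5.0,
    min_hb: int = 3,
    hb_radius_px: int = 1,
    rotations: Optional[Sequence[float]] = None,
) -> DockResult:
    """Exhaustive placement search of patch ``b`` onto patch ``a``.

    ``b`` is mirrored internally so the two facing surfaces meet, then every
    rotation (``rotations`` or multiples of ``rotation_step``) and every
    integer translation with bounding-box overlap is scored.  Feasible
    placements (donor/acceptor pairs >= ``min_hb``) are returned sorted by
    hydrophobic overlap descending, ties broken by (rotation, dx, dy).
    """
    if abs(a.spacing - b.spacing) > 1e-9:
        raise ValueError("patch spacings differ")
    if a.n_occupied == 0 or b.n_occupied == 0:
        raise ValueError("empty patch")
    if rotations is None:
        n_steps = int(round(360.0 / rotation_step))
        rotations = [i * rotation_step for i in range(n_steps)]
    mirrored = np.fliplr(b.grid)
    a_hydro = a.grid == HYDROPHOBIC
    a_donor = a.grid == DONOR
    a_acceptor = a.grid == ACCEPTOR
    ha, wa = a.grid.shape
    r = hb_radius_px
    feasible: List[DockingPlacement] = []
    n_evaluated = 0
    best_score_any = 0
    for theta in rotations:
        c = rotate_grid(mirrored, theta)
        c_hydro = c == HYDROPHOBIC
        c_donor = c == DONOR
        c_acceptor = c == ACCEPTOR
        don_counts = _window_counts_fast(c_donor, r)
        acc_counts = _window_counts_fast(c_acceptor, r)
        hc, wc = c.shape
        for dy in range(-(hc - 1), ha):
            a_r0, a_r1 = max(0, dy), min(ha, dy + hc)
            c_r0 = a_r0 - dy
            c_r1 = a_r1 - dy
            for dx in range(-(wc - 1), wa):
                a_c0, a_c1 = max(0, dx), min(wa, dx + wc)
                c_c0 = a_c0 - dx
                c_c1 = a_c1 - dx
                n_evaluated += 1
                score = int(
                    np.count_nonzero(
                        a_hydro[a_r0:a_r1, a_c0:a_c1]
                        & c_hydro[c_r0:c_r1, c_c0:c_c1]
                    )
                )
                if score > best_score_any:
                    best_score_any = score
                # donor/acceptor pairs within Chebyshev radius r; the padded
                # window-count grids let a-pixels just outside c still see
                # nearby c-pixels
                ae_r0, ae_r1 = max(0, dy - r), min(ha, dy + hc + r)
                ae_c0, ae_c1 = max(0, dx - r), min(wa, dx + wc + r)
                hb = 0
                if ae_r1 > ae_r0 and ae_c1 > ae_c0:
                    sub_d = a_donor[ae_r0:ae_r1, ae_c0:ae_c1]
                    sub_a = a_acceptor[ae_r0:ae_r1, ae_c0:ae_c1]
                    if sub_d.any() or sub_a.any():
                        p_r0 = ae_r0 - dy + r
                        p_c0 = ae_c0 - dx + r
                        acc_win = acc_counts[
                            p_r0 : p_r0 + (ae_r1 - ae_r0),
                            p_c0 : p_c0 + (ae_c1 - ae_c0),
                        ]
                        don_win = don_counts[
                            p_r0 : p_r0 + (ae_r1 - ae_r0),
                            p_c0 : p_c0 + (ae_c1 - ae_c0),
                        ]
                        hb = int((sub_d * acc_win).sum() + (sub_a * don_win).sum())
                if hb >= min_hb:
                    feasible.append(
                        DockingPlacement(
                            rotation=float(theta),
                            flipped=True,
                            dx=dx,
                            dy=dy,
                            hydrophobic_overlap=score,
                            hb_contacts=hb,
                            feasible=True,
                        )
                    )
    feasible.sort(key=lambda pl: (-pl.hydrophobic_overlap, pl.rotation, pl.dx, pl.dy))
    return DockResult(
        placements=feasible,
        n_evaluated=n_evaluated,
        n_feasible=len(feasible),
        best_score_any=best_score_any,
    )
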