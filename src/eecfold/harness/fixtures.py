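"""Synthetic fixture generation: sequences with planted motifs, ball
clusters, and complementary 2-D patch pairs with a recorded transform.

All generators are pure functions of their spec/seed.  The sequence motifs
are built so that their true labels follow the prediction rules exactly:

* strand: alternating fully-hydrophobic letters and T (even offsets carry
  the hydrophobic face), starts and ends hydrophobic;
* helix: repeats of the L,A,E,E cycle (dense interval-2/3 attraction);
* turn_linker: blocking-group runs (GG, PG, NG, GPG, ...);
* coil: isolated D/N/S interleaved with T so no blocking run and no
  attraction edge forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from ..dock2d import (
    ACCEPTOR,
    DONOR,
    EMPTY,
    HYDROPHOBIC,
    HYDROPHILIC,
    PatchImage,
    dock_images,
    rotate_grid,
)
from ..gibbs_surface import BallAtom, BallModel
from ..residue_model import AMINO_ACIDS

__all__ = [
    "FixtureSpec",
    "PlantedTransform",
    "generate_sequence",
    "generate_corpus",
    "generate_ball_cluster",
    "generate_patch_pair",
]

MOTIF_KINDS = ("strand", "helix", "turn_linker", "coil")

_STRAND_HYDRO = "LVIF"
_HELIX_CYCLE = "LAEE"
_COIL_POLAR = "DNS"
_LINKER_PAIRS = ("GG", "PG", "NG")


@dataclass(frozen=True)
class FixtureSpec:
    """Plan of (motif kind, length) blocks plus seed and mutation rate."""

    plan: Tuple[Tuple[str, int], ...]
    seed: int = 0
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan", tuple((k, int(n)) for k, n in self.plan))
        for kind, length in self.plan:
            if kind not in MOTIF_KINDS:
                raise ValueError(f"unknown motif kind {kind!r}")
            if length < 1:
                raise ValueError("motif lengths must be >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")


def _strand_motif(length: int, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(list(_STRAND_HYDRO)) if i % 2 == 0 else "T"
        for i in range(length)
    )


def _helix_motif(length: int, rng: np.random.Generator) -> str:
    return "".join(_HELIX_CYCLE[i % 4] for i in range(length))


def _linker_motif(length: int, rng: np.random.Generator) -> str:
    if length == 2:
        return str(rng.choice(list(_LINKER_PAIRS)))
    if length == 3:
        return "GPG"
    # longer linkers: glycine-rich blocking run
    return "".join(str(rng.choice(list("GNS"))) for _ in range(length))


def _coil_motif(length: int, rng: np.random.Generator) -> str:
    # T at even offsets (and always at the end) keeps every blocking residue
    # isolated, so a coil never fuses with a neighbouring blocking run
    return "".join(
        "T" if (i % 2 == 0 or i == length - 1) else str(rng.choice(list(_COIL_POLAR)))
        for i in range(length)
    )


_MOTIF_BUILDERS = {
    "strand": (_strand_motif, "E"),
    "helix": (_helix_motif, "H"),
    "turn_linker": (_linker_motif, "T"),
    "coil": (_coil_motif, "C"),
}


def generate_sequence(spec: FixtureSpec) -> Tuple[str, str]:
    """Return (sequence, true per-residue labels) for a fixture spec.

    With a positive mutation rate each position is substituted (to a
    different letter) with that probability; the labels are kept from the
    clean sequence.
    """
    rng = np.random.default_rng(spec.seed)
    seq_parts: List[str] = []
    label_parts: List[str] = []
    for kind, length in spec.plan:
        builder, label = _MOTIF_BUILDERS[kind]
        seq_parts.append(builder(length, rng))
        label_parts.append(label * length)
    seq = "".join(seq_parts)
    if spec.mutation_rate > 0:
        letters = list(seq)
        for pos in range(len(letters)):
            if rng.random() < spec.mutation_rate:
                options = [aa for aa in AMINO_ACIDS if aa != letters[pos]]
                letters[pos] = str(rng.choice(options))
        seq = "".join(letters)
    return seq, "".join(label_parts)


def generate_corpus(
    n_sequences: int, seed: int = 0, mutation_rate: float = 0.0
) -> List[Tuple[str, str]]:
    """Random multi-motif sequences: structured blocks separated by linkers."""
    rng = np.random.default_rng(seed)
    corpus = []
    for idx in range(n_sequences):
        n_blocks = int(rng.integers(2, 6))
        plan: List[Tuple[str, int]] = []
        for b in range(n_blocks):
            kind = str(rng.choice(["strand", "helix", "coil"]))
            if kind == "strand":
                length = int(rng.integers(5, 11))
            elif kind == "helix":
                length = int(rng.integers(6, 13))
            else:
                length = int(rng.integers(5, 10))
            plan.append((kind, length))
            if b < n_blocks - 1:
                plan.append(("turn_linker", int(rng.integers(2, 4))))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        corpus.append(
            generate_sequence(
                FixtureSpec(
                    plan=tuple(plan), seed=sub_seed, mutation_rate=mutation_rate
                )
            )
        )
    return corpus


def generate_ball_cluster(
    n: int,
    seed: int = 0,
    box: float = 6.0,
    radius_range: Tuple[float, float] = (1.4, 2.0),
    charged: bool = False,
) -> BallModel:
    """A random cluster of n balls with mixed hydrophobicity classes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    atoms = []
    for _ in range(n):
        center = tuple(rng.uniform(-box / 2, box / 2, size=3))
        radius = float(rng.uniform(*radius_range))
        hclass = int(rng.integers(1, 3))
        z = float(rng.integers(1, 9)) if charged else 0.0
        atoms.append(BallAtom(center=center, radius=radius, hclass=hclass, z=z))
    return BallModel(atoms=tuple(atoms), class_count=2)


@dataclass(frozen=True)
class PlantedTransform:
    """The transform hidden in a generated patch pair, in the docking
    search's own parametrization."""

    rotation: float
    dx: int
    dy: int
    score: int
    n_hb: int


def _random_blob(
    rng: np.random.Generator, size: int, target: int
) -> np.ndarray:
    """Connected random-walk blob mask of about ``target`` cells."""
    mask = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    mask[r, c] = True
    steps = 0
    while mask.sum() < target and steps < 50 * target:
        steps += 1
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(rng.integers(4))]
        r2, c2 = r + dr, c + dc
        if 1 <= r2 < size - 1 and 1 <= c2 < size - 1:
            r, c = r2, c2
            mask[r, c] = True
    return mask


def generate_patch_pair(
    seed: int = 0,
    size: int = 12,
    n_hb: int = 3,
    rotations: Sequence[float] = (0.0, 90.0, 180.0, 270.0),
    max_attempts: int = 50,
) -> Tuple[PatchImage, PatchImage, PlantedTransform]:
    """A complementary patch pair with a recorded planted transform.

    One hydrophobic blob is stamped into both facing patches; ``n_hb``
    matched donor (patch a) / acceptor (patch b) pixels are planted at
    coincident docked positions; then the recorded rotation is undone and
    the image mirrored, exactly inverting what the docking search applies.
    The generator retries until the planted placement is the strict argmax,
    so recovery is well-posed.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        blob = _random_blob(rng, size, target=int(0.4 * size * size))
        cells = np.argwhere(blob)
        if len(cells) < n_hb + 4:
            continue
        picks = cells[rng.choice(len(cells), size=n_hb, replace=False)]
        grid_a = np.full((size, size), EMPTY, dtype=np.int8)
        grid_a[blob] = HYDROPHOBIC
        b_dock = grid_a.copy()
        for rr, cc in picks:
            grid_a[rr, cc] = DONOR
            b_dock[rr, cc] = ACCEPTOR
        # a couple of hydrophilic pixels outside the blob for realism
        outside = np.argwhere(~blob)
        for rr, cc in outside[rng.choice(len(outside), size=3, replace=False)]:
            grid_a[rr, cc] = HYDROPHILIC
        theta = float(rng.choice(list(rotations)))
        rows = np.where(blob.any(axis=1))[0]
        cols = np.where(blob.any(axis=0))[0]
        local = b_dock[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        planted = PlantedTransform(
            rotation=theta,
            dx=int(cols[0]),
            dy=int(rows[0]),
            score=int(blob.sum()) - n_hb,
            n_hb=n_hb,
        )
        b_image = np.fliplr(rotate_grid(local, -theta))
        patch_a = PatchImage(grid=grid_a)
        patch_b = PatchImage(grid=b_image)
        result = dock_images(
            patch_a, patch_b, rotations=rotations, min_hb=0, hb_radius_px=1
        )
        top = result.placements
        if not top:
            continue
        best = top[0]
        unique = len(top) < 2 or top[1].hydrophobic_overlap < best.hydrophobic_overlap
        recovered = (
            best.rotation == planted.rotation
            and best.dx == planted.dx
            and best.dy == planted.dy
            and best.hydrophobic_overlap == planted.score
        )
        if unique and recovered and best.hb_contacts >= n_hb:
            return patch_a, patch_b, planted
    raise RuntimeError(f"could not plant a unique patch pair for seed {seed}")
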