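"""Side-chain hydrophobicity classes and the pairwise lateral-attraction rule.

Each of the 20 standard amino acids is assigned to one of seven classes
describing the hydrophobic portion of its side-chain.  From those classes a
deterministic, symmetric 20x20 verdict table is derived that says whether two
side-chains at small sequence separation can laterally attract each other
through their hydrophobic portions.  Everything downstream (attraction
graphs, secondary-structure calls, survey statistics) consumes this table.

The default table can be replaced by a user-supplied 20x20 matrix file, see
:func:`load_attraction_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Tuple

__all__ = [
    "AMINO_ACIDS",
    "HydroLabel",
    "ResidueClass",
    "InteractionVerdict",
    "UnknownResidueError",
    "classify_residue",
    "is_rb",
    "lateral_attraction",
    "verdict_table",
    "format_verdict_table",
    "load_attraction_matrix",
]

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class HydroLabel(str, Enum):
    """Category of the hydrophobic portion of a side-chain."""

    FULL_HYDROPHOBIC = "FULL_HYDROPHOBIC"
    LONG_AMPHIPATHIC = "LONG_AMPHIPATHIC"
    LIMITED_POLAR = "LIMITED_POLAR"
    ALANINE = "ALANINE"
    NEGLIGIBLE = "NEGLIGIBLE"
    PROLINE = "PROLINE"
    SHORT_POLAR = "SHORT_POLAR"


class InteractionVerdict(str, Enum):
    """Binary outcome of the lateral-attraction decision table."""

    ATTRACT = "ATTRACT"
    NONE = "NONE"


class UnknownResidueError(ValueError):
    """Raised for any letter outside the 20 standard amino acids."""

    def __init__(self, aa: str, position: Optional[int] = None):
        self.aa = aa
        self.position = position
        msg = f"unknown residue letter {aa!r}"
        if position is not None:
            msg += f" at position {position}"
        super().__init__(msg)


@dataclass(frozen=True)
class ResidueClass:
    """Per-residue classification record.

    Attributes
    ----------
    aa : str
        One-letter amino-acid code.
    label : HydroLabel
        Hydrophobic-portion category.
    has_backbone_nh : bool
        False only for proline, which lacks the backbone N-H donor.
    is_rb : bool
        Member of the hydrophobic-blocking group {D, N, S, P, G}.
    hydrophobic_reach : int
        Ordinal extent of the hydrophobic portion: 0 none, 1 short, 2 long.
    """

    aa: str
    label: HydroLabel
    has_backbone_nh: bool
    is_rb: bool
    hydrophobic_reach: int


_LABEL_OF = {}
for _aa in "CILMWFYV":
    _LABEL_OF[_aa] = HydroLabel.FULL_HYDROPHOBIC
for _aa in "RHKEQ":
    _LABEL_OF[_aa] = HydroLabel.LONG_AMPHIPATHIC
for _aa in "DN":
    _LABEL_OF[_aa] = HydroLabel.LIMITED_POLAR
_LABEL_OF["A"] = HydroLabel.ALANINE
_LABEL_OF["G"] = HydroLabel.NEGLIGIBLE
_LABEL_OF["P"] = HydroLabel.PROLINE
for _aa in "ST":
    _LABEL_OF[_aa] = HydroLabel.SHORT_POLAR

_RB_SET = frozenset("DNSPG")

_REACH_OF_LABEL = {
    HydroLabel.FULL_HYDROPHOBIC: 2,
    HydroLabel.LONG_AMPHIPATHIC: 2,
    HydroLabel.LIMITED_POLAR: 1,
    HydroLabel.ALANINE: 1,
    HydroLabel.NEGLIGIBLE: 0,
    HydroLabel.PROLINE: 1,
    HydroLabel.SHORT_POLAR: 1,
}

_CLASSES: dict[str, ResidueClass] = {
    aa: ResidueClass(
        aa=aa,
        label=_LABEL_OF[aa],
        has_backbone_nh=(aa != "P"),
        is_rb=(aa in _RB_SET),
        hydrophobic_reach=_REACH_OF_LABEL[_LABEL_OF[aa]],
    )
    for aa in AMINO_ACIDS
}


def classify_residue(aa: str, position: Optional[int] = None) -> ResidueClass:
    """Return the :class:`ResidueClass` for a one-letter amino-acid code.

    Raises :class:`UnknownResidueError` for anything outside the 20 standard
    letters (including B, J, O, U, X, Z); non-standard codes are never
    silently coerced.
    """
    try:
        return _CLASSES[aa]
    except KeyError:
        raise UnknownResidueError(aa, position) from None


def is_rb(aa: str) -> bool:
    """True iff ``aa`` belongs to the hydrophobic-blocking group {D,N,S,P,G}."""
    return classify_residue(aa).is_rb


# Classes whose members never take part in a lateral hydrophobic contact:
# glycine has no hydrophobic portion worth speaking of, aspartate/asparagine
# expose too little of theirs, and proline is excluded by its backbone.
_EXCLUDED_LABELS = frozenset(
    {HydroLabel.NEGLIGIBLE, HydroLabel.LIMITED_POLAR, HydroLabel.PROLINE}
)
_T_PARTNERS = frozenset({HydroLabel.FULL_HYDROPHOBIC, HydroLabel.ALANINE})


def _default_attracts(a: str, b: str) -> bool:
    ca, cb = _CLASSES[a], _CLASSES[b]
    if ca.label in _EXCLUDED_LABELS or cb.label in _EXCLUDED_LABELS:
        return False
    # serine is a blocking-group member despite sharing a class with threonine
    if a == "S" or b == "S":
        return False
    if ca.hydrophobic_reach < 1 or cb.hydrophobic_reach < 1:
        return False
    # threonine's single methyl is a weak attractor: strongly hydrophobic or
    # alanine partners only
    if a == "T":
        return cb.label in _T_PARTNERS
    if b == "T":
        return ca.label in _T_PARTNERS
    return True


def lateral_attraction(
    aa1: str,
    aa2: str,
    matrix: Optional[Mapping[Tuple[str, str], bool]] = None,
) -> InteractionVerdict:
    """Symmetric verdict on whether two side-chains can laterally attract.

    Parameters
    ----------
    aa1, aa2 : str
        One-letter amino-acid codes.
    matrix : mapping, optional
        Override table mapping ordered letter pairs to booleans, as produced
        by :func:`load_attraction_matrix`.  When given it replaces the
        built-in rule entirely.
    """
    classify_residue(aa1)
    classify_residue(aa2)
    if matrix is not None:
        hit = matrix.get((aa1, aa2))
        if hit is None:
            hit = matrix.get((aa2, aa1), False)
        return InteractionVerdict.ATTRACT if hit else InteractionVerdict.NONE
    if _default_attracts(aa1, aa2):
        return InteractionVerdict.ATTRACT
    return InteractionVerdict.NONE


def verdict_table(
    matrix: Optional[Mapping[Tuple[str, str], bool]] = None,
) -> dict[Tuple[str, str], InteractionVerdict]:
    """The full 20x20 verdict table as a dict over ordered letter pairs."""
    return {
        (a, b): lateral_attraction(a, b, matrix=matrix)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
    }


def format_verdict_table(
    matrix: Optional[Mapping[Tuple[str, str], bool]] = None,
) -> str:
    """Render the verdict table as comma-separated 1/0 rows.

    Rows and columns are in alphabetical one-letter order; the first row and
    column carry the letters.  The same layout is accepted back by
    :func:`load_attraction_matrix` (minus the header row/column).
    """
    table = verdict_table(matrix=matrix)
    lines = ["," + ",".join(AMINO_ACIDS)]
    for a in AMINO_ACIDS:
        cells = [
            "1" if table[(a, b)] is InteractionVerdict.ATTRACT else "0"
            for b in AMINO_ACIDS
        ]
        lines.append(a + "," + ",".join(cells))
    return "\n".join(lines) + "\n"


def load_attraction_matrix(path: str | Path) -> dict[Tuple[str, str], bool]:
    """Read a 20x20 replacement matrix: comma-separated 1/0 cells.

    Rows and columns are in alphabetical one-letter order (ACDEFGHIKLMNPQRSTVWY).
    An optional header row/column of letters is tolerated and checked.
    The matrix must be symmetric.
    """
    raw = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    rows = [r.split(",") for r in raw]
    # strip an optional header row / label column
    if rows and rows[0] and rows[0][-1].strip().upper() == "Y":
        rows = rows[1:]
    rows = [
        r[1:] if r and r[0].strip().upper() in AMINO_ACIDS and len(r) == 21 else r
        for r in rows
    ]
    if len(rows) != 20 or any(len(r) != 20 for r in rows):
        raise ValueError(f"attraction matrix in {path} is not 20x20")
    out: dict[Tuple[str, str], bool] = {}
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            cell = rows[i][j].strip()
            if cell not in ("0", "1"):
                raise ValueError(f"matrix cell ({a},{b}) is {cell!r}, expected 0/1")
            out[(a, b)] = cell == "1"
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            if out[(a, b)] != out[(b, a)]:
                raise ValueError(f"matrix not symmetric at ({a},{b})")
    return out


def validate_sequence(seq: str) -> str:
    """Upper-case and validate a sequence; positioned error on bad letters."""
    seq = seq.upper()
    for pos, aa in enumerate(seq):
        if aa not in _CLASSES:
            raise UnknownResidueError(aa, pos)
    return seq
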