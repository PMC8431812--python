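"""File formats: FASTA, PDB ATOM subset, ball-model tables, patch grids.

FASTA parsing is delegated to Biopython; PDB parsing to Bio.PDB.  The
2-D patch grids travel as ASCII PGM (P2, label values 0-4) or CSV, and ball
models as whitespace-separated tables (x y z radius hclass z) - all plain
text so fixtures survive any copy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..dock2d import LABELS, PatchImage
from ..gibbs_surface import BallAtom, BallModel
from ..residue_model import UnknownResidueError, classify_residue, validate_sequence

logger = logging.getLogger("eecfold.io")

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_pdb_atoms",
    "read_ball_model",
    "write_ball_model",
    "read_patch",
    "write_patch",
    "VDW_RADII",
    "ATOMIC_NUMBERS",
]


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str


def read_fasta(path: str | Path) -> List[FastaRecord]:
    """Read a multi-record FASTA file of amino-acid sequences.

    Lower-case letters are upper-cased with a logged notice; illegal
    characters raise a positioned error; duplicate ids and empty files are
    errors.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        if any(c.islower() for c in raw):
            logger.info("record %s: lower-case letters upper-cased", rec.id)
        try:
            seq = validate_sequence(raw)
        except UnknownResidueError as err:
            raise UnknownResidueError(err.aa, err.position) from err
        records.append(FastaRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Sequence[FastaRecord], path: str | Path, width: int = 60
) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# van der Waals radii (A) by element symbol; fallback carbon-like
VDW_RADII: Dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70

ATOMIC_NUMBERS: Dict[str, int] = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "P": 15,
    "S": 16,
    "SE": 34,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_HYDROPHOBIC_ONE = set("CILMWFYVA")  # fully hydrophobic side-chains + alanine


def read_pdb_atoms(
    path: str | Path, chain: Optional[str] = None
) -> Tuple[BallModel, str]:
    """Read ATOM records into a ball model plus the one-letter sequence.

    HETATM records are ignored.  For alternate locations the highest
    occupancy wins, ties broken by altLoc letter ('A' first).  Atoms inherit
    hydrophobicity class 1 when their residue's side-chain is fully
    hydrophobic (or alanine), class 2 otherwise.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    atoms: List[BallAtom] = []
    sequence: List[str] = []
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for residue in ch:
                hetflag, _, _ = residue.id
                if hetflag.strip():
                    continue  # HETATM / water
                resname = residue.get_resname().strip().upper()
                if resname not in _THREE_TO_ONE:
                    raise UnknownResidueError(resname)
                one = _THREE_TO_ONE[resname]
                classify_residue(one)
                sequence.append(one)
                hclass = 1 if one in _HYDROPHOBIC_ONE else 2
                for atom in residue:  # yields DisorderedAtom wrappers intact
                    if atom.is_disordered():
                        children = atom.disordered_get_list()
                        atom = sorted(
                            children,
                            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                        )[0]
                    elif (atom.get_altloc() or " ").strip():
                        # lone altLoc copies appear as plain atoms; keep them
                        pass
                    element = (atom.element or "").strip().upper()
                    radius = VDW_RADII.get(element, _DEFAULT_RADIUS)
                    z = ATOMIC_NUMBERS.get(element, 6)
                    x, y, zc = atom.coord
                    atoms.append(
                        BallAtom(
                            center=(float(x), float(y), float(zc)),
                            radius=radius,
                            hclass=hclass,
                            z=z,
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(f"no ATOM records found in {path}")
    return BallModel(atoms=tuple(atoms), class_count=2), "".join(sequence)


def write_ball_model(m: BallModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z radius hclass protons\n")
        fh.write(f"# class_count {m.class_count}\n")
        for a in m.atoms:
            x, y, z = a.center
            fh.write(
                f"{x:.6f} {y:.6f} {z:.6f} {a.radius:.6f} {a.hclass} {a.z:g}\n"
            )


def read_ball_model(path: str | Path) -> BallModel:
    class_count = 2
    atoms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "class_count":
                class_count = int(parts[1])
            continue
        x, y, z, r, hclass, protons = line.split()
        atoms.append(
            BallAtom(
                center=(float(x), float(y), float(z)),
                radius=float(r),
                hclass=int(hclass),
                z=float(protons),
            )
        )
    if not atoms:
        raise ValueError(f"no atoms in model file {path}")
    return BallModel(atoms=tuple(atoms), class_count=class_count)


def write_patch(patch: PatchImage, path: str | Path) -> None:
    """Write a patch as ASCII PGM (``.pgm``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        h, w = patch.grid.shape
        lines = [
            "P2",
            f"# spacing {patch.spacing:g} labels "
            + " ".join(f"{k}={v}" for k, v in sorted(LABELS.items())),
            f"{w} {h}",
            "4",
        ]
        for row in patch.grid:
            lines.append(" ".join(str(int(v)) for v in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        header = f"# spacing {patch.spacing:g}\n"
        body = "\n".join(
            ",".join(str(int(v)) for v in row) for row in patch.grid
        )
        path.write_text(header + body + "\n")


def read_patch(path: str | Path) -> PatchImage:
    path = Path(path)
    text = path.read_text()
    spacing = 1.0
    for line in text.splitlines():
        if line.startswith("#") and "spacing" in line:
            try:
                spacing = float(line.split("spacing", 1)[1].split()[0])
            except (IndexError, ValueError):
                pass
    if path.suffix.lower() == ".pgm":
        tokens: List[str] = []
        for line in text.splitlines():
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
        if not tokens or tokens[0] != "P2":
            raise ValueError(f"{path} is not an ASCII (P2) PGM file")
        w, h, _maxval = int(tokens[1]), int(tokens[2]), int(tokens[3])
        values = [int(t) for t in tokens[4 : 4 + w * h]]
        if len(values) != w * h:
            raise ValueError(f"{path}: expected {w * h} pixels")
        grid = np.array(values, dtype=np.int8).reshape(h, w)
    else:
        rows = [
            [int(v) for v in line.split(",")]
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        grid = np.array(rows, dtype=np.int8)
    return PatchImage(grid=grid, spacing=spacing)
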