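"""Survey statistics against reference secondary-structure annotations.

Coverage (recall) and success rate (precision) are segment-level: a predicted
segment matches a reference segment of the same class when their overlap is
at least ``min_overlap_frac`` of the shorter of the two, matched greedily
one-to-one left to right.  Undefined ratios are reported as ``None`` (never
0 or 1) so empty corpora cannot inflate a statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

from .residue_model import HydroLabel, classify_residue, is_rb
from .ss_predict import SSPrediction, build_attraction_graph, segments_of_states

__all__ = [
    "ReferenceAnnotation",
    "ClassMatchStats",
    "MatchReport",
    "TurnStats",
    "CompositionStats",
    "read_reference_annotation",
    "segment_match",
    "turn_composition_stats",
    "composition_stats",
    "combine_match_reports",
]

STATE_CLASSES = ("E", "H", "T", "C")

# ingest folding of common annotation alphabets (STRIDE/DSSP letters):
# 3-10 and pi helices count as helix, bridges as strand, the rest as coil.
_FOLD = {"E": "E", "B": "E", "H": "H", "G": "H", "I": "H", "T": "T"}


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Normalized per-residue states over {E, H, T, C}."""

    states: str

    def __len__(self) -> int:
        return len(self.states)


def read_reference_annotation(
    text: str, sequence: Optional[str] = None
) -> ReferenceAnnotation:
    """Parse a two-column (index, state) file or a bare state string.

    Letters are folded on ingest: G/I -> H, B -> E, E/H/T kept, any other
    letter -> C.  A supplied sequence must match in length.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    entries: List[Tuple[int, str]] = []
    bare: List[str] = []
    for ln in lines:
        parts = ln.split()
        if len(parts) == 2 and parts[0].lstrip("-").isdigit():
            entries.append((int(parts[0]), parts[1]))
        else:
            bare.append("".join(parts))
    if entries and bare:
        raise ValueError("annotation mixes two-column and bare-string lines")
    if entries:
        entries.sort(key=lambda t: t[0])
        letters = [st for _, st in entries]
    else:
        letters = list("".join(bare))
    states = []
    for pos, letter in enumerate(letters):
        letter = letter.upper()
        if len(letter) != 1 or not letter.isalpha():
            raise ValueError(f"bad annotation letter {letter!r} at position {pos}")
        states.append(_FOLD.get(letter, "C"))
    annotation = ReferenceAnnotation(states="".join(states))
    if sequence is not None and len(annotation) != len(sequence):
        raise ValueError(
            f"annotation length {len(annotation)} != sequence length {len(sequence)}"
        )
    return annotation


StatesLike = Union[str, SSPrediction, ReferenceAnnotation]


def _states_of(x: StatesLike) -> str:
    if isinstance(x, SSPrediction):
        return x.states
    if isinstance(x, ReferenceAnnotation):
        return x.states
    return x


@dataclass
class ClassMatchStats:
    """Segment counts and matches for a single state class."""

    n_ref: int = 0
    n_pred: int = 0
    n_matched: int = 0

    @property
    def recall(self) -> Optional[float]:
        """Coverage: matched fraction of reference segments; None if no ref."""
        return self.n_matched / self.n_ref if self.n_ref else None

    @property
    def precision(self) -> Optional[float]:
        """Success rate: matched fraction of predicted segments; None if none."""
        return self.n_matched / self.n_pred if self.n_pred else None


@dataclass
class MatchReport:
    per_class: dict = field(default_factory=dict)
    min_overlap_frac: float = 0.5


def _class_segments(states: str, cls: str) -> List[Tuple[int, int]]:
    return [(s, e) for s, e, st in segments_of_states(states) if st == cls]


def _greedy_match(
    pred: List[Tuple[int, int]], ref: List[Tuple[int, int]], frac: float
) -> int:
    """One-to-one greedy matching in left-to-right order; returns match count."""
    i = j = matched = 0
    while i < len(pred) and j < len(ref):
        ps, pe = pred[i]
        rs, re = ref[j]
        overlap = min(pe, re) - max(ps, rs)
        if overlap >= frac * min(pe - ps, re - rs) and overlap > 0:
            matched += 1
            i += 1
            j += 1
        elif pe <= re:
            i += 1
        else:
            j += 1
    return matched


def segment_match(
    pred: StatesLike, ref: StatesLike, min_overlap_frac: float = 0.5
) -> MatchReport:
    """Per-class segment recall (coverage) and precision (success rate)."""
    pred_states = _states_of(pred)
    ref_states = _states_of(ref)
    if len(pred_states) != len(ref_states):
        raise ValueError(
            f"length mismatch: predicted {len(pred_states)}, reference {len(ref_states)}"
        )
    report = MatchReport(min_overlap_frac=min_overlap_frac)
    for cls in STATE_CLASSES:
        p_segments = _class_segments(pred_states, cls)
        r_segments = _class_segments(ref_states, cls)
        matched = _greedy_match(p_segments, r_segments, min_overlap_frac)
        report.per_class[cls] = ClassMatchStats(
            n_ref=len(r_segments), n_pred=len(p_segments), n_matched=matched
        )
    return report


def combine_match_reports(reports: Iterable[MatchReport]) -> MatchReport:
    """Pool segment counts across a corpus (rates recomputed from totals)."""
    out = MatchReport()
    for cls in STATE_CLASSES:
        out.per_class[cls] = ClassMatchStats()
    for rep in reports:
        out.min_overlap_frac = rep.min_overlap_frac
        for cls, stats in rep.per_class.items():
            acc = out.per_class[cls]
            acc.n_ref += stats.n_ref
            acc.n_pred += stats.n_pred
            acc.n_matched += stats.n_matched
    return out


@dataclass
class TurnStats:
    n_turns: int = 0
    n_turns_with_rb: int = 0
    n_hairpins: int = 0
    n_hairpins_with_rb: int = 0

    @property
    def turn_rb_fraction(self) -> Optional[float]:
        return self.n_turns_with_rb / self.n_turns if self.n_turns else None

    @property
    def hairpin_rb_fraction(self) -> Optional[float]:
        return self.n_hairpins_with_rb / self.n_hairpins if self.n_hairpins else None


def turn_composition_stats(
    pairs: Sequence[Tuple[str, StatesLike]]
) -> TurnStats:
    """Fractions of turns (and strand-flanked hairpin turns) containing RB.

    ``pairs`` is a sequence of (sequence, annotation) items.
    """
    stats = TurnStats()
    for seq, ann in pairs:
        states = _states_of(ann)
        if len(states) != len(seq):
            raise ValueError("annotation length mismatch")
        segments = segments_of_states(states)
        for idx, (s, e, st) in enumerate(segments):
            if st != "T":
                continue
            stats.n_turns += 1
            has_rb = any(is_rb(aa) for aa in seq[s:e])
            if has_rb:
                stats.n_turns_with_rb += 1
            hairpin = (
                idx > 0
                and idx < len(segments) - 1
                and segments[idx - 1][2] == "E"
                and segments[idx + 1][2] == "E"
            )
            if hairpin:
                stats.n_hairpins += 1
                if has_rb:
                    stats.n_hairpins_with_rb += 1
    return stats


@dataclass
class CompositionStats:
    n_strand_residues: int = 0
    n_strand_hydrophobic: int = 0
    n_strand_involved: int = 0
    n_helix_residues: int = 0
    n_helix_hydrophobic: int = 0
    n_helix_involved: int = 0

    @property
    def strand_hydrophobic_fraction(self) -> Optional[float]:
        if not self.n_strand_residues:
            return None
        return self.n_strand_hydrophobic / self.n_strand_residues

    @property
    def helix_hydrophobic_fraction(self) -> Optional[float]:
        if not self.n_helix_residues:
            return None
        return self.n_helix_hydrophobic / self.n_helix_residues

    @property
    def strand_involvement(self) -> Optional[float]:
        if not self.n_strand_hydrophobic:
            return None
        return self.n_strand_involved / self.n_strand_hydrophobic

    @property
    def helix_involvement(self) -> Optional[float]:
        if not self.n_helix_hydrophobic:
            return None
        return self.n_helix_involved / self.n_helix_hydrophobic


def composition_stats(
    pairs: Sequence[Tuple[str, StatesLike]]
) -> CompositionStats:
    """Hydrophobic fractions and attraction involvement inside E/H segments.

    A fully hydrophobic residue counts as involved when it carries at least
    one attraction edge to another residue of the same segment: interval-1
    edges for strands, interval-2/3 edges for helices.
    """
    stats = CompositionStats()
    for seq, ann in pairs:
        states = _states_of(ann)
        if len(states) != len(seq):
            raise ValueError("annotation length mismatch")
        graph = build_attraction_graph(seq)
        for s, e, st in segments_of_states(states):
            if st not in ("E", "H"):
                continue
            intervals = (1,) if st == "E" else (2, 3)
            inside = {
                edge
                for edge in graph.edges_within(s, e)
                if edge[2] in intervals
            }
            touched = set()
            for i, j, _ in inside:
                touched.add(i)
                touched.add(j)
            for pos in range(s, e):
                hydrophobic = (
                    classify_residue(seq[pos]).label is HydroLabel.FULL_HYDROPHOBIC
                )
                if st == "E":
                    stats.n_strand_residues += 1
                    if hydrophobic:
                        stats.n_strand_hydrophobic += 1
                        if pos in touched:
                            stats.n_strand_involved += 1
                else:
                    stats.n_helix_residues += 1
                    if hydrophobic:
                        stats.n_helix_hydrophobic += 1
                        if pos in touched:
                            stats.n_helix_involved += 1
    return stats
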