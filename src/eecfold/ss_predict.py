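"""Rule-based secondary-structure prediction from sequence.

The predictor works on an attraction graph whose edges connect residue
positions at sequence separations 2, 3 and 4 ("1, 2 and 3 intervals": the
interval is the number of residues strictly between the pair).  Interval-1
contacts sit on the same strand face; interval-2/3 contacts are the i/i+3 and
i/i+4 helix contacts.  Runs of two or more blocking (RB) residues nucleate
turns and, together with proline, partition the chain into stretches that are
scored for strand and helix attraction density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Tuple

from .residue_model import (
    InteractionVerdict,
    is_rb,
    lateral_attraction,
    validate_sequence,
)

__all__ = [
    "PredictorParams",
    "AttractionGraph",
    "SSPrediction",
    "build_attraction_graph",
    "find_turn_sites",
    "predict_secondary_structure",
    "explain_prediction",
    "segments_of_states",
]

Edge = Tuple[int, int, int]  # (i, j, interval) with i < j, interval = j - i - 1


@dataclass(frozen=True)
class PredictorParams:
    """Thresholds of the stretch-scoring rules.

    Densities normalise segment length away; the defaults are declared
    values, not fitted ones.
    """

    min_strand_len: int = 3
    min_helix_len: int = 4
    strand_density_min: float = 0.5
    helix_density_min: float = 0.5
    turn_block_len: int = 2

    def __post_init__(self) -> None:
        if self.min_strand_len < 1 or self.min_helix_len < 1:
            raise ValueError("minimum segment lengths must be >= 1")
        if not (0.0 <= self.strand_density_min <= 1.0):
            raise ValueError("strand_density_min must lie in [0, 1]")
        if not (0.0 <= self.helix_density_min <= 1.0):
            raise ValueError("helix_density_min must lie in [0, 1]")
        if self.turn_block_len < 1:
            raise ValueError("turn_block_len must be >= 1")


@dataclass(frozen=True)
class AttractionGraph:
    """Lateral-attraction edges of a sequence at separations 2-4."""

    n: int
    edges: frozenset

    def edges_at_interval(self, interval: int) -> set:
        return {e for e in self.edges if e[2] == interval}

    def edges_within(self, start: int, end: int) -> set:
        """Edges with both endpoints in the half-open range [start, end)."""
        return {e for e in self.edges if start <= e[0] and e[1] < end}


@dataclass(frozen=True)
class SSPrediction:
    """Per-residue states over {E, H, T, C} plus the segment tiling."""

    states: str
    segments: Tuple[Tuple[int, int, str], ...]
    params_used: PredictorParams


def build_attraction_graph(
    seq: str, matrix: Optional[Mapping[Tuple[str, str], bool]] = None
) -> AttractionGraph:
    """Enumerate lateral-attraction edges at sequence separations 2-4.

    An edge (i, j, interval) exists iff
      * the verdict table says seq[i] and seq[j] attract,
      * no proline lies strictly between i and j,
      * no two consecutive RB residues lie strictly between i and j,
      * threonine endpoints occur at interval 1 only (its methyl is too
        short to bridge a helix-turn contact).
    """
    seq = validate_sequence(seq)
    n = len(seq)
    rb = [is_rb(aa) for aa in seq]
    edges = set()
    for i in range(n):
        for interval in (1, 2, 3):
            j = i + interval + 1
            if j >= n:
                break
            if lateral_attraction(seq[i], seq[j], matrix=matrix) is not (
                InteractionVerdict.ATTRACT
            ):
                continue
            if interval >= 2 and ("T" in (seq[i], seq[j])):
                continue
            if any(seq[k] == "P" for k in range(i + 1, j)):
                continue
            if any(rb[k] and rb[k + 1] for k in range(i + 1, j - 1)):
                continue
            edges.add((i, j, interval))
    return AttractionGraph(n=n, edges=frozenset(edges))


def find_turn_sites(
    seq: str, params: PredictorParams | None = None
) -> List[Tuple[int, int]]:
    """Maximal runs of consecutive RB residues of length >= turn_block_len.

    Returned as 0-based half-open ranges, left to right.
    """
    params = params or PredictorParams()
    seq = validate_sequence(seq)
    sites = []
    run_start = None
    for pos, aa in enumerate(seq + "#"):  # sentinel terminates a trailing run
        if pos < len(seq) and is_rb(aa):
            if run_start is None:
                run_start = pos
        else:
            if run_start is not None and pos - run_start >= params.turn_block_len:
                sites.append((run_start, pos))
            run_start = None
    return sites


def segments_of_states(states: str) -> Tuple[Tuple[int, int, str], ...]:
    """Maximal runs of identical state letters as (start, end, state)."""
    segments = []
    start = 0
    for pos in range(1, len(states) + 1):
        if pos == len(states) or states[pos] != states[start]:
            segments.append((start, pos, states[start]))
            start = pos
    return tuple(segments)


def _stretches(seq: str, turn_sites: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Maximal runs of positions outside turn sites and not proline."""
    n = len(seq)
    blocked = [False] * n
    for s, e in turn_sites:
        for k in range(s, e):
            blocked[k] = True
    for k, aa in enumerate(seq):
        if aa == "P":
            blocked[k] = True
    out = []
    start = None
    for pos in range(n + 1):
        if pos < n and not blocked[pos]:
            if start is None:
                start = pos
        else:
            if start is not None:
                out.append((start, pos))
            start = None
    return out


def _stretch_densities(
    graph: AttractionGraph, start: int, end: int
) -> Tuple[float, float, dict]:
    """(strand_density, helix_density, edge counts) for the range [start, end)."""
    length = end - start
    inside = graph.edges_within(start, end)
    n1 = sum(1 for e in inside if e[2] == 1)
    n2 = sum(1 for e in inside if e[2] == 2)
    n3 = sum(1 for e in inside if e[2] == 3)
    max1 = max(length - 2, 0)
    max23 = max(length - 3, 0) + max(length - 4, 0)
    strand_density = n1 / max1 if max1 else 0.0
    helix_density = (n2 + n3) / max23 if max23 else 0.0
    counts = {"interval1": n1, "interval2": n2, "interval3": n3}
    return strand_density, helix_density, counts


def predict_secondary_structure(
    seq: str,
    params: PredictorParams | None = None,
    matrix: Optional[Mapping[Tuple[str, str], bool]] = None,
) -> SSPrediction:
    """Assign E/H/T/C states to every residue of ``seq``.

    Procedure: (1) mark turn sites T; (2) split the remaining chain into
    stretches at turn runs and at proline; (3) score each stretch's strand
    density (interval-1 edges over the maximum possible) and helix density
    (interval-2/3 edges over the maximum possible); (4) call H when the helix
    criterion passes, else E when the strand criterion passes, else C.  The
    helix call takes precedence when both pass.  Proline outside turn runs
    is C; it is never inside an E segment.
    """
    params = params or PredictorParams()
    seq = validate_sequence(seq)
    n = len(seq)
    states = ["C"] * n
    turn_sites = find_turn_sites(seq, params)
    for s, e in turn_sites:
        for k in range(s, e):
            states[k] = "T"
    graph = build_attraction_graph(seq, matrix=matrix)
    for s, e in _stretches(seq, turn_sites):
        length = e - s
        strand_density, helix_density, _ = _stretch_densities(graph, s, e)
        if helix_density >= params.helix_density_min and length >= params.min_helix_len:
            state = "H"
        elif (
            strand_density >= params.strand_density_min
            and length >= params.min_strand_len
        ):
            state = "E"
        else:
            state = "C"
        for k in range(s, e):
            states[k] = state
    state_string = "".join(states)
    return SSPrediction(
        states=state_string,
        segments=segments_of_states(state_string),
        params_used=params,
    )


def explain_prediction(
    seq: str,
    params: PredictorParams | None = None,
    matrix: Optional[Mapping[Tuple[str, str], bool]] = None,
) -> str:
    """Human-readable per-segment report of the prediction.

    Ranges are 1-based inclusive.  For each scored stretch the report lists
    the edge counts per interval and the per-face split of interval-1 edges
    (edges anchored at even vs odd offsets within the stretch; the two
    strand faces alternate).
    """
    params = params or PredictorParams()
    seq = validate_sequence(seq)
    pred = predict_secondary_structure(seq, params, matrix=matrix)
    graph = build_attraction_graph(seq, matrix=matrix)
    turn_sites = find_turn_sites(seq, params)
    lines = [f"sequence length {len(seq)}", f"states {pred.states}"]
    if turn_sites:
        for s, e in turn_sites:
            lines.append(f"turn block {s + 1}-{e} residues {seq[s:e]}")
    else:
        lines.append("no turn blocks")
    for s, e in _stretches(seq, turn_sites):
        strand_density, helix_density, counts = _stretch_densities(graph, s, e)
        inside = graph.edges_within(s, e)
        even_face = sum(1 for (i, j, iv) in inside if iv == 1 and (i - s) % 2 == 0)
        odd_face = sum(1 for (i, j, iv) in inside if iv == 1 and (i - s) % 2 == 1)
        lines.append(
            f"stretch {s + 1}-{e} state {pred.states[s]} "
            f"strand_density {strand_density:.3f} helix_density {helix_density:.3f} "
            f"edges i1={counts['interval1']} (faces {even_face}/{odd_face}) "
            f"i2={counts['interval2']} i3={counts['interval3']}"
        )
        for i, j, iv in sorted(inside):
            lines.append(
                f"  edge {seq[i]}{i + 1}-{seq[j]}{j + 1} interval {iv}"
            )
    return "\n".join(lines) + "\n"
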