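"""Degenerate short-linear-motif scanning and RING zinc-motif classification.

The TAD's MDM-binding core is the FxxxWxxL motif: three anchor residues
(Phe, Trp, Leu) in an 8-residue window, with the non-anchor positions
unconstrained.  "Resembling in amino acid character" is operationalised as a
per-anchor substitution-matrix similarity threshold (default: BLOSUM62
similarity >= 0 against each reference anchor).

MDM-family RING domains coordinate two zinc ions with an unusual
Cys2-His2-Cys4 slot pattern, against the canonical Cys3-His-Cys4 of most
RING E3 ligases; classification searches for an 8-slot assignment whose
inter-slot spacings fall inside configurable windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from Bio.Align import substitution_matrices

from .records import AMINO_ACIDS

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _similarity(matrix, ref: str, obs: str) -> float:
    if obs == "X" or obs not in AMINO_ACIDS:
        return -math.inf
    return float(matrix[ref, obs])


@dataclass
class MotifPattern:
    """An anchored fixed-width motif with similarity-based anchor matching."""

    name: str
    window_length: int
    anchors: list[tuple[int, str]]
    similarity_matrix: object = field(default_factory=lambda: _BLOSUM62, repr=False)
    min_anchor_similarity: float = 0.0

    def __post_init__(self) -> None:
        offsets = [off for off, _ in self.anchors]
        if offsets != sorted(set(offsets)):
            raise ValueError("anchor offsets must be strictly increasing")
        for off, ref in self.anchors:
            if not (0 <= off < self.window_length):
                raise ValueError(f"anchor offset {off} outside window of {self.window_length}")
            if ref not in AMINO_ACIDS:
                raise ValueError(f"anchor reference {ref!r} is not a standard amino acid")

    @property
    def self_similarity(self) -> float:
        return sum(_similarity(self.similarity_matrix, ref, ref) for _, ref in self.anchors)


def tad_fxxxwxxl_pattern(min_anchor_similarity: float = 0.0) -> MotifPattern:
    """The default TAD pattern: window 8, anchors F at 0, W at 4, L at 7."""
    return MotifPattern(
        name="FxxxWxxL",
        window_length=8,
        anchors=[(0, "F"), (4, "W"), (7, "L")],
        min_anchor_similarity=min_anchor_similarity,
    )


@dataclass(frozen=True)
class MotifHit:
    """A window matching a pattern; coordinates are 0-based half-open."""

    record_id: str
    start: int
    end: int
    anchor_residues: tuple[str, ...]
    anchor_score: float
    exact: bool

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end  # half-open 0-based end == 1-based inclusive end


def scan_motif(residues: str, pattern: MotifPattern, record_id: str = "") -> list[MotifHit]:
    """All windows whose every anchor meets the similarity threshold,
    reported left to right; overlapping hits allowed.  ``X`` at an anchor
    always fails (similarity -inf)."""
    residues = residues.upper()
    w = pattern.window_length
    hits: list[MotifHit] = []
    for start in range(len(residues) - w + 1):
        obs = []
        score = 0.0
        ok = True
        exact = True
        for off, ref in pattern.anchors:
            ch = residues[start + off]
            sim = _similarity(pattern.similarity_matrix, ref, ch)
            if sim < pattern.min_anchor_similarity:
                ok = False
                break
            obs.append(ch)
            score += sim
            exact = exact and ch == ref
        if ok:
            hits.append(
                MotifHit(
                    record_id=record_id,
                    start=start,
                    end=start + w,
                    anchor_residues=tuple(obs),
                    anchor_score=score,
                    exact=exact,
                )
            )
    return hits


def tad_motif_present(residues: str, pattern: MotifPattern | None = None) -> bool:
    """True iff the sequence carries at least one motif hit."""
    return bool(scan_motif(residues, pattern or tad_fxxxwxxl_pattern()))


class RingClass(Enum):
    MDM_TYPE = "MDM_TYPE"
    CANONICAL = "CANONICAL"
    NONE = "NONE"


_MDM_SLOTS = "CCHHCCCC"
_CANONICAL_SLOTS = "CCCHCCCC"

#: Allowed residue gaps between consecutive coordinating slots (inclusive):
#: short within-lobe spacings alternate with the long inter-lobe loops of the
#: cross-brace geometry.
DEFAULT_RING_SPACING: tuple[tuple[int, int], ...] = (
    (1, 6), (8, 45), (1, 6), (8, 45), (1, 6), (8, 45), (1, 6),
)


@dataclass(frozen=True)
class RingClassification:
    ring_class: RingClass
    coordinating_positions: tuple[int, ...] | None = None  # 1-based, ungapped


def _find_slot_assignment(
    residues: str,
    slots: str,
    spacing: tuple[tuple[int, int], ...],
) -> tuple[int, ...] | None:
    """Lexicographically smallest 0-based position vector matching the slot
    residues within the spacing windows, or None."""
    n = len(residues)

    def extend(prefix: list[int], slot_idx: int) -> tuple[int, ...] | None:
        if slot_idx == len(slots):
            return tuple(prefix)
        want = slots[slot_idx]
        if slot_idx == 0:
            candidates = range(n)
        else:
            lo, hi = spacing[slot_idx - 1]
            prev = prefix[-1]
            candidates = range(prev + lo + 1, min(n, prev + hi + 2))
        for pos in candidates:
            if residues[pos] == want:
                result = extend(prefix + [pos], slot_idx + 1)
                if result is not None:
                    return result
        return None

    return extend([], 0)


def classify_ring(
    residues: str,
    spacing_config: tuple[tuple[int, int], ...] = DEFAULT_RING_SPACING,
) -> RingClassification:
    """Classify the zinc-coordination pattern of an (ungapped) sequence.

    The MDM-type pattern (C,C,H,H,C,C,C,C) takes precedence over the canonical
    (C,C,C,H,C,C,C,C) when both admit an assignment.  Returns 1-based
    coordinating positions for the leftmost assignment found.
    """
    if len(spacing_config) != 7:
        raise ValueError("spacing_config must give 7 inter-slot gap windows")
    residues = residues.upper()
    for slots, cls in ((_MDM_SLOTS, RingClass.MDM_TYPE), (_CANONICAL_SLOTS, RingClass.CANONICAL)):
        assignment = _find_slot_assignment(residues, slots, spacing_config)
        if assignment is not None:
            return RingClassification(
                ring_class=cls,
                coordinating_positions=tuple(p + 1 for p in assignment),
            )
    return RingClassification(ring_class=RingClass.NONE)
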