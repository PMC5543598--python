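"""Alignment post-processing: gap-column stripping, confidence masking,
reference-numbering maps and phosphosite profiling.

Column numbering follows human p53 residue numbering via a reference row: the
k-th non-gap character of the reference row maps its alignment column to
reference position k.  Phosphosite profiling asks, for each row, which of a
set of reference positions (default Ser15, Thr18, Ser20) carry a
phospho-acceptor (Ser or Thr) in that row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .records import GAP, Alignment

DEFAULT_PHOSPHO_POSITIONS = (15, 18, 20)
PHOSPHO_ACCEPTORS = frozenset("ST")


def strip_gap_columns(
    alignment: Alignment, tolerance: float = 0.95
) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``tolerance``.

    Returns the stripped alignment and the removed 0-based column indices.
    A column at exactly the tolerance (e.g. 95/100 gaps at 0.95) is kept.
    """
    if not (0 <= tolerance <= 1):
        raise ValueError(f"tolerance must be in [0, 1], got {tolerance}")
    n_rows = alignment.n_rows
    removed: list[int] = []
    kept_idx: list[int] = []
    for col in range(alignment.n_columns):
        gap_fraction = alignment.column(col).count(GAP) / n_rows
        if gap_fraction > tolerance:
            removed.append(col)
        else:
            kept_idx.append(col)
    if not kept_idx:
        raise ValueError("all columns removed; nothing left to align")
    rows = [
        (rid, "".join(gapped[i] for i in kept_idx)) for rid, gapped in alignment.rows
    ]
    return Alignment(rows), removed


def apply_confidence_mask(
    alignment: Alignment,
    score_table: dict[tuple[str, int], float],
    cutoff: float = 0.050,
) -> tuple[Alignment, float]:
    """Replace residues whose confidence score is below ``cutoff`` with X.

    ``score_table`` maps (row_id, 1-based column) -> confidence in [0, 1] and
    must cover every residue (non-gap) cell.  Gaps are untouched.  Returns the
    masked alignment and the fraction of residues retained.
    """
    if not (0 <= cutoff <= 1):
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    total = 0
    masked = 0
    rows: list[tuple[str, str]] = []
    for rid, gapped in alignment.rows:
        chars = list(gapped)
        for col0, ch in enumerate(chars):
            if ch == GAP:
                continue
            total += 1
            key = (rid, col0 + 1)
            if key not in score_table:
                raise ValueError(f"missing confidence score for row {rid!r}, column {col0 + 1}")
            if score_table[key] < cutoff:
                chars[col0] = "X"
                masked += 1
        rows.append((rid, "".join(chars)))
    fraction_retained = (total - masked) / total if total else 1.0
    return Alignment(rows), fraction_retained


def read_score_table(path: str | Path) -> dict[tuple[str, int], float]:
    """TSV with columns row_id, column (1-based), score."""
    scores: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"row_id", "column", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: score table must have columns {sorted(required)}")
        for row in reader:
            scores[(row["row_id"].strip(), int(row["column"]))] = float(row["score"])
    return scores


@dataclass
class ColumnMap:
    """Partial map: 1-based alignment column -> 1-based reference position."""

    reference_row_id: str
    column_to_position: dict[int, int]

    @property
    def position_to_column(self) -> dict[int, int]:
        return {pos: col for col, pos in self.column_to_position.items()}


def map_to_reference(alignment: Alignment, reference_row_id: str) -> ColumnMap:
    """Number alignment columns by the reference row's ungapped positions."""
    try:
        ref = alignment.row(reference_row_id)
    except KeyError as exc:
        raise ValueError(f"reference row {reference_row_id!r} not in alignment") from exc
    mapping: dict[int, int] = {}
    pos = 0
    for col0, ch in enumerate(ref):
        if ch != GAP:
            pos += 1
            mapping[col0 + 1] = pos
    return ColumnMap(reference_row_id=reference_row_id, column_to_position=mapping)


@dataclass
class PhosphoProfile:
    """Per-row occupied phospho positions (reference numbering) and residues."""

    reference_row_id: str
    profiled_positions: tuple[int, ...]
    occupied: dict[str, dict[int, str]]  # row_id -> {position: residue}

    def count(self, record_id: str) -> int:
        return len(self.occupied[record_id])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["record_id"] + [f"pos{p}" for p in self.profiled_positions])
            for rid, occ in self.occupied.items():
                writer.writerow([rid] + [occ.get(p, ".") for p in self.profiled_positions])


def phospho_profile(
    alignment: Alignment,
    reference_row_id: str,
    profiled_positions: tuple[int, ...] = DEFAULT_PHOSPHO_POSITIONS,
) -> PhosphoProfile:
    """Which profiled reference positions carry Ser/Thr in each row."""
    cmap = map_to_reference(alignment, reference_row_id)
    ref_len = len(cmap.column_to_position)
    for pos in profiled_positions:
        if not (1 <= pos <= ref_len):
            raise ValueError(
                f"profiled position {pos} outside reference length {ref_len}"
            )
    pos_to_col = cmap.position_to_column
    occupied: dict[str, dict[int, str]] = {}
    for rid, gapped in alignment.rows:
        occ: dict[int, str] = {}
        for pos in profiled_positions:
            ch = gapped[pos_to_col[pos] - 1]
            if ch in PHOSPHO_ACCEPTORS:
                occ[pos] = ch
        occupied[rid] = occ
    return PhosphoProfile(
        reference_row_id=reference_row_id,
        profiled_positions=tuple(profiled_positions),
        occupied=occupied,
    )
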