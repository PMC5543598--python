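"""Core sequence containers: protein records and gapped alignments.

Sequences are uppercase strings over the 20 standard amino acids plus ``X``
(unknown/masked residue).  Alignments are ordered lists of equal-length gapped
rows keyed by record id; the gap character is ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}
GAP = "-"


@dataclass
class SequenceRecord:
    """One protein sequence with provenance.

    The header convention used by the FASTA reader is pipe-delimited:
    ``id|species|label1;label2``, anything after the first whitespace ignored.
    """

    id: str
    residues: str
    species: str = ""
    lineage_labels: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be nonempty")
        self.residues = self.residues.upper()
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Ordered gapped rows of equal length with unique record ids."""

    def __init__(self, rows: list[tuple[str, str]]):
        if not rows:
            raise ValueError("alignment must have at least one row")
        length = len(rows[0][1])
        if length < 1:
            raise ValueError("alignment rows must have length >= 1")
        seen: set[str] = set()
        norm: list[tuple[str, str]] = []
        for rid, gapped in rows:
            if rid in seen:
                raise ValueError(f"duplicate row id {rid!r} in alignment")
            seen.add(rid)
            gapped = gapped.upper()
            if len(gapped) != length:
                raise ValueError(
                    f"row {rid!r} has length {len(gapped)}, expected {length}"
                )
            for pos, ch in enumerate(gapped, start=1):
                if ch != GAP and ch not in ALLOWED_RESIDUES:
                    raise ValueError(
                        f"row {rid!r}: illegal character {ch!r} at column {pos}"
                    )
            norm.append((rid, gapped))
        self.rows: list[tuple[str, str]] = norm

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, record_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == record_id:
                return gapped
        raise KeyError(f"no row with id {record_id!r}")

    def ungapped(self, record_id: str) -> str:
        return self.row(record_id).replace(GAP, "")

    def column(self, index: int) -> str:
        """0-based column as a string down the rows."""
        return "".join(gapped[index] for _, gapped in self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self.rows == other.rows

    def __repr__(self) -> str:
        return f"Alignment({self.n_rows} rows x {self.n_columns} columns)"
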