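"""Readers and writers for FASTA, aligned FASTA and tabular inputs.

FASTA headers follow the pipe-delimited convention ``id|species|label1;label2``
(anything after the first whitespace is ignored).  Unaligned FASTA forbids the
gap character; aligned FASTA requires equal-length rows.  Locus tables are TSV
with a header row and 1-based inclusive base-pair coordinates, matching
Ensembl-style gene coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .records import GAP, Alignment, SequenceRecord


@dataclass(frozen=True)
class GeneLocus:
    """A gene's chromosomal location, 1-based inclusive base pairs."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"locus {self.gene_id!r}: chromosome must be nonempty")
        if not (1 <= self.start_bp <= self.end_bp):
            raise ValueError(
                f"locus {self.gene_id!r}: require 1 <= start ({self.start_bp}) "
                f"<= end ({self.end_bp})"
            )

    @property
    def midpoint_mb(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0 / 1e6


@dataclass(frozen=True)
class ParalogonBlock:
    """A paralogous chromosome block in megabase coordinates."""

    block_id: str
    chromosome: str
    start_mb: float
    end_mb: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_mb < self.end_mb):
            raise ValueError(
                f"block {self.block_id!r}: require 0 <= start_mb < end_mb, "
                f"got ({self.start_mb}, {self.end_mb})"
            )


def _parse_header(header: str) -> tuple[str, str, list[str]]:
    head = header.split(None, 1)[0] if header.split() else ""
    parts = head.split("|")
    rid = parts[0]
    species = parts[1] if len(parts) > 1 else ""
    lineage = [x for x in parts[2].split(";") if x] if len(parts) > 2 else []
    return rid, species, lineage


def _iter_fasta(path: str | Path):
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:]
                chunks = []
            elif line.strip():
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
        if header is not None:
            yield header, "".join(chunks)


def read_fasta(path: str | Path, source: str = "") -> list[SequenceRecord]:
    """Read unaligned protein FASTA; gap characters are rejected."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for header, seq in _iter_fasta(path):
        rid, species, lineage = _parse_header(header)
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        if GAP in seq:
            raise ValueError(
                f"{path}: record {rid!r} contains gap characters; "
                "use read_alignment_fasta for aligned input"
            )
        records.append(
            SequenceRecord(
                id=rid,
                residues=seq,
                species=species,
                lineage_labels=lineage,
                source=source or str(path),
            )
        )
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species or rec.lineage_labels:
                header += f"|{rec.species}"
            if rec.lineage_labels:
                header += "|" + ";".join(rec.lineage_labels)
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment_fasta(path: str | Path) -> Alignment:
    rows = []
    for header, seq in _iter_fasta(path):
        rid, _, _ = _parse_header(header)
        rows.append((rid, seq))
    if not rows:
        raise ValueError(f"{path}: empty alignment file")
    return Alignment(rows)


def write_alignment_fasta(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, gapped in alignment.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(gapped), width):
                fh.write(gapped[i : i + width] + "\n")


def deduplicate_sequences(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse exact full-length residue duplicates (case-insensitive).

    The first occurrence in input order is kept; ``duplicate_map`` maps each
    dropped id to the id it duplicated.
    """
    kept: list[SequenceRecord] = []
    by_residues: dict[str, str] = {}
    duplicate_map: dict[str, str] = {}
    for rec in records:
        key = rec.residues  # records normalise to uppercase on construction
        if key in by_residues:
            duplicate_map[rec.id] = by_residues[key]
        else:
            by_residues[key] = rec.id
            kept.append(rec)
    return kept, duplicate_map


def _parse_mb(text: str) -> float:
    """Parse a megabase coordinate tolerating a decimal comma (e.g. ``5,01``)."""
    return float(text.strip().replace(",", "."))


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a TSV locus table with columns gene_id, chromosome, start_bp, end_bp."""
    loci: list[GeneLocus] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "chromosome", "start_bp", "end_bp"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: locus table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            if not (row["chromosome"] or "").strip():
                raise ValueError(f"{path}:{i}: missing chromosome")
            try:
                start = int(row["start_bp"].replace(",", ""))
                end = int(row["end_bp"].replace(",", ""))
            except (ValueError, AttributeError) as exc:
                raise ValueError(f"{path}:{i}: non-integer coordinates") from exc
            loci.append(
                GeneLocus(
                    gene_id=row["gene_id"].strip(),
                    chromosome=row["chromosome"].strip(),
                    start_bp=start,
                    end_bp=end,
                )
            )
    return loci


def write_locus_table(loci: list[GeneLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "chromosome", "start_bp", "end_bp"])
        for locus in loci:
            writer.writerow([locus.gene_id, locus.chromosome, locus.start_bp, locus.end_bp])
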