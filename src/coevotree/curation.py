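"""Per-record domain architectures, curation filters and the species x trait
presence matrix.

The curation rule mirrors the sequence-selection step of the analysis this
package implements: p53/p63/p73-family records are kept only when they carry a
TAD *and* an MDM-binding FxxxWxxL-like motif inside it; MDM-family records are
kept only when they carry the p53/p63/p73-binding domain *and* an MDM-type
(Cys2-His2-Cys4) RING zinc motif.  Folded-domain presence is taken from a
provided annotation table (detected upstream by homology search, which is not
part of this package); motif evidence comes from :mod:`coevotree.motifs`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .motifs import MotifHit, RingClass, RingClassification
from .records import SequenceRecord


class Domain(Enum):
    TAD = "TAD"
    DNA_BD = "DNA_BD"
    OD = "OD"
    SAM = "SAM"
    P53BD = "P53BD"
    ACIDIC = "ACIDIC"
    ZINC_BD = "ZINC_BD"
    RING = "RING"


class Family(Enum):
    P53_FAMILY = "P53_FAMILY"
    MDM_FAMILY = "MDM_FAMILY"


FAMILY_DOMAINS: dict[Family, frozenset[Domain]] = {
    Family.P53_FAMILY: frozenset({Domain.TAD, Domain.DNA_BD, Domain.OD, Domain.SAM}),
    Family.MDM_FAMILY: frozenset({Domain.P53BD, Domain.ACIDIC, Domain.ZINC_BD, Domain.RING}),
}

#: The interaction trait of each family (the domain whose loss is studied).
FAMILY_INTERACTION_DOMAIN: dict[Family, Domain] = {
    Family.P53_FAMILY: Domain.TAD,
    Family.MDM_FAMILY: Domain.P53BD,
}


class Presence(Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class ReasonCode(Enum):
    OK = "OK"
    NO_TAD = "NO_TAD"
    NO_TAD_MOTIF = "NO_TAD_MOTIF"
    NO_P53BD = "NO_P53BD"
    RING_NOT_MDM = "RING_NOT_MDM"
    NO_RING = "NO_RING"


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain interval on the ungapped sequence, 1-based inclusive."""

    record_id: str
    domain: Domain
    start: int
    end: int
    evidence: str = "provided"  # "provided" or "motif"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"annotation {self.record_id}/{self.domain.value}: "
                f"require 1 <= start <= end, got ({self.start}, {self.end})"
            )

    def overlaps(self, other: "DomainAnnotation") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ArchitectureProfile:
    record_id: str
    family: Family
    domains_present: set[Domain]
    tad_motif_exactish: bool = False
    ring_class: RingClass | None = None
    species: str = ""

    def __post_init__(self) -> None:
        extra = self.domains_present - FAMILY_DOMAINS[self.family]
        if extra:
            raise ValueError(
                f"profile {self.record_id!r}: domains {sorted(d.value for d in extra)} "
                f"not in the {self.family.value} vocabulary"
            )


@dataclass(frozen=True)
class CurationDecision:
    record_id: str
    kept: bool
    reason_codes: tuple[ReasonCode, ...]

    def __post_init__(self) -> None:
        if self.kept != (self.reason_codes == (ReasonCode.OK,)):
            raise ValueError("kept must hold exactly when reason_codes == [OK]")


def annotate_architecture(
    record: SequenceRecord,
    family: Family,
    provided_annotations: list[DomainAnnotation],
    tad_motif_hits: list[MotifHit] | None = None,
    ring: RingClassification | None = None,
) -> ArchitectureProfile:
    """Assemble a profile from provided domain intervals plus motif evidence.

    A TAD counts as present when a provided TAD annotation exists, or when a
    TAD motif hit exists even without one (motif-only TAD).  RING presence is
    carried by the classification result when it is not NONE.
    """
    tad_motif_hits = tad_motif_hits or []
    seqlen = len(record)
    for ann in provided_annotations:
        if ann.record_id != record.id:
            raise ValueError(
                f"annotation for {ann.record_id!r} applied to record {record.id!r}"
            )
        if ann.end > seqlen:
            raise ValueError(
                f"annotation {ann.record_id}/{ann.domain.value} ends at {ann.end} "
                f"beyond sequence length {seqlen}"
            )
    for i, a in enumerate(provided_annotations):
        for b in provided_annotations[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping annotations on {record.id!r}: "
                    f"{a.domain.value} [{a.start},{a.end}] and "
                    f"{b.domain.value} [{b.start},{b.end}]"
                )

    domains = {ann.domain for ann in provided_annotations}
    if tad_motif_hits and family is Family.P53_FAMILY:
        domains.add(Domain.TAD)
    ring_class = ring.ring_class if ring is not None else None
    if ring_class is not None and ring_class is not RingClass.NONE:
        domains.add(Domain.RING)
    return ArchitectureProfile(
        record_id=record.id,
        family=family,
        domains_present=domains,
        tad_motif_exactish=bool(tad_motif_hits),
        ring_class=ring_class,
        species=record.species,
    )


def curate_family(profiles: list[ArchitectureProfile], family: Family) -> list[CurationDecision]:
    """Apply the interaction-domain filter to one family's profiles.

    P53_FAMILY: kept iff TAD present and a TAD motif hit exists.
    MDM_FAMILY: kept iff P53BD present and the RING classifies as MDM_TYPE.
    """
    mixed = [p.record_id for p in profiles if p.family is not family]
    if mixed:
        raise ValueError(f"profiles not of family {family.value}: {mixed}")
    decisions: list[CurationDecision] = []
    for p in profiles:
        reasons: list[ReasonCode] = []
        if family is Family.P53_FAMILY:
            if Domain.TAD not in p.domains_present:
                reasons.append(ReasonCode.NO_TAD)
            if not p.tad_motif_exactish:
                reasons.append(ReasonCode.NO_TAD_MOTIF)
        else:
            if Domain.P53BD not in p.domains_present:
                reasons.append(ReasonCode.NO_P53BD)
            if p.ring_class is None or p.ring_class is RingClass.NONE:
                reasons.append(ReasonCode.NO_RING)
            elif p.ring_class is not RingClass.MDM_TYPE:
                reasons.append(ReasonCode.RING_NOT_MDM)
        if not reasons:
            reasons = [ReasonCode.OK]
        decisions.append(
            CurationDecision(
                record_id=p.record_id,
                kept=reasons == [ReasonCode.OK],
                reason_codes=tuple(reasons),
            )
        )
    return decisions


def write_curation_report(decisions: list[CurationDecision], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["record_id", "kept", "reason_codes"])
        for d in decisions:
            writer.writerow(
                [d.record_id, int(d.kept), ";".join(r.value for r in d.reason_codes)]
            )


@dataclass
class PresenceMatrix:
    """Species x trait cells in {present, absent, unknown}."""

    species: list[str]
    traits: list[str]
    cells: dict[tuple[str, str], Presence]

    def get(self, species: str, trait: str) -> Presence:
        return self.cells[(species, trait)]

    def vector(self, trait: str) -> dict[str, Presence]:
        return {sp: self.cells[(sp, trait)] for sp in self.species}

    def to_frame(self) -> pd.DataFrame:
        code = {Presence.PRESENT: 1, Presence.ABSENT: 0, Presence.UNKNOWN: pd.NA}
        return pd.DataFrame(
            [[code[self.cells[(sp, t)]] for t in self.traits] for sp in self.species],
            index=self.species,
            columns=self.traits,
            dtype="Int64",
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species", na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="species", dtype="object")
        cells: dict[tuple[str, str], Presence] = {}
        for sp in df.index:
            for t in df.columns:
                raw = df.loc[sp, t]
                if pd.isna(raw) or str(raw).upper() == "NA":
                    cells[(sp, t)] = Presence.UNKNOWN
                else:
                    cells[(sp, t)] = Presence.PRESENT if int(raw) == 1 else Presence.ABSENT
        return cls(species=list(df.index), traits=list(df.columns), cells=cells)


_TRAIT_TO_FAMILY = {"TAD": Family.P53_FAMILY, "P53BD": Family.MDM_FAMILY}


def presence_matrix(
    profiles: list[ArchitectureProfile],
    species_map: dict[str, str],
    traits: list[str] | None = None,
    species_order: list[str] | None = None,
    require_all_paralogs: bool = False,
) -> PresenceMatrix:
    """Aggregate record-level profiles to species-level trait presence.

    A trait is present for a species when ANY of its records of the relevant
    family carries it (or, with ``require_all_paralogs``, when all do); absent
    when the species has records of that family and the rule fails; unknown
    when the species has no record of that family at all.
    """
    traits = traits or ["TAD", "P53BD"]
    for p in profiles:
        if p.record_id not in species_map:
            raise ValueError(f"record {p.record_id!r} has no species mapping")
    if species_order is None:
        seen: list[str] = []
        for p in profiles:
            sp = species_map[p.record_id]
            if sp not in seen:
                seen.append(sp)
        species_order = seen
    cells: dict[tuple[str, str], Presence] = {}
    for trait in traits:
        family = _TRAIT_TO_FAMILY.get(trait)
        if family is None:
            raise ValueError(f"unknown trait {trait!r}; expected one of {sorted(_TRAIT_TO_FAMILY)}")
        domain = Domain(trait)
        for sp in species_order:
            fam_profiles = [
                p
                for p in profiles
                if species_map[p.record_id] == sp and p.family is family
            ]
            if not fam_profiles:
                cells[(sp, trait)] = Presence.UNKNOWN
                continue
            flags = [domain in p.domains_present for p in fam_profiles]
            hit = all(flags) if require_all_paralogs else any(flags)
            cells[(sp, trait)] = Presence.PRESENT if hit else Presence.ABSENT
    return PresenceMatrix(species=list(species_order), traits=list(traits), cells=cells)


def read_domain_annotation_table(path: str | Path) -> list[DomainAnnotation]:
    """TSV with columns record_id, domain, start, end (header required)."""
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"record_id", "domain", "start", "end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: annotation table must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                domain = Domain(row["domain"].strip())
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: unknown domain {row['domain']!r}") from exc
            out.append(
                DomainAnnotation(
                    record_id=row["record_id"].strip(),
                    domain=domain,
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    return out
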