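"""Paralogon co-localization checks.

After a whole-genome duplication, paralogous genes are expected to sit on (or
near) the two members of a paralogous chromosome block pair.  Membership is
decided by the locus midpoint in megabases falling inside the block interval,
optionally widened by a slack, because published block boundaries are coarse
Mb ranges while gene coordinates are base-pair exact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GeneLocus, ParalogonBlock


@dataclass(frozen=True)
class ParalogonPair:
    block_a: ParalogonBlock
    block_b: ParalogonBlock
    label: str = ""

    def __post_init__(self) -> None:
        a, b = self.block_a, self.block_b
        if a.chromosome == b.chromosome and a.start_mb < b.end_mb and b.start_mb < a.end_mb:
            raise ValueError(
                f"paralogon blocks must be on distinct chromosomes or "
                f"non-overlapping intervals: {a} vs {b}"
            )


def locus_in_block(locus: GeneLocus, block: ParalogonBlock, slack_mb: float = 0.0) -> bool:
    """True iff same chromosome and the locus midpoint (Mb) lies within the
    block extended by ``slack_mb`` on both sides."""
    if slack_mb < 0:
        raise ValueError(f"slack_mb must be >= 0, got {slack_mb}")
    if locus.chromosome != block.chromosome:
        return False
    mid = locus.midpoint_mb
    return block.start_mb - slack_mb <= mid <= block.end_mb + slack_mb


@dataclass(frozen=True)
class PairSupport:
    supported: bool
    reasons: tuple[str, ...]
    slack_mb: float


def paralogon_pair_support(
    locus_a: GeneLocus,
    locus_b: GeneLocus,
    pair: ParalogonPair,
    slack_mb: float = 0.0,
) -> PairSupport:
    """Supported iff one locus sits in each block (either assignment).

    Reasons name the failing memberships of the better-scoring assignment.
    """
    def check(la: GeneLocus, lb: GeneLocus) -> list[str]:
        reasons = []
        if not locus_in_block(la, pair.block_a, slack_mb):
            reasons.append(
                f"{la.gene_id} (chr{la.chromosome}, {la.midpoint_mb:.2f} Mb) not in "
                f"block {pair.block_a.block_id} (chr{pair.block_a.chromosome} "
                f"{pair.block_a.start_mb}-{pair.block_a.end_mb} Mb, slack {slack_mb})"
            )
        if not locus_in_block(lb, pair.block_b, slack_mb):
            reasons.append(
                f"{lb.gene_id} (chr{lb.chromosome}, {lb.midpoint_mb:.2f} Mb) not in "
                f"block {pair.block_b.block_id} (chr{pair.block_b.chromosome} "
                f"{pair.block_b.start_mb}-{pair.block_b.end_mb} Mb, slack {slack_mb})"
            )
        return reasons

    direct = check(locus_a, locus_b)
    if not direct:
        return PairSupport(supported=True, reasons=(), slack_mb=slack_mb)
    swapped = check(locus_b, locus_a)
    if not swapped:
        return PairSupport(supported=True, reasons=(), slack_mb=slack_mb)
    better = direct if len(direct) <= len(swapped) else swapped
    return PairSupport(supported=False, reasons=tuple(better), slack_mb=slack_mb)
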