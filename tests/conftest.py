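"""Shared fixtures: a metazoan species-tree/presence pattern, a TAD alignment
around the human p53 N-terminus, and random-tree helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coevotree.curation import Presence, PresenceMatrix
from coevotree.records import Alignment
from coevotree.trees import PhyloTree

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Accepted animal phylogeny at the lineage level used throughout: Placozoa as
# the outgroup lineage, Cnidaria sister to Bilateria, protostomes split into
# Lophotrochozoa (Mollusca+Annelida) and Ecdysozoa (Arthropoda subphyla +
# Nematoda).
METAZOA_NEWICK = (
    "(Placozoa:1,(Cnidaria:1,((Chordata:1,(Echinodermata:1,Hemichordata:1):1):1,"
    "((Mollusca:1,Annelida:1):1,(((Chelicerata:1,Myriapoda:1):1,"
    "(Hexapoda:1,Crustacea:1):1):1,Nematoda:1):1):1):1):1);"
)

#: lineages that retain both interaction domains
_RETAINING = {
    "Placozoa", "Chordata", "Echinodermata", "Hemichordata",
    "Mollusca", "Annelida", "Chelicerata", "Myriapoda",
}
_ALL_LINEAGES = _RETAINING | {"Cnidaria", "Hexapoda", "Crustacea", "Nematoda"}


@pytest.fixture
def metazoa_tree() -> PhyloTree:
    return PhyloTree.from_newick(METAZOA_NEWICK, rooted=True)


@pytest.fixture
def metazoa_presence() -> PresenceMatrix:
    """TAD and P53BD presence per lineage: both domains lost in Cnidaria,
    Hexapoda+Crustacea and Nematoda, retained everywhere else."""
    cells = {}
    for sp in _ALL_LINEAGES:
        state = Presence.PRESENT if sp in _RETAINING else Presence.ABSENT
        cells[(sp, "TAD")] = state
        cells[(sp, "P53BD")] = state
    return PresenceMatrix(species=sorted(_ALL_LINEAGES), traits=["TAD", "P53BD"], cells=cells)


#: Human p53 residues 1-40 (UniProt P04637): the TAD with the FxxxWxxL motif
#: (F19/W23/L26) and phosphosites Ser15, Thr18, Ser20.
HUMAN_P53_N40 = "MEEPQSDPSVEPPLSQETFSDLWKLLPENNVLSPLPSQAM"

def _substitute(seq: str, changes: dict[int, str]) -> str:
    chars = list(seq)
    for pos1, ch in changes.items():
        chars[pos1 - 1] = ch
    return "".join(chars)


# Synthetic companion rows: constructed (not database sequences) to the
# lineage conservation pattern under study — a p63-like row keeping only
# Ser15, a p73-like row keeping only Thr18, and a row with no acceptor at any
# profiled position.
P63_LIKE_SYNTHETIC = _substitute(HUMAN_P53_N40, {18: "Q", 20: "E"})
P73_LIKE_SYNTHETIC = _substitute(HUMAN_P53_N40, {15: "A", 20: "V"})
NO_ACCEPTOR_SYNTHETIC = _substitute(HUMAN_P53_N40, {15: "A", 18: "A", 20: "A"})


@pytest.fixture
def tad_alignment() -> Alignment:
    return Alignment(
        [
            ("p53_human", HUMAN_P53_N40),
            ("p63_like", P63_LIKE_SYNTHETIC),
            ("p73_like", P73_LIKE_SYNTHETIC),
            ("no_acceptor", NO_ACCEPTOR_SYNTHETIC),
        ]
    )


def random_tree_newick(rng: np.random.Generator, n_leaves: int,
                       min_bl: float = 0.1, max_bl: float = 2.0) -> str:
    """A random binary topology with uniform branch lengths, as Newick."""
    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    nodes = [f"L{i}:{bl():.6f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        nodes.append(f"({a},{b}):{bl():.6f}")
    return f"({nodes[0]},{nodes[1]});"
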