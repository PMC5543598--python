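"""Dollo-parsimony loss mapping and a permutation test for correlated loss.

Both interaction domains are assumed present in the common animal ancestor
(single origin at the root); character change is loss-only and irreversible
(Dollo).  The minimal reconstruction places one loss on the stem of every
maximal clade whose known tips are all absent.  Tips with unknown state carry
no evidence and are ignored (equivalently, pruned before reconstruction);
loss branches are identified by the set of *known* tips below them, which
makes the output invariant to pruning order.

The co-loss statistic is the number of branches on which both traits were
lost.  Its significance is assessed against a null that places the same
numbers of losses independently and uniformly at random on non-root branches,
subject to Dollo's non-nesting constraint (no loss branch ancestral to
another), by rejection sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curation import Presence
from .trees import PhyloTree


@dataclass(frozen=True)
class LossSet:
    """Loss branches of one trait, each identified by its child-side set of
    known tips."""

    trait: str
    branches: frozenset[frozenset[str]]
    tree_leaves: frozenset[str]
    no_observed_presence: bool = False

    @property
    def n_losses(self) -> int:
        return len(self.branches)


def dollo_losses(
    species_tree: PhyloTree, presence_vector: dict[str, Presence], trait: str = ""
) -> LossSet:
    """Minimal Dollo loss placement for one binary trait on a rooted tree.

    ``presence_vector`` must cover every tip.  If no tip is known-present the
    trait is treated as never observed: an empty LossSet flagged
    ``no_observed_presence``.
    """
    leaves = set(species_tree.leaf_labels)
    missing = leaves - set(presence_vector)
    if missing:
        raise ValueError(f"presence vector missing tips: {sorted(missing)}")

    dtree = species_tree._dtree
    known_below: dict = {}
    present_below: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            state = presence_vector[node.taxon.label]
            known = frozenset([node.taxon.label]) if state is not Presence.UNKNOWN else frozenset()
            known_below[node] = known
            present_below[node] = state is Presence.PRESENT
        else:
            acc: set[str] = set()
            pres = False
            for child in node.child_nodes():
                acc |= known_below[child]
                pres = pres or present_below[child]
            known_below[node] = frozenset(acc)
            present_below[node] = pres

    root = dtree.seed_node
    if not present_below[root]:
        return LossSet(
            trait=trait,
            branches=frozenset(),
            tree_leaves=frozenset(leaves),
            no_observed_presence=True,
        )

    branches: set[frozenset[str]] = set()
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if not known_below[node] or present_below[node]:
            continue
        # all known tips below are absent; keep only the maximal such clade
        # (the parent's subtree still shows a known-present tip)
        if present_below[node.parent_node]:
            branches.add(known_below[node])
    return LossSet(
        trait=trait,
        branches=frozenset(branches),
        tree_leaves=frozenset(leaves),
    )


@dataclass(frozen=True)
class CoLossResult:
    statistic: int
    n_lossA: int
    n_lossB: int
    p_value: float
    n_permutations: int
    seed: int
    trait_a: str = ""
    trait_b: str = ""

    def summary(self) -> str:
        return (
            f"Correlated-loss permutation test\n"
            f"  traits: {self.trait_a or 'A'} vs {self.trait_b or 'B'}\n"
            f"  losses: {self.n_lossA} and {self.n_lossB}; shared branches: {self.statistic}\n"
            f"  p = {self.p_value:.6g} ({self.n_permutations} permutations, seed {self.seed})"
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "trait_a": self.trait_a,
                "trait_b": self.trait_b,
                "statistic": self.statistic,
                "n_lossA": self.n_lossA,
                "n_lossB": self.n_lossB,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def co_loss_statistic(lossA: LossSet, lossB: LossSet) -> int:
    """Number of loss branches shared by the two traits (identical child-side
    leaf sets)."""
    if lossA.tree_leaves != lossB.tree_leaves:
        raise ValueError("loss sets were computed on different trees")
    return len(lossA.branches & lossB.branches)


def _eligible_branches(tree: PhyloTree) -> list[frozenset[str]]:
    return sorted(tree.clade_leafsets(), key=lambda s: (len(s), sorted(s)))


def _sample_non_nested(
    branches: list[frozenset[str]], k: int, rng: np.random.Generator
) -> list[frozenset[str]]:
    if k == 0:
        return []
    n = len(branches)
    for _ in range(100_000):
        idx = rng.choice(n, size=k, replace=False)
        chosen = [branches[i] for i in idx]
        ok = True
        for i in range(k):
            for j in range(k):
                if i != j and chosen[i] < chosen[j]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return chosen
    raise RuntimeError(
        f"could not draw {k} non-nested branches from {n} candidates by rejection"
    )


def co_loss_permutation_test(
    species_tree: PhyloTree,
    lossA: LossSet,
    lossB: LossSet,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CoLossResult:
    """Permutation p-value for the shared-loss-branch statistic.

    The null places |lossA| and |lossB| losses independently, uniformly at
    random on non-root branches (non-nesting enforced by rejection);
    p = (1 + #{perm: stat >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = co_loss_statistic(lossA, lossB)
    branches = _eligible_branches(species_tree)
    kA, kB = lossA.n_losses, lossB.n_losses
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        a = set(_sample_non_nested(branches, kA, rng))
        b = set(_sample_non_nested(branches, kB, rng))
        if len(a & b) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return CoLossResult(
        statistic=observed,
        n_lossA=kA,
        n_lossB=kB,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        trait_a=lossA.trait,
        trait_b=lossB.trait,
    )
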