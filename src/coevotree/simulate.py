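"""Ground-truthed synthetic data: species trees with a whole-genome
duplication, coupled interaction-domain loss histories, and sequence evolution
with per-domain rates and motif-anchor constraints.

The generator emulates the biology under study: two protein families (a
p53/p63/p73-like family and an MDM-like family) evolve along one species
tree.  Each family carries one interaction domain (TAD and P53BD) that can be
lost on a branch; losses are irreversible and may be coupled, so that losing
one interaction domain on a branch drags the partner domain with probability
``coupling_kappa`` on the same branch.  Sequences evolve under JTT with
discrete-gamma site rates scaled by per-domain multipliers (the disordered
TAD fast, folded domains slow).  The MDM-binding motif anchors inside the TAD
are held invariant while the partner domain is present and are released
(evolving at ``release_factor`` times the TAD rate) once the partner is lost;
domains whose own trait is lost are emitted as gap blocks, keeping all rows in
one coordinate frame.  The RING zinc-coordination residues are always held
invariant (the most conserved part of MDM).

No indel process is modelled: the emitted alignment *is* the true alignment.
"""

from __future__ import annotations

import csv
import hashlib
import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .curation import Presence, PresenceMatrix
from .records import Alignment
from .substitution import SubstitutionModel
from .trees import PhyloTree

TRAIT_TAD = "TAD"
TRAIT_P53BD = "P53BD"
PARTNER = {TRAIT_TAD: TRAIT_P53BD, TRAIT_P53BD: TRAIT_TAD}

#: family name -> (interaction trait, always-present companion domains)
FAMILY_LAYOUT_KEYS = {"p53": TRAIT_TAD, "mdm": TRAIT_P53BD}


@dataclass
class SimConfig:
    """Simulation parameters; defaults define the study conditions."""

    seed: int = 0
    n_species: int = 16
    species_tree: str = "birth_death"  # or an explicit Newick string
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_height: float = 0.5  # root-to-tip depth, substitutions/site at rate 1
    wgd: str | None = "auto"  # "auto", None, or "sp01,sp02,..." (a clade)
    p53_layout: tuple[tuple[str, int, float], ...] = (
        ("TAD", 60, 2.0),
        ("DNA_BD", 120, 0.5),
        ("OD", 40, 0.8),
    )
    mdm_layout: tuple[tuple[str, int, float], ...] = (
        ("P53BD", 50, 0.8),
        ("ACIDIC", 40, 1.5),
        ("ZINC_BD", 30, 0.8),
        ("RING", 50, 0.5),
    )
    motif_offset_in_tad: int = 18
    motif_anchors: tuple[tuple[int, str], ...] = ((0, "F"), (4, "W"), (7, "L"))
    ring_anchor_offsets: tuple[int, ...] = (1, 4, 14, 18, 28, 31, 41, 45)
    ring_anchor_residues: str = "CCHHCCCC"
    loss_rate_per_branch: float = 0.3  # hazard per unit branch length
    coupling_kappa: float = 1.0
    release_factor: float = 5.0
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.loss_rate_per_branch < 0:
            raise ValueError("loss_rate_per_branch must be >= 0")
        if not (0 <= self.coupling_kappa <= 1):
            raise ValueError("coupling_kappa must be in [0, 1]")
        if self.release_factor < 1:
            raise ValueError("release_factor must be >= 1")
        for layout in (self.p53_layout, self.mdm_layout):
            for name, length, mult in layout:
                if length < 1 or mult <= 0:
                    raise ValueError(f"bad domain layout entry ({name}, {length}, {mult})")
        tad_len = dict((n, l) for n, l, _ in self.p53_layout)["TAD"]
        for off, ref in self.motif_anchors:
            if not (0 <= self.motif_offset_in_tad + off < tad_len):
                raise ValueError("motif anchor offsets must fall inside the TAD")
        ring_len = dict((n, l) for n, l, _ in self.mdm_layout)["RING"]
        if len(self.ring_anchor_offsets) != len(self.ring_anchor_residues):
            raise ValueError("ring anchor offsets and residues must have equal length")
        if max(self.ring_anchor_offsets) >= ring_len:
            raise ValueError("ring anchor offsets must fall inside the RING domain")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        kwargs = dict(data)
        for key in ("p53_layout", "mdm_layout"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(x) for x in kwargs[key])
        if "motif_anchors" in kwargs:
            kwargs["motif_anchors"] = tuple((int(o), str(r)) for o, r in kwargs["motif_anchors"])
        if "ring_anchor_offsets" in kwargs:
            kwargs["ring_anchor_offsets"] = tuple(int(x) for x in kwargs["ring_anchor_offsets"])
        return cls(**kwargs)


def _build_species_tree(config: SimConfig, seed: int) -> dendropy.Tree:
    if config.species_tree != "birth_death":
        ptree = PhyloTree.from_newick(config.species_tree, rooted=True)
        return ptree._dtree
    dtree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_species,
        rng=random.Random(int(seed)),
    )
    width = max(2, len(str(config.n_species)))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    # scale so the deepest tip sits at tree_height substitutions/site
    depths: dict = {dtree.seed_node: 0.0}
    max_depth = 0.0
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
            max_depth = max(max_depth, depths[node])
    if max_depth <= 0:
        raise RuntimeError("degenerate simulated tree with zero height")
    scale = config.tree_height / max_depth
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return dtree


def _leafsets(dtree: dendropy.Tree) -> dict:
    below: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= below[child]
            below[node] = frozenset(acc)
    return below


def _wgd_edge(dtree: dendropy.Tree, config: SimConfig):
    """Resolve the WGD branch; returns (node, leafset) or (None, None)."""
    if config.wgd is None or config.wgd == "":
        return None, None
    below = _leafsets(dtree)
    if config.wgd == "auto":
        children = dtree.seed_node.child_nodes()
        target = max(children, key=lambda c: (len(below[c]), sorted(below[c])))
        return target, below[target]
    want = frozenset(x.strip() for x in str(config.wgd).split(",") if x.strip())
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None and below[node] == want:
            return node, want
    raise ValueError(f"wgd clade {sorted(want)} does not match any branch of the tree")


def simulate_domain_history(
    config: SimConfig,
) -> tuple[PhyloTree, list[tuple[str, frozenset]], dict[str, dict[str, set[str]]]]:
    """Species tree plus coupled, irreversible interaction-domain losses.

    Both traits start present at the root.  On each branch (preorder), each
    trait still present is lost with probability 1 - exp(-rate * length); when
    one trait is lost on a branch and its partner is still present, the
    partner is lost on the same branch with probability ``coupling_kappa``.

    Returns the tree, the loss events as (trait, child-side leaf set), and the
    per-species per-family domain-presence truth table.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_seed, history_seed, _, _ = ss.generate_state(4)
    dtree = _build_species_tree(config, int(tree_seed % (2**31)))
    rng = np.random.default_rng(history_seed)
    below = _leafsets(dtree)

    states: dict = {dtree.seed_node: {TRAIT_TAD: True, TRAIT_P53BD: True}}
    loss_events: list[tuple[str, frozenset]] = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_state = states[node.parent_node]
        state = dict(parent_state)
        length = node.edge.length or 0.0
        p_loss = 1.0 - np.exp(-config.loss_rate_per_branch * length)
        primaries = []
        for trait in (TRAIT_TAD, TRAIT_P53BD):
            if state[trait] and rng.random() < p_loss:
                primaries.append(trait)
        for trait in primaries:
            if state[trait]:
                state[trait] = False
                loss_events.append((trait, below[node]))
            partner = PARTNER[trait]
            if state[partner] and rng.random() < config.coupling_kappa:
                state[partner] = False
                loss_events.append((partner, below[node]))
        states[node] = state

    truth: dict[str, dict[str, set[str]]] = {}
    for leaf in dtree.leaf_node_iter():
        sp = leaf.taxon.label
        st = states[leaf]
        p53_domains = {name for name, _, _ in config.p53_layout if name != "TAD"}
        if st[TRAIT_TAD]:
            p53_domains.add("TAD")
        mdm_domains = {name for name, _, _ in config.mdm_layout if name != "P53BD"}
        if st[TRAIT_P53BD]:
            mdm_domains.add("P53BD")
        truth[sp] = {"p53": p53_domains, "mdm": mdm_domains}

    tree = PhyloTree(dtree, rooted=True)
    tree._trait_states = states  # node-level states, reused by simulate_bundle
    return tree, loss_events, truth


@dataclass
class TruthBundle:
    """Everything the simulator knows: tree, losses, truth table, alignments."""

    species_tree: PhyloTree
    loss_events: list[tuple[str, frozenset]]
    architecture_truth: dict[str, dict[str, set[str]]]
    alignments: dict[str, Alignment]
    species_map: dict[str, str]
    config: SimConfig
    wgd_clade: frozenset | None = None

    def presence_matrix(self) -> PresenceMatrix:
        species = sorted(self.architecture_truth)
        cells = {}
        for sp in species:
            cells[(sp, TRAIT_TAD)] = (
                Presence.PRESENT
                if "TAD" in self.architecture_truth[sp]["p53"]
                else Presence.ABSENT
            )
            cells[(sp, TRAIT_P53BD)] = (
                Presence.PRESENT
                if "P53BD" in self.architecture_truth[sp]["mdm"]
                else Presence.ABSENT
            )
        return PresenceMatrix(species=species, traits=[TRAIT_TAD, TRAIT_P53BD], cells=cells)

    def write(self, outdir: str | Path) -> None:
        from .io import write_alignment_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.species_tree.write_newick(outdir / "species_tree.nwk")
        with open(outdir / "loss_events.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["trait", "clade"])
            for trait, clade in self.loss_events:
                writer.writerow([trait, ",".join(sorted(clade))])
        with open(outdir / "truth_architecture.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["species", "family", "domains"])
            for sp in sorted(self.architecture_truth):
                for fam in ("p53", "mdm"):
                    writer.writerow(
                        [sp, fam, ",".join(sorted(self.architecture_truth[sp][fam]))]
                    )
        for fam, aln in self.alignments.items():
            write_alignment_fasta(aln, outdir / f"family_{fam}.aln.fasta")
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "n_species": len(self.architecture_truth),
            "wgd_clade": sorted(self.wgd_clade) if self.wgd_clade else None,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _domain_ranges(layout) -> dict[str, tuple[int, int]]:
    ranges = {}
    pos = 0
    for name, length, _ in layout:
        ranges[name] = (pos, pos + length)
        pos += length
    return ranges


def _evolve_sites(
    parent: np.ndarray,
    rates: np.ndarray,
    length: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of site-wise CTMC evolution; rate 0 sites stay fixed."""
    child = parent.copy()
    for rate in np.unique(rates):
        if rate == 0.0:
            continue
        sites = np.nonzero(rates == rate)[0]
        P = model.transition_matrix(length * rate)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(len(sites))
        child[sites] = (u[:, None] > cum[parent[sites]]).sum(axis=1)
    return child


class _FamilySimulator:
    """Evolves one family's alignment along the species tree."""

    def __init__(self, family: str, config: SimConfig, model: SubstitutionModel,
                 rng: np.random.Generator):
        self.family = family
        self.config = config
        self.model = model
        self.rng = rng
        self.layout = config.p53_layout if family == "p53" else config.mdm_layout
        self.ranges = _domain_ranges(self.layout)
        self.n_sites = sum(length for _, length, _ in self.layout)
        self.own_trait = FAMILY_LAYOUT_KEYS[family]
        self.partner_trait = PARTNER[self.own_trait]

        # per-site domain multiplier and gamma category rate
        self.domain_mult = np.empty(self.n_sites)
        self.domain_of_site = np.empty(self.n_sites, dtype=object)
        for name, _, mult in self.layout:
            lo, hi = self.ranges[name]
            self.domain_mult[lo:hi] = mult
            self.domain_of_site[lo:hi] = name
        cats = rng.integers(0, config.n_categories, size=self.n_sites)
        self.site_gamma = model.category_rates[-config.n_categories :][cats]

        # anchor positions (absolute site indices)
        if family == "p53":
            tad_lo, _ = self.ranges["TAD"]
            self.anchor_sites = np.array(
                [tad_lo + config.motif_offset_in_tad + off for off, _ in config.motif_anchors]
            )
            self.anchor_residues = "".join(ref for _, ref in config.motif_anchors)
            self.always_fixed = np.array([], dtype=int)
        else:
            ring_lo, _ = self.ranges["RING"]
            self.anchor_sites = np.array([], dtype=int)
            self.anchor_residues = ""
            self.always_fixed = np.array(
                [ring_lo + off for off in config.ring_anchor_offsets]
            )
            self.ring_residues = config.ring_anchor_residues

        lo, hi = self.ranges[self.own_trait] if self.own_trait in self.ranges else (0, 0)
        self.interaction_sites = np.arange(lo, hi)

    def root_sequence(self) -> np.ndarray:
        seq = self.rng.choice(20, size=self.n_sites, p=self.model.frequencies)
        for site, ref in zip(self.anchor_sites, self.anchor_residues):
            seq[site] = self.model.encode(ref)[0]
        for site, ref in zip(self.always_fixed, getattr(self, "ring_residues", "")):
            seq[site] = self.model.encode(ref)[0]
        return seq

    def branch_rates(self, partner_present: bool) -> np.ndarray:
        rates = self.site_gamma * self.domain_mult
        if partner_present:
            rates[self.anchor_sites] = 0.0
        else:
            factor = self.config.release_factor
            rates[self.interaction_sites] *= factor
        rates[self.always_fixed] = 0.0
        return rates

    def emit_row(self, seq: np.ndarray, own_present: bool) -> str:
        residues = list(self.model.decode(seq))
        if not own_present:
            lo, hi = self.ranges[self.own_trait]
            residues[lo:hi] = ["-"] * (hi - lo)
        return "".join(residues)


def simulate_bundle(config: SimConfig) -> TruthBundle:
    """Full generative run: tree, losses, and per-family true alignments."""
    tree, loss_events, truth = simulate_domain_history(config)
    states = tree._trait_states
    dtree = tree._dtree
    wgd_node, wgd_set = _wgd_edge(dtree, config)

    ss = np.random.SeedSequence(config.seed)
    _, _, p53_seed, mdm_seed = ss.generate_state(4)
    model = SubstitutionModel(alpha=config.alpha, n_categories=config.n_categories)

    alignments: dict[str, Alignment] = {}
    species_map: dict[str, str] = {}
    for family, seq_seed in (("p53", p53_seed), ("mdm", mdm_seed)):
        rng = np.random.default_rng(seq_seed)
        sim = _FamilySimulator(family, config, model, rng)
        tip_rows: list[tuple[str, str]] = []

        def recurse(node, seq: np.ndarray, copy: str) -> None:
            if node.is_leaf():
                sp = node.taxon.label
                rid = f"{sp}_{family}_{copy}"
                own_present = states[node][sim.own_trait]
                tip_rows.append((rid, sim.emit_row(seq, own_present)))
                species_map[rid] = sp
                return
            for child in node.child_nodes():
                partner_present = states[child][sim.partner_trait]
                rates = sim.branch_rates(partner_present)
                length = child.edge.length or 0.0
                child_seq = _evolve_sites(seq, rates, length, model, rng)
                if wgd_node is not None and child is wgd_node and copy == "A":
                    dup_seq = _evolve_sites(seq, rates, length, model, rng)
                    recurse(child, dup_seq, "B")
                recurse(child, child_seq, copy)

        recurse(dtree.seed_node, sim.root_sequence(), "A")
        tip_rows.sort(key=lambda r: r[0])
        alignments[family] = Alignment(tip_rows)

    return TruthBundle(
        species_tree=tree,
        loss_events=loss_events,
        architecture_truth=truth,
        alignments=alignments,
        species_map=species_map,
        config=config,
        wgd_clade=wgd_set,
    )


def mask_unknown_species(
    matrix: PresenceMatrix,
    species_to_mask: set[str] | list[str],
    traits: list[str] | None = None,
) -> PresenceMatrix:
    """Set the given species' cells to unknown (emulating poor genome
    coverage); the evolutionary model itself never produces unknowns."""
    traits = traits or matrix.traits
    unknown_sp = set(species_to_mask)
    missing = unknown_sp - set(matrix.species)
    if missing:
        raise ValueError(f"species not in matrix: {sorted(missing)}")
    cells = dict(matrix.cells)
    for sp in unknown_sp:
        for t in traits:
            cells[(sp, t)] = Presence.UNKNOWN
    return PresenceMatrix(species=list(matrix.species), traits=list(matrix.traits), cells=cells)
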