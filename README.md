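# coevotree

Interaction-domain-aware curation, phylogeny and co-evolution analysis of the
p53/p63/p73–MDM system.

## The scientific problem

The tumor suppressor p53 and its paralogs p63/p73 are negatively regulated by
MDM2/MDM4.  The interaction runs through two domains: the intrinsically
disordered **transactivation domain (TAD)** of p53/p63/p73, whose
**FxxxWxxL** anchor motif (Phe, Trp, Leu in an 8-residue window) docks into
the **p53/p63/p73-binding domain (p53BD)** of MDM.  Across animal phyla these
two domains co-evolve: when one partner's domain is lost in a lineage, the
other tends to lose function, evolve fast, and eventually disappear.  Gene
trees built from all homologs are notoriously discordant with the species
tree; restricting the analysis to genes that retain both interaction domains
(and the motif) yields trees that track species evolution.

`coevotree` packages that analysis as reusable, tested components for
molecular evolution work at desk scale:

- **Curation** — degenerate FxxxWxxL motif scanning (per-anchor BLOSUM62
  similarity ≥ a threshold), RING zinc-motif classification
  (MDM-type Cys₂His₂Cys₄ vs canonical Cys₃HisCys₄), and architecture-based
  keep/drop decisions with reason codes.
- **Alignment post-processing** — gap-column stripping (column removed when
  its gap fraction strictly exceeds the tolerance, default 0.95),
  per-residue confidence masking (default cutoff 0.050), reference numbering
  (human p53 positions) and phosphosite profiling (Ser15/Thr18/Ser20).
- **Phylogeny** — maximum-likelihood pairwise distances under JTT+Γ
  (4 equal-probability discrete categories, optional +F and +I), neighbor
  joining with deterministic tie-breaking, outgroup rooting,
  Robinson–Foulds distances and monophyly checks.
- **Co-evolution** — Dollo-parsimony loss mapping of binary domain traits on
  a species tree (single origin at the root, irreversible losses on the stems
  of maximal absent clades) and a permutation test for correlated loss.
- **Synteny** — paralogon co-localization checks: do paralogs sit on/near the
  two members of a whole-genome-duplication block pair (midpoint membership
  in Mb, explicit slack).
- **Simulator** — ground-truthed synthetic data: a species tree with one WGD
  event, coupled irreversible domain losses, and JTT+Γ sequence evolution
  with per-domain rate multipliers, motif anchors frozen while the partner
  domain exists and released (rate × `release_factor`) after partner loss.

## Worked example

Map domain losses on a lineage-level species tree and test whether TAD and
p53BD losses land on the same branches:

```python
from coevotree import (Presence, PresenceMatrix, dollo_losses,
                       co_loss_permutation_test)
from coevotree.trees import PhyloTree

newick = ("(Placozoa:1,(Cnidaria:1,((Chordata:1,(Echinodermata:1,"
          "Hemichordata:1):1):1,((Mollusca:1,Annelida:1):1,(((Chelicerata:1,"
          "Myriapoda:1):1,(Hexapoda:1,Crustacea:1):1):1,Nematoda:1):1):1):1):1);")
tree = PhyloTree.from_newick(newick, rooted=True)

retaining = {"Placozoa", "Chordata", "Echinodermata", "Hemichordata",
             "Mollusca", "Annelida", "Chelicerata", "Myriapoda"}
species = sorted(retaining | {"Cnidaria", "Hexapoda", "Crustacea", "Nematoda"})
cells = {(sp, t): Presence.PRESENT if sp in retaining else Presence.ABSENT
         for sp in species for t in ("TAD", "P53BD")}
pm = PresenceMatrix(species=species, traits=["TAD", "P53BD"], cells=cells)

tad = dollo_losses(tree, pm.vector("TAD"), "TAD")
bd = dollo_losses(tree, pm.vector("P53BD"), "P53BD")
print(co_loss_permutation_test(tree, tad, bd, n_permutations=10_000, seed=1).summary())
```

```
Correlated-loss permutation test
  traits: TAD vs P53BD
  losses: 3 and 3; shared branches: 3
  p = 0.00189981 (10000 permutations, seed 1)
```

Both domains map their three losses to the same stems (Cnidaria, Nematoda,
Hexapoda+Crustacea), and placing three losses per trait at random on the
tree's branches almost never reproduces three shared branches — the
correlated-loss signal is strong.

The headline synthetic experiment asks whether curation helps tree quality:

```python
from coevotree import ExperimentConfig, SimConfig, run_experiment

report = run_experiment(ExperimentConfig(sim=SimConfig(seed=0, n_species=16),
                                         n_replicates=10, seed=20170803))
print(report.summary())
```

```
Curation-vs-concordance experiment
  replicates scored: 9 (failed: 1)
  RF(curated) <= RF(uncurated) in 100% of replicates
  mean RF curated:   0.889
  mean RF uncurated: 1.111
  config hash: 3ee3d3230ff7e4dd
```

Each replicate simulates 16 species with coupled domain losses, infers a
neighbor-joining tree from the curated rows (interaction domain + motif
retained) and from all rows, and scores both against the true species tree by
Robinson–Foulds distance on the common species set.  Curated trees are at
least as concordant in every scored replicate (one replicate aborted because
too few species survived curation).

A CLI mirrors the library (`coevotree simulate|curate|strip|tree|coevo|
synteny|phospho|experiment`); see `coevotree --help`.

## Documentation

`docs/methods.md` describes the models, the simulator's generative
assumptions, numerical choices and known limitations.
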