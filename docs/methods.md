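# Methods

## Scope and design

`coevotree` implements an interaction-domain-aware analysis of the
p53/p63/p73–MDM system as a set of small, composable stages: sequence
curation by motif and domain content, alignment post-processing, distance
phylogenetics, Dollo co-loss analysis, paralogon synteny checks, and a
ground-truthed simulator that makes every stage testable at desk scale.
Homology search, multiple-sequence alignment construction, alignment
confidence scoring and full ML tree search are deliberately outside the
package: alignments, domain-annotation tables and confidence scores are
accepted as inputs, and tree inference is provided as ML pairwise distances
plus neighbor joining, which is sufficient for the package's target claim —
topological concordance between gene trees and the species tree.

## Motif and RING classification

The TAD's MDM-binding core is modelled as an anchored window: length 8,
anchors Phe at offset 0, Trp at 4, Leu at 7; non-anchor positions are
unconstrained.  "Resembles the motif" is operationalised per anchor as
substitution-matrix similarity: a window qualifies when every anchor's
BLOSUM62 similarity to its reference residue is at least
`min_anchor_similarity` (default 0, i.e. non-negative similarity to F/W/L).
This accepts conservative replacements such as Tyr for Phe (+3) and rejects
dissimilar ones such as Ala for Trp (−3).  `X` at an anchor always fails
(similarity −∞).  The threshold is a configuration knob and is reported with
the scan results, since any single cutoff for "resemblance" is a choice.

RING domains are classified by searching for an 8-slot zinc-coordination
assignment.  MDM-type reads (C,C,H,H,C,C,C,C), canonical
(C,C,C,H,C,C,C,C).  Consecutive slots must be separated by gaps inside
configurable windows; the defaults alternate short within-lobe spacings
(1–6 residues) with long inter-lobe loops (8–45 residues), wide enough to
accept the canonical cross-brace geometry.  The search returns the
lexicographically smallest position vector (leftmost assignment); when both
patterns admit an assignment the MDM-type call takes precedence, because the
classifier's purpose is to detect the MDM-specific motif.

## Curation rules

p53-family records are kept iff the TAD is present **and** a motif hit lies in
the sequence; MDM-family records are kept iff the p53BD is present **and**
the RING classifies as MDM-type.  Every drop carries reason codes
(`NO_TAD`, `NO_TAD_MOTIF`, `NO_P53BD`, `NO_RING`, `RING_NOT_MDM`), and
decisions are pure functions of the profile (order-independent).  Folded
domains (DNA-binding, oligomerisation, SAM, acidic, zinc-binding, p53BD) are
taken from a provided annotation table rather than detected de novo — locating
them is a homology-search task outside the package; the simulator and test
fixtures supply these tables.

Species-level presence aggregates records by the "any paralog" rule (a trait
is present for a species when any of its records carries it); a stricter
all-paralog mode is available.  A species with no record of a family is
**unknown**, not absent — missing evidence from poorly covered genomes must
not be mistaken for domain loss.

## Alignment operations

Gap stripping removes a column only when its gap fraction **strictly
exceeds** the tolerance (default 0.95), so a 95/100-gap column survives at
tolerance 0.95 and a 96/100-gap column does not; the convention is explicit
because published descriptions of gap-stripping tools rarely state the
boundary.  Confidence masking is per residue cell: scores below the cutoff
(default 0.050) become `X`, gaps are untouched, and the fraction of residues
retained is reported, which lets a residue-level retention figure be
reproduced exactly.  Whether masking should instead remove whole columns is
ambiguous in common pipelines; per-residue replacement was chosen and is the
only interpretation that can hit a stated residue-level retention.
Reference numbering maps the k-th non-gap character of a chosen reference row
(human p53 by convention) to position k; phosphosite profiling reports which
of the profiled positions (default 15, 18, 20) carry Ser or Thr in each row
— Thr counts as a phospho-acceptor equal to Ser.

## Substitution model and distances

The amino-acid model is JTT: published exchangeabilities and stationary
frequencies, rate matrix Q = S·diag(π) normalised to mean rate 1 at
stationarity.  Rate heterogeneity is the standard discrete gamma: K
equal-probability categories (default 4) represented by their conditional
mean rates; "+I" adds a zero-rate category of weight p and rescales the gamma
rates by 1/(1−p) (default off — a fitted invariant fraction is
dataset-specific).  "+F" frequencies are counted from the alignment excluding
gaps and `X`, floored at 1e-6 and renormalised so the model stays reversible.

Pairwise distances maximise the two-sequence likelihood
Σ_sites log Σ_k w_k · π_a · [exp(Q·d·r_k)]_{ab} over d ∈ (1e-8, 10] with
Brent search to 1e-6, after pairwise deletion of sites where either row has a
gap or `X` (pairwise deletion keeps the maximal usable signal per pair).
Site patterns are compressed to a 20×20 count table and P(t) is assembled
from a cached eigendecomposition of the reversible Q, so a fit costs
milliseconds.  Distances that hit the 10 substitutions/site cap are returned
capped and flagged saturated, rather than as infinities.

Neighbor joining follows the Q-criterion; ties are broken by the
lexicographically smallest pair of cluster representative labels, making the
output deterministic; negative branch-length estimates are clamped to zero
with a warning.  Outgroup rooting places the root at the midpoint of the
outgroup's stem edge and requires a multi-taxon outgroup to be monophyletic.
Robinson–Foulds distance counts non-trivial bipartitions present in exactly
one tree.

## Dollo co-loss analysis

Both interaction domains are assumed present in the animal common ancestor,
so trait change is modelled as single-origin, irreversible loss (Dollo).  The
minimal reconstruction places one loss on the stem of every maximal clade
whose known tips are all absent; unknown tips carry no evidence (equivalent
to pruning them first), and loss branches are identified by the set of known
tips below them, which makes the output invariant to pruning order.  The
co-loss statistic is the number of branches where both traits were lost.  Its
null distribution places the observed numbers of losses per trait
independently and uniformly at random on non-root branches, enforcing the
Dollo non-nesting constraint by rejection, and
p = (1 + #{permutation statistic ≥ observed}) / (1 + N).  The permutation
test is this package's quantification of a correlation that is usually
argued qualitatively; it is an extension, not a reproduction of a published
statistic.

## Synteny checks

Block membership uses the locus midpoint in megabases against the block
interval extended by an explicit slack (default 0): published paralogon
boundaries are coarse Mb ranges, so full-interval containment would be false
precision.  Block coordinates tolerate a decimal comma on input.  A paralog
pair supports a block pair when one locus falls in each block under either
assignment; "close proximity" cases are handled by raising the slack
explicitly rather than silently.

## The simulator

The generator emulates the study system, not generic sequence evolution:

- **Species tree**: a birth–death (default pure-birth) tree with
  `n_species` tips (default 16), scaled to root-to-tip height
  `tree_height` = 0.5 expected substitutions/site at rate 1 — folded-domain
  divergence stays comfortably sub-saturated across the tree, as it is across
  metazoan p53 folded domains.  An explicit Newick tree can be supplied.
- **WGD**: one branch (by default the stem of the larger root child clade)
  duplicates the locus; the two copies evolve independently from the
  duplication onward, giving two paralog rows per descendant species.
- **Domain losses**: TAD and p53BD start present at the root; on each branch
  a still-present trait is lost with probability 1 − exp(−λ·length)
  (λ = `loss_rate_per_branch`, default 0.3, giving a few losses per tree);
  when one trait is lost on a branch the partner is lost on the same branch
  with probability `coupling_kappa` (default 1 — fully coupled losses, the
  co-evolution regime under study).  Losses are irreversible.
- **Sequences**: per family, domains are laid out contiguously with
  per-domain rate multipliers (defaults: disordered TAD 2.0, acidic 1.5,
  DNA-BD 0.5, OD/zinc-BD 0.8, p53BD 0.8, RING 0.5); each site's rate is the
  product of its domain multiplier and a discrete-gamma category rate drawn
  uniformly from the K categories (so simulation matches the inference model
  exactly).  Motif anchors inside the TAD are invariant on branches where the
  partner domain is present; after partner loss the whole interaction domain
  — anchors included — evolves at `release_factor` (default 5) times its
  rate.  RING coordinating residues are always invariant (the most conserved
  part of MDM).  Domains whose own trait is lost are emitted as gap blocks,
  keeping all rows in one coordinate frame so truth-based evaluation never
  needs re-alignment.
- **No indels**: the emitted alignment is the true alignment by construction;
  alignment inference is out of scope, so no indel process is modelled.
  "Unknown" species states are produced by a separate masking utility, never
  by the evolutionary model.

All stochastic draws flow from a single seed through named substreams
(tree, history, one per family), so outputs are bit-reproducible.

Note an interaction of the defaults: with `coupling_kappa = 1`, the partner
domain is lost on the same branch as the primary loss, so a released (fast,
motif-free) but still-present TAD never reaches a tip; the release mechanism
is visible at `coupling_kappa < 1`, where one domain can outlive its partner,
and is tested there.  At full coupling the curated/uncurated contrast is
carried by the gap-block rows — genes that lost the interaction domain —
which is precisely the exclusion scenario the curation rule exists for.

## The headline experiment

For each replicate: simulate a bundle; curate the p53-family rows
(TAD present + motif hit) versus keep all rows; pick one representative row
per species per arm (longest retained row, ties by id); strip gap columns at
0.95; estimate JTT+Γ distances with the generating α; build NJ trees; score
both trees by RF distance against the true species tree.  Both arms are
scored on the common species set retained by the curated arm (all trees
pruned to it): RF values on different leaf sets are not comparable, and
pruning the uncurated tree after inference preserves any distortion the extra
rows caused among the scored species.  Replicates where fewer than
`min_species` (default 4) species survive curation abort and are counted as
failures, not successes.

## What passing tests do and do not show

The simulator draws sequences from exactly the model family the estimator
assumes, has no indels, no alignment error, no among-lineage rate variation
beyond the domain/release structure, and no gene-specific (as opposed to
species-level) domain loss.  Passing tests therefore demonstrate internal
correctness — the estimator recovers its own model's distances, NJ recovers
additive trees, Dollo recovers simulated loss histories, curation removes
exactly the rows it should — and that the curation step cannot hurt
concordance under the generative assumptions.  They do not show that curation
rescues phylogenies of real, misaligned, indel-rich proteins; that claim
needs real data.

## Numerical choices and degenerate inputs

- Distance optimisation bracket (1e-8, 10], tolerance 1e-6; identical rows
  return ≈ 0; zero comparable sites raise an error naming the pair.
- Transition probabilities are clipped at 0 to absorb eigendecomposition
  round-off; rows of P(t) sum to 1 within 1e-10.
- Missing Newick branch lengths default to 1.0 with a warning.
- Empty alignments, all-absent presence vectors (returned as a flagged empty
  loss set), non-monophyletic outgroups and mixed-family curation inputs all
  raise explicit errors rather than guessing.
- Permutation rejection sampling caps at 1e5 attempts per draw and raises if
  a non-nested sample cannot be found (only conceivable when the requested
  loss count approaches the branch count).

## Known limitations

- Distance + NJ substitutes for full ML topology search; branch support
  values (e.g. SH-aLRT) are not computed, and only topology is evaluated.
- The permutation null treats all non-root branches as equally likely loss
  sites, ignoring branch lengths; a length-weighted null would be a natural
  extension.
- The RING spacing defaults are permissive geometry windows, not fitted to a
  domain database; unusual RINGs may need custom windows.
- Lineage-level presence patterns mix phylum- and subphylum-level statements;
  the bundled pattern encodes one tip per named lineage and inherits that
  granularity choice.
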