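"""The headline curation-vs-concordance experiment.

For each replicate a ground-truthed dataset is simulated; the p53-family
alignment is then analysed twice: once keeping every row (uncurated arm) and
once keeping only rows that pass the interaction-domain filter (TAD present
and an FxxxWxxL-like motif hit — the curated arm).  Each arm picks one
representative row per species (the longest retained row; ties broken by id),
strips high-gap columns, estimates JTT+gamma ML distances, builds a
neighbor-joining tree, and is scored by Robinson-Foulds distance to the true
species tree.

Both arms are scored on the common species set retained by the curated arm
(all trees pruned to it) so that the two RF values are comparable; scoring on
different leaf sets would conflate leaf-count effects with topology quality.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .curation import (
    ArchitectureProfile,
    Domain,
    Family,
    curate_family,
)
from .distances import distance_matrix
from .motifs import scan_motif, tad_fxxxwxxl_pattern
from .msa import strip_gap_columns
from .records import Alignment
from .simulate import SimConfig, simulate_bundle
from .substitution import SubstitutionModel
from .trees import nj_tree, rf_distance


@dataclass
class ExperimentConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    n_replicates: int = 10
    seed: int = 0
    gap_tolerance: float = 0.95
    min_species: int = 4  # replicate aborts below this in either arm

    def replicate_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s % (2**31)) for s in ss.generate_state(self.n_replicates)]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReplicateResult:
    seed: int
    rf_curated: int
    rf_uncurated: int
    n_species_scored: int
    n_rows_dropped: int


@dataclass
class ExperimentReport:
    replicates: list[ReplicateResult]
    fraction_curated_le_uncurated: float
    mean_rf_curated: float
    mean_rf_uncurated: float
    config_hash: str
    n_failed: int = 0

    def summary(self) -> str:
        lines = [
            "Curation-vs-concordance experiment",
            f"  replicates scored: {len(self.replicates)} (failed: {self.n_failed})",
            f"  RF(curated) <= RF(uncurated) in "
            f"{self.fraction_curated_le_uncurated:.0%} of replicates",
            f"  mean RF curated:   {self.mean_rf_curated:.3f}",
            f"  mean RF uncurated: {self.mean_rf_uncurated:.3f}",
            f"  config hash: {self.config_hash}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "replicates": [asdict(r) for r in self.replicates],
                "fraction_curated_le_uncurated": self.fraction_curated_le_uncurated,
                "mean_rf_curated": self.mean_rf_curated,
                "mean_rf_uncurated": self.mean_rf_uncurated,
                "n_failed": self.n_failed,
                "config_hash": self.config_hash,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _curated_row_ids(bundle) -> list[str]:
    """Rows of the p53 alignment passing the interaction-domain filter."""
    aln = bundle.alignments["p53"]
    pattern = tad_fxxxwxxl_pattern()
    profiles: list[ArchitectureProfile] = []
    for rid, _ in aln.rows:
        sp = bundle.species_map[rid]
        truth_domains = bundle.architecture_truth[sp]["p53"]
        domains = {Domain(d) for d in truth_domains}
        residues = aln.ungapped(rid)
        hits = scan_motif(residues, pattern, record_id=rid) if residues else []
        profiles.append(
            ArchitectureProfile(
                record_id=rid,
                family=Family.P53_FAMILY,
                domains_present=domains,
                tad_motif_exactish=bool(hits),
                species=sp,
            )
        )
    decisions = curate_family(profiles, Family.P53_FAMILY)
    return [d.record_id for d in decisions if d.kept]


def _representatives(aln: Alignment, row_ids: list[str], species_map: dict[str, str]) -> dict[str, str]:
    """One row id per species: longest ungapped row, ties by smallest id."""
    best: dict[str, tuple[int, str]] = {}
    for rid in row_ids:
        sp = species_map[rid]
        length = len(aln.ungapped(rid))
        key = (-length, rid)
        if sp not in best or key < best[sp]:
            best[sp] = key
    return {sp: rid for sp, (_, rid) in best.items()}


def _arm_tree(aln: Alignment, reps: dict[str, str], model: SubstitutionModel,
              gap_tolerance: float):
    rows = [(sp, aln.row(rid)) for sp, rid in sorted(reps.items())]
    sub = Alignment(rows)
    stripped, _ = strip_gap_columns(sub, gap_tolerance)
    D = distance_matrix(stripped, model)
    return nj_tree(D)


def run_replicate(config: ExperimentConfig, seed: int) -> ReplicateResult:
    sim_cfg = replace(config.sim, seed=seed)
    bundle = simulate_bundle(sim_cfg)
    aln = bundle.alignments["p53"]
    all_ids = aln.ids
    kept_ids = _curated_row_ids(bundle)

    reps_curated = _representatives(aln, kept_ids, bundle.species_map)
    reps_uncurated = _representatives(aln, all_ids, bundle.species_map)
    common = set(reps_curated)
    if len(common) < config.min_species:
        raise RuntimeError(
            f"replicate seed {seed}: only {len(common)} species pass curation"
        )

    model = SubstitutionModel(alpha=sim_cfg.alpha, n_categories=sim_cfg.n_categories)
    tree_curated = _arm_tree(aln, reps_curated, model, config.gap_tolerance)
    tree_uncurated = _arm_tree(aln, reps_uncurated, model, config.gap_tolerance)

    true_tree = bundle.species_tree.restrict_to(common)
    rf_c = rf_distance(tree_curated.restrict_to(common), true_tree)
    rf_u = rf_distance(tree_uncurated.restrict_to(common), true_tree)
    return ReplicateResult(
        seed=seed,
        rf_curated=rf_c,
        rf_uncurated=rf_u,
        n_species_scored=len(common),
        n_rows_dropped=len(all_ids) - len(kept_ids),
    )


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run all replicates and assemble the report (bit-identical for a fixed
    config and seed)."""
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    results: list[ReplicateResult] = []
    failed = 0
    for seed in config.replicate_seeds():
        try:
            results.append(run_replicate(config, seed))
        except (RuntimeError, ValueError):
            failed += 1
    if not results:
        raise RuntimeError("every replicate failed")
    frac = float(np.mean([r.rf_curated <= r.rf_uncurated for r in results]))
    return ExperimentReport(
        replicates=results,
        fraction_curated_le_uncurated=frac,
        mean_rf_curated=float(np.mean([r.rf_curated for r in results])),
        mean_rf_uncurated=float(np.mean([r.rf_uncurated for r in results])),
        config_hash=config.config_hash(),
        n_failed=failed,
    )
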