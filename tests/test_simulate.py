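"""The ground-truthed generator: loss histories, coupled traits, anchored
motifs, gap-block emission, WGD paralogs and determinism."""

import numpy as np
import pytest

from coevotree.coevolution import co_loss_statistic, dollo_losses
from coevotree.curation import Presence
from coevotree.io import read_alignment_fasta
from coevotree.motifs import tad_motif_present
from coevotree.simulate import (
    SimConfig,
    mask_unknown_species,
    simulate_bundle,
    simulate_domain_history,
)

BALANCED_8 = (
    "(((s1:0.2,s2:0.2):0.2,(s3:0.2,s4:0.2):0.2):0.2,"
    "((s5:0.2,s6:0.2):0.2,(s7:0.2,s8:0.2):0.2):0.2);"
)


def cfg(**kwargs) -> SimConfig:
    base = dict(seed=1, n_species=8)
    base.update(kwargs)
    return SimConfig(**base)


class TestDomainHistory:
    def test_zero_loss_rate_keeps_everything(self):
        tree, events, truth = simulate_domain_history(cfg(loss_rate_per_branch=0.0))
        assert events == []
        assert all("TAD" in v["p53"] and "P53BD" in v["mdm"] for v in truth.values())

    def test_full_coupling_gives_identical_loss_sets(self):
        for seed in range(6):
            _, events, _ = simulate_domain_history(
                cfg(seed=seed, coupling_kappa=1.0, loss_rate_per_branch=0.6)
            )
            tad = {clade for trait, clade in events if trait == "TAD"}
            bd = {clade for trait, clade in events if trait == "P53BD"}
            assert tad == bd

    def test_determinism(self):
        c = cfg(seed=99)
        out1 = simulate_domain_history(c)
        out2 = simulate_domain_history(c)
        assert out1[1] == out2[1]
        assert out1[2] == out2[2]
        assert out1[0].to_newick() == out2[0].to_newick()

    def test_explicit_tree_is_respected(self):
        tree, _, truth = simulate_domain_history(
            cfg(species_tree=BALANCED_8, loss_rate_per_branch=0.0)
        )
        assert sorted(tree.leaf_labels) == [f"s{i}" for i in range(1, 9)]
        assert set(truth) == set(tree.leaf_labels)

    def test_dollo_recovers_loss_events(self):
        """Whenever no clade is pruned entirely, Dollo on the truth table
        reproduces the simulated TAD loss branches exactly."""
        checked = 0
        for seed in range(10):
            bundle = simulate_bundle(cfg(seed=seed, loss_rate_per_branch=0.4))
            pm = bundle.presence_matrix()
            losses = dollo_losses(bundle.species_tree, pm.vector("TAD"), "TAD")
            expected = {c for t, c in bundle.loss_events if t == "TAD"}
            if all(
                pm.get(sp, "TAD") is Presence.ABSENT for sp in pm.species
            ):
                assert losses.no_observed_presence
                continue
            assert losses.branches == expected
            checked += 1
        assert checked >= 5

    def test_independence_when_uncoupled(self):
        """With kappa=0 the per-branch joint loss frequency factorises."""
        joint = {}
        marg_tad = {}
        marg_bd = {}
        n = 400
        for seed in range(n):
            _, events, _ = simulate_domain_history(
                SimConfig(
                    seed=seed,
                    n_species=8,
                    species_tree=BALANCED_8,
                    coupling_kappa=0.0,
                    loss_rate_per_branch=0.5,
                )
            )
            tad = {c for t, c in events if t == "TAD"}
            bd = {c for t, c in events if t == "P53BD"}
            for c in tad | bd | set(joint):
                joint[c] = joint.get(c, 0) + (c in tad and c in bd)
                marg_tad[c] = marg_tad.get(c, 0) + (c in tad)
                marg_bd[c] = marg_bd.get(c, 0) + (c in bd)
        for c in joint:
            p_joint = joint[c] / n
            p_prod = (marg_tad[c] / n) * (marg_bd[c] / n)
            se = np.sqrt(max(p_prod * (1 - p_prod), 1e-4) / n)
            assert abs(p_joint - p_prod) < 5 * se + 0.02


class TestBundle:
    def test_anchor_residues_exact_while_partner_present(self):
        bundle = simulate_bundle(cfg(seed=3, loss_rate_per_branch=0.3))
        config = bundle.config
        tad_len = dict((n, l) for n, l, _ in config.p53_layout)["TAD"]
        motif_start = config.motif_offset_in_tad
        for rid, row in bundle.alignments["p53"].rows:
            sp = bundle.species_map[rid]
            tad_present = "TAD" in bundle.architecture_truth[sp]["p53"]
            bd_present = "P53BD" in bundle.architecture_truth[sp]["mdm"]
            if tad_present and bd_present:
                window = row[: tad_len][motif_start : motif_start + 8]
                assert window[0] == "F" and window[4] == "W" and window[7] == "L"
                assert tad_motif_present(row.replace("-", ""))

    def test_lost_tad_emitted_as_gap_block(self):
        found_losers = False
        for seed in range(10):
            bundle = simulate_bundle(cfg(seed=seed, loss_rate_per_branch=0.6))
            config = bundle.config
            tad_len = dict((n, l) for n, l, _ in config.p53_layout)["TAD"]
            losers = {
                sp for sp, v in bundle.architecture_truth.items() if "TAD" not in v["p53"]
            }
            found_losers = found_losers or bool(losers)
            for rid, row in bundle.alignments["p53"].rows:
                sp = bundle.species_map[rid]
                if sp in losers:
                    assert set(row[:tad_len]) == {"-"}
                    assert "-" not in row[tad_len:]
        assert found_losers, "losses occur at this rate across seeds"

    def test_wgd_duplicates_rows_in_clade(self):
        bundle = simulate_bundle(cfg(seed=2, loss_rate_per_branch=0.0))
        assert bundle.wgd_clade is not None
        copies: dict[str, set[str]] = {}
        for rid in bundle.alignments["p53"].ids:
            sp = bundle.species_map[rid]
            copies.setdefault(sp, set()).add(rid.rsplit("_", 1)[-1])
        for sp, cps in copies.items():
            if sp in bundle.wgd_clade:
                assert cps == {"A", "B"}
            else:
                assert cps == {"A"}

    def test_wgd_none_single_copy(self):
        bundle = simulate_bundle(cfg(seed=2, wgd=None, loss_rate_per_branch=0.0))
        assert bundle.wgd_clade is None
        assert bundle.alignments["p53"].n_rows == 8

    def test_released_motif_can_decay(self):
        """With uncoupled losses and a strong release, TAD-retaining tips whose
        partner is gone lose the exact motif in at least some lineages, while
        partner-retaining tips never do."""
        released_rows = []
        decayed = 0
        for seed in range(12):
            bundle = simulate_bundle(
                SimConfig(
                    seed=seed,
                    n_species=12,
                    coupling_kappa=0.0,
                    release_factor=8.0,
                    loss_rate_per_branch=0.5,
                    tree_height=1.0,
                )
            )
            for rid, row in bundle.alignments["p53"].rows:
                sp = bundle.species_map[rid]
                tad = "TAD" in bundle.architecture_truth[sp]["p53"]
                bd = "P53BD" in bundle.architecture_truth[sp]["mdm"]
                if tad and not bd:
                    released_rows.append(rid)
                    decayed += not tad_motif_present(row.replace("-", ""))
        assert released_rows, "released lineages occur at these rates"
        assert decayed > 0, "strong release degrades the motif in some lineages"

    def test_determinism_and_fasta_round_trip(self, tmp_path):
        c = cfg(seed=11)
        b1 = simulate_bundle(c)
        b2 = simulate_bundle(c)
        assert b1.alignments["p53"] == b2.alignments["p53"]
        assert b1.alignments["mdm"] == b2.alignments["mdm"]
        b1.write(tmp_path)
        back = read_alignment_fasta(tmp_path / "family_p53.aln.fasta")
        assert back == b1.alignments["p53"]
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "species_tree.nwk").exists()

    def test_mask_unknown_species(self):
        bundle = simulate_bundle(cfg(seed=1))
        pm = bundle.presence_matrix()
        target = pm.species[0]
        masked = mask_unknown_species(pm, {target})
        assert masked.get(target, "TAD") is Presence.UNKNOWN
        assert masked.get(pm.species[1], "TAD") is pm.get(pm.species[1], "TAD")
        with pytest.raises(ValueError):
            mask_unknown_species(pm, {"not_a_species"})


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 2},
            {"coupling_kappa": 1.5},
            {"release_factor": 0.5},
            {"loss_rate_per_branch": -1},
            {"motif_offset_in_tad": 59},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cfg(**kwargs)

    def test_wgd_clade_must_match_branch(self):
        with pytest.raises(ValueError, match="wgd"):
            simulate_bundle(cfg(species_tree=BALANCED_8, wgd="s1,s3"))
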