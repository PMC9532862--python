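import dataclasses
import json

import numpy as np
import pytest

import cernet
from cernet import SimulationConfig, simulate_counts, simulate_sequences
from cernet.network import pearson, spearman
from cernet.simulate import (read_fixture_bundle, write_fixture_bundle,
                             write_site)
from cernet.targets import find_seed_sites


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"replicates_per_group": 1},
        {"n_planted_triples": 100, "n_circ": 50},
        {"effect_log2fc": -1.0},
        {"effect_log2fc": float("nan")},
        {"nb_dispersion": -0.1},
        {"mirna_length_range": (18, 24)},
        {"cluster_noise_rho": 1.5},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()


class TestSimulateCounts:
    def test_determinism_same_seed(self):
        cfg = SimulationConfig(n_mrna=50, n_mirna=20, n_circ=20, seed=9,
                               n_planted_triples=4, n_planted_de_per_layer=6)
        m1, d1, t1 = simulate_counts(cfg)
        m2, d2, t2 = simulate_counts(cfg)
        for layer in m1:
            assert m1[layer].values.equals(m2[layer].values)
        assert t1.planted_triples == t2.planted_triples

    def test_design_matches_study_layout(self, fixture_bundle):
        design = fixture_bundle[1]
        groups = design.groups
        assert sorted(groups.unique()) == ["LL", "LN", "TL", "TN"]
        assert (groups.value_counts() == 3).all()
        assert design.comparisons() == [("TN", "TL"), ("LN", "LL")]

    def test_planted_triple_correlation_structure(self):
        """Planted triples show the ceRNA signature within TN+TL samples."""
        cfg = SimulationConfig(n_mrna=200, n_mirna=50, n_circ=60,
                               n_planted_triples=10, effect_log2fc=2,
                               nb_dispersion=0.05, seed=42)
        matrices, design, truth = simulate_counts(cfg)
        samples = (design.samples_in_group("TN")
                   + design.samples_in_group("TL"))
        for c, m, g in truth.planted_triples:
            mir = matrices["miRNA"].values.loc[m, samples]
            gene = matrices["mRNA"].values.loc[g, samples]
            circ = matrices["circRNA"].values.loc[c, samples]
            assert spearman(mir, gene) < 0
            assert pearson(circ, gene) > 0

    def test_planted_de_has_true_fold_change(self):
        """Expected group means differ by >= 2-fold for every planted DE feature."""
        cfg = SimulationConfig(seed=3)
        matrices, design, truth = simulate_counts(cfg)
        tn = design.samples_in_group("TN")
        tl = design.samples_in_group("TL")
        for layer in ("circRNA", "miRNA", "mRNA"):
            vals = matrices[layer].values
            for fid, direction in truth.planted_de[layer]:
                lfc = np.log2((vals.loc[fid, tl].mean() + 1)
                              / (vals.loc[fid, tn].mean() + 1))
                assert abs(lfc) >= 1.0
                assert (lfc > 0) == (direction == "up")

    def test_triple_members_are_planted_de_with_opposite_directions(
            self, fixture_bundle):
        truth = fixture_bundle[2]
        de = {layer: dict(pairs) for layer, pairs in truth.planted_de.items()}
        for c, m, g in truth.planted_triples:
            assert de["circRNA"][c] == de["mRNA"][g]
            assert de["miRNA"][m] != de["mRNA"][g]

    def test_no_planted_structure_when_zero_triples(self):
        cfg = SimulationConfig(n_planted_triples=0, n_planted_de_per_layer=0,
                               seed=1)
        _, _, truth = simulate_counts(cfg)
        assert truth.planted_triples == []
        assert all(not s for s in truth.planted_de.values())


class TestSimulateSequences:
    def test_every_planted_site_found_by_scanner(self, fixture_bundle):
        _, _, truth, mirna_seqs, utr_seqs, circ_seqs = fixture_bundle
        assert truth.planted_sites, "fixture must plant sites"
        for rec in truth.planted_sites:
            circular = rec["target_layer"] == "circRNA"
            seqs = circ_seqs if circular else utr_seqs
            found = find_seed_sites(mirna_seqs[rec["mirna"]],
                                    seqs[rec["target"]],
                                    "circular" if circular else "linear")
            assert any(s.position == rec["position"]
                       and s.site_type == rec["site_type"]
                       and s.spans_junction == rec["spans_junction"]
                       for s in found)

    def test_junction_sites_exist_and_hide_from_linear_scan(
            self, fixture_bundle):
        _, _, truth, mirna_seqs, _, circ_seqs = fixture_bundle
        wrapped = [r for r in truth.planted_sites if r["spans_junction"]]
        assert wrapped, "default junction fraction must wrap some sites"
        for rec in wrapped:
            linear = find_seed_sites(mirna_seqs[rec["mirna"]],
                                     circ_seqs[rec["target"]], "linear")
            assert all(s.position != rec["position"] for s in linear)

    def test_background_targets_carry_no_planted_mirna_sites(
            self, fixture_bundle):
        _, _, truth, mirna_seqs, utr_seqs, circ_seqs = fixture_bundle
        planted_mirnas = {m for _, m, _ in truth.planted_triples}
        with_sites = {(r["mirna"], r["target"]) for r in truth.planted_sites}
        background_genes = [g for g in list(utr_seqs)
                            if all((m, g) not in with_sites
                                   for m in planted_mirnas)][:20]
        for m in planted_mirnas:
            for g in background_genes:
                assert find_seed_sites(mirna_seqs[m], utr_seqs[g]) == []

    def test_mirna_lengths_in_mature_range(self, fixture_bundle):
        mirna_seqs = fixture_bundle[3]
        assert all(21 <= len(s) <= 24 for s in mirna_seqs.values())

    def test_site_position_beyond_target_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            write_site(list("ACGUACGUACGU"), 8, "UGAGGUAGUAGGUUGUAUAGUU",
                       "8mer", circular=False)


class TestWrittenSiteClasses:
    @pytest.mark.parametrize("stype", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
    def test_written_class_is_exact(self, stype):
        rng = np.random.default_rng(0)
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        for _ in range(20):
            seq = list("".join(rng.choice(list("ACGU"), size=40)))
            write_site(seq, 10, mir, stype, circular=False)
            sites = [s for s in find_seed_sites(mir, "".join(seq))
                     if abs(s.position - 11) <= 1]
            assert [s.site_type for s in sites] == [stype]


class TestFixtureBundle:
    def test_roundtrip_and_manifest(self, tmp_path, fixture_bundle,
                                    default_config):
        matrices, design, truth, mir, utr, circ = fixture_bundle
        manifest = write_fixture_bundle(tmp_path / "b", matrices, design,
                                        truth, mir, utr, circ, default_config)
        m2, d2, t2, mir2, utr2, circ2 = read_fixture_bundle(tmp_path / "b")
        for layer in matrices:
            assert np.array_equal(matrices[layer].values.to_numpy(),
                                  m2[layer].values.to_numpy())
        assert d2.groups.tolist() == design.groups.tolist()
        assert t2.planted_triples == truth.planted_triples
        assert mir2 == mir and utr2 == utr and circ2 == circ
        listed = set(manifest["files"])
        on_disk = {f.name for f in (tmp_path / "b").iterdir()} - \
            {"manifest.json"}
        assert listed == on_disk

    def test_checksums_stable_under_fixed_seed(self, tmp_path,
                                               default_config):
        bundles = []
        for sub in ("x", "y"):
            b = cernet.simulate_all(default_config)
            bundles.append(write_fixture_bundle(tmp_path / sub, b[0], b[1],
                                                b[2], b[3], b[4], b[5]))
        assert bundles[0]["files"] == bundles[1]["files"]

    def test_truth_json_roundtrip(self, tmp_path, fixture_bundle):
        truth = fixture_bundle[2]
        truth.to_json(tmp_path / "t.json")
        back = cernet.GroundTruth.from_json(tmp_path / "t.json")
        assert back.planted_triples == truth.planted_triples
        assert back.planted_de == truth.planted_de
        assert back.planted_sites == truth.planted_sites
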