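import numpy as np
import pandas as pd
import pytest

from degnet import io as dio
from degnet.clinical import spearman
from degnet.network import integrate, mark_degs, parse_pathway, select_hub_degs
from degnet.ppi import classify_pairs, extract_subnetwork
from degnet.screen import filter_mapped, rpkm_matrix, screen_paired
from degnet.simulate import (
    SimulationConfig,
    calibrate_latent_r,
    clinical_gene_map,
    make_truth,
    simulate_bundle,
    simulate_clinical,
    simulate_clinical_expression,
    simulate_ct_table,
    simulate_paired_discovery,
    simulate_pathways,
    simulate_ppi_and_locations,
    simulate_validation_cohort,
)


class TestDiscovery:
    def test_matrix_shape_and_pair_naming(self, small_config):
        expr, truth = simulate_paired_discovery(small_config)
        assert expr.values.shape == (small_config.n_genes, 2 * small_config.n_pairs)
        assert expr.samples[:2] == ["1ca", "1adj"]
        assert len(truth) == small_config.n_genes

    def test_same_seed_reproduces_identical_matrices(self, small_config):
        a, _ = simulate_paired_discovery(small_config)
        b, _ = simulate_paired_discovery(small_config)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_different_seeds_differ(self, small_config):
        a, _ = simulate_paired_discovery(small_config)
        cfg2 = SimulationConfig(**{**small_config.__dict__, "seed": 8})
        b, _ = simulate_paired_discovery(cfg2)
        assert not a.values.equals(b.values)

    def test_unit_fold_leaves_truth_empty_and_screen_quiet(self):
        cfg = SimulationConfig(seed=3, n_genes=2000, effect_fold=1.0,
                               planted_up=0, planted_down=0)
        expr, truth = simulate_paired_discovery(cfg)
        assert (truth["direction"] == "null").all()
        mapped = filter_mapped(rpkm_matrix(expr))
        fp = len(screen_paired(mapped)) / cfg.n_genes
        assert fp < 0.01

    def test_planted_baseline_realized_in_rpkm(self, small_config):
        expr, truth = simulate_paired_discovery(small_config)
        r = rpkm_matrix(expr)
        planted = truth.index[truth["direction"] == "up"]
        adj_mean = r.adjacent_matrix().loc[planted].to_numpy().mean()
        assert adj_mean == pytest.approx(small_config.baseline_rpkm, rel=0.25)


class TestValidationCohort:
    def test_column_counts_and_labels(self, small_config):
        truth = make_truth(small_config)
        counts, groups = simulate_validation_cohort(small_config, truth)
        assert counts.shape[1] == small_config.n_tumor + small_config.n_normal
        assert (groups == "tumor").sum() == small_config.n_tumor

    def test_label_permutation_destroys_planted_signal(self, small_config):
        from degnet.validation import cohort_de

        truth = make_truth(small_config)
        counts, groups = simulate_validation_cohort(small_config, truth)
        planted = truth.index[truth["direction"] != "null"]
        de = cohort_de(counts, groups)
        assert (de.loc[planted, "direction"] != "ns").mean() > 0.9
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(groups.to_numpy()), index=groups.index)
        de_perm = cohort_de(counts, perm)
        hit = sum(de_perm.loc[g, "direction"] == truth.loc[g, "direction"]
                  for g in planted) / len(planted)
        assert hit < 0.2


class TestPathways:
    def test_files_reparse_to_generating_counts(self, small_config, tmp_path):
        truth = make_truth(small_config)
        paths, hubs = simulate_pathways(small_config, truth, tmp_path)
        graph = integrate([parse_pathway(p) for p in sorted(paths)])
        c = small_config
        assert graph.n_nodes == c.planted_hub_count + c.n_pathways * (c.pathway_size - 1)
        edges_per_pw = (c.hub_degree - 1) + c.deg_leaves_per_pathway + 1 + 1
        assert graph.n_edges == c.n_pathways * edges_per_pw
        assert all(graph.degree((h,)) == c.hub_degree for h in hubs)

    def test_planted_hubs_recovered_exactly(self, small_config, tmp_path):
        truth = make_truth(small_config)
        paths, hubs = simulate_pathways(small_config, truth, tmp_path)
        graph = integrate([parse_pathway(p) for p in sorted(paths)])
        degs = {g: d for g, d in truth["direction"].items() if d != "null"}
        mark_degs(graph, degs)
        sel = select_hub_degs(graph, 0.10)
        assert sorted(sel.hub_genes) == sorted(hubs)

    def test_leaf_wired_hubs_are_not_recovered(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_genes=800, planted_up=30, planted_down=20,
                               hub_degree=1, deg_leaves_per_pathway=2)
        truth = make_truth(cfg)
        paths, hubs = simulate_pathways(cfg, truth, tmp_path)
        graph = integrate([parse_pathway(p) for p in sorted(paths)])
        degs = {g: d for g, d in truth["direction"].items() if d != "null"}
        mark_degs(graph, degs)
        sel = select_hub_degs(graph, 0.10)
        assert sorted(sel.hub_genes) != sorted(hubs)


class TestPpiAndLocations:
    def test_planted_pairs_recovered_and_trans_chromosomal(self, small_config):
        truth = make_truth(small_config)
        edges, locations, planted = simulate_ppi_and_locations(small_config, truth)
        seeds = {g for p in planted for g in p}
        sub = extract_subnetwork(edges, seeds)
        assert set(planted) <= set(sub.seed_edges)
        for pair in classify_pairs(planted, locations):
            assert pair.colocation == "different_chromosomes"

    def test_background_edge_count(self, small_config):
        truth = make_truth(small_config)
        edges, _, planted = simulate_ppi_and_locations(small_config, truth)
        assert len(edges) == len(planted) + small_config.ppi_background_edges


class TestClinical:
    def test_seed_deterministic(self, small_config):
        truth = make_truth(small_config)
        expr = simulate_clinical_expression(small_config, truth)
        t1, _ = simulate_clinical(small_config, expr, truth)
        t2, _ = simulate_clinical(small_config, expr, truth)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_null_rho_stays_within_sampling_band(self):
        cfg = SimulationConfig(seed=21, n_clinical_samples=500,
                               planted_rho={"node": 0.0})
        truth = make_truth(cfg)
        expr = simulate_clinical_expression(cfg, truth)
        table, ctruth = simulate_clinical(cfg, expr, truth)
        gene = ctruth.loc["node", "gene_id"]
        rho, _ = spearman(expr.loc[gene].to_numpy(), table.data["node"].to_numpy())
        assert abs(rho) < 2 / np.sqrt(cfg.n_clinical_samples)

    def test_ordinal_codes_within_declared_ranges(self, small_config):
        truth = make_truth(small_config)
        expr = simulate_clinical_expression(small_config, truth)
        table, _ = simulate_clinical(small_config, expr, truth)
        assert table.data["tumor_size"].between(1, 4).all()
        assert table.data["node"].isin([0, 1]).all()

    def test_unattainable_rho_rejected(self):
        with pytest.raises(ValueError, match="unattainable"):
            calibrate_latent_r(0.9, (0.9, 0.1))

    def test_gene_map_assigns_planted_genes(self, small_config):
        truth = make_truth(small_config)
        gmap = clinical_gene_map(small_config, truth)
        assert set(gmap) == set(small_config.planted_rho)
        for g in gmap.values():
            assert truth.loc[g, "direction"] != "null"


class TestCtTable:
    def test_directions_encoded_in_ct_shifts(self, small_config):
        truth = make_truth(small_config)
        up = truth.index[truth["direction"] == "up"][0]
        down = truth.index[truth["direction"] == "down"][0]
        ct = simulate_ct_table(small_config, truth, [up, down], n_patients=8)
        from degnet.validation import paired_ct_test

        assert paired_ct_test(ct, up)["direction"] == "up"
        assert paired_ct_test(ct, down)["direction"] == "down"


def test_bundle_files_feed_every_reader(small_config, tmp_path):
    files = simulate_bundle(small_config, tmp_path)
    expr = dio.read_expression(files["discovery_counts"], unit="counts")
    assert expr.n_pairs == small_config.n_pairs
    coll = dio.read_gmt(files["gene_sets"])
    assert len(coll) > 0
    edges = dio.read_ppi(files["ppi"])
    assert len(edges) > 0
    locs = dio.read_gene_locations(files["locations"])
    assert len(locs) == small_config.n_genes
    clin = dio.read_clinical(files["clinical"])
    assert len(clin.data) == small_config.n_clinical_samples
    ct = dio.read_ct_table(files["ct_table"])
    assert set(ct["tissue"]) == {"ca", "adj"}
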