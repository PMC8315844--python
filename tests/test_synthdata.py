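"""The generator must realize the statistical world it claims to realize."""

import numpy as np
import pandas as pd
import pytest

from cernaforge.synthdata import (
    SimConfig,
    generate_expression,
    generate_interactions,
    generate_genesets,
    generate_ppi,
    simulate_ct_table,
    write_bundle,
    read_bundle,
    write_gmt,
    read_gmt,
)


class TestSimConfig:
    @pytest.mark.parametrize("kwargs", [
        {"frac_de": 1.5}, {"source_recall": -0.1}, {"planted_lfc": 0.0},
        {"dispersion": -1.0}, {"n_replicates": 1}, {"n_mrna": -5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenerateExpression:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=5, n_lnc=20, n_mir=20, n_mrna=50)
        a = generate_expression(cfg)
        b = generate_expression(cfg)
        for cls in a.counts:
            pd.testing.assert_frame_equal(a.counts[cls], b.counts[cls])
            pd.testing.assert_series_equal(a.truth_de[cls], b.truth_de[cls])

    def test_no_planted_effect_means_null_labels_and_flat_fold_changes(self):
        cfg = SimConfig(seed=1, n_lnc=20, n_mir=20, n_mrna=400, frac_de=0.0)
        b = generate_expression(cfg)
        assert all((b.truth_de[cls] == "null").all() for cls in b.truth_de)
        counts = b.counts["mRNA"]
        ctrl = counts[b.samples("control")].mean(axis=1)
        trt = counts[b.samples("treated")].mean(axis=1)
        lfc = np.log2((trt + 1) / (ctrl + 1))
        assert abs(np.median(lfc)) < 0.2

    def test_planted_fraction_is_exact(self):
        cfg = SimConfig(seed=7, n_lnc=10, n_mir=10, n_mrna=200, frac_de=0.1,
                        planted_lfc=3.0)
        b = generate_expression(cfg)
        labels = b.truth_de["mRNA"]
        assert (labels != "null").sum() == 20
        assert set(labels.unique()) <= {"up", "down", "null"}

    def test_sample_map_covers_both_conditions(self, bundle):
        assert len(bundle.samples("control")) >= 2
        assert len(bundle.samples("treated")) >= 2
        for cls, counts in bundle.counts.items():
            assert list(counts.columns) == list(bundle.sample_condition.index)
            assert (counts.to_numpy() >= 0).all()
            assert (bundle.lengths[cls] >= 20).all()

    def test_negative_binomial_marginals_match_parameterization(self):
        # self-normalized 3-SE checks on >= 1000 null features
        cfg = SimConfig(seed=2, n_lnc=2, n_mir=2, n_mrna=1500, frac_de=0.0,
                        n_replicates=30, dispersion=0.1)
        b = generate_expression(cfg)
        x = b.counts["mRNA"].to_numpy().astype(float)
        mu_hat = x.mean(axis=1)
        var_theory = mu_hat + cfg.dispersion * mu_hat**2
        ratio = x.var(axis=1, ddof=1) / var_theory
        n = len(ratio)
        assert abs(ratio.mean() - 1.0) < 3 * ratio.std(ddof=1) / np.sqrt(n)


class TestGenerateInteractions:
    def test_noise_free_sources_equal_true_edges(self, noisefree_world):
        _, _, truth = noisefree_world
        for df in truth.source_tables.values():
            edges = {(r.type, r.regulator, r.target) for r in df.itertuples()}
            assert edges == truth.true_edges

    def test_each_triplet_contributes_two_true_edges(self, noisefree_world):
        cfg, _, truth = noisefree_world
        assert len(truth.planted_triplets) == cfg.n_triplets == 4
        expected = set()
        for lnc, mir, mrna in truth.planted_triplets:
            expected.add(("lnc_mir", lnc, mir))
            expected.add(("mir_mrna", mir, mrna))
        assert expected == truth.true_edges

    def test_planted_directions_are_coherent(self, noisefree_world):
        _, b, truth = noisefree_world
        for lnc, mir, mrna in truth.planted_triplets:
            d_l = b.truth_de["lncRNA"][lnc]
            d_m = b.truth_de["miRNA"][mir]
            d_g = b.truth_de["mRNA"][mrna]
            assert {d_l, d_m} == {"up", "down"}
            assert {d_g, d_m} == {"up", "down"}

    def test_zero_recall_gives_empty_tables(self, bundle, small_cfg):
        cfg = SimConfig(seed=small_cfg.seed, n_lnc=60, n_mir=40, n_mrna=300,
                        n_triplets=4, source_recall=0.0, source_fpr=0.0)
        truth = generate_interactions(cfg, bundle)
        assert all(df.empty for df in truth.source_tables.values())

    def test_insufficient_de_features_raises(self, bundle):
        cfg = SimConfig(seed=1, n_lnc=60, n_mir=40, n_mrna=300, n_triplets=10**6)
        with pytest.raises(ValueError, match="cannot plant"):
            generate_interactions(cfg, bundle)


class TestGeneratePPI:
    def test_pure_cliques_have_closed_form_edge_count(self):
        cfg = SimConfig(seed=3, ppi_n_nodes=30, ppi_n_complexes=2,
                        ppi_complex_size=5, ppi_bg_edge_prob=0.0)
        truth = generate_ppi(cfg)
        assert len(truth.edges) == 2 * 10  # 2 * C(5,2)
        assert all(len(c) == 5 for c in truth.complexes)

    def test_parameter_inconsistency_rejected(self):
        cfg = SimConfig(seed=3, ppi_n_nodes=10, ppi_n_complexes=3, ppi_complex_size=5)
        with pytest.raises(ValueError):
            generate_ppi(cfg)
        with pytest.raises(ValueError):
            generate_ppi(SimConfig(seed=3, ppi_complex_size=2))

    def test_complex_scores_exceed_standard_cutoff(self):
        truth = generate_ppi(SimConfig(seed=4))
        df = truth.edges.set_index(["protein_a", "protein_b"])["combined_score"]
        for members in truth.complexes:
            mem = sorted(members)
            for i, a in enumerate(mem):
                for b in mem[i + 1:]:
                    assert df.get((a, b), df.get((b, a))) > 0.4


class TestGenerateGenesets:
    def test_planted_set_is_maximally_de_loaded(self, bundle, small_cfg):
        cfg = SimConfig(seed=small_cfg.seed, n_lnc=60, n_mir=40, n_mrna=300,
                        n_triplets=4, planted_set_de_frac=1.0, n_genesets=20)
        truth = generate_genesets(cfg, bundle)
        de = set(bundle.truth_de["mRNA"].index[bundle.truth_de["mRNA"] != "null"])
        planted = truth.sets[truth.planted_set]
        frac_planted = len(planted & de) / len(planted)
        others = [len(truth.sets[s] & de) / len(truth.sets[s])
                  for s in truth.sets if s != truth.planted_set]
        assert frac_planted > max(others)

    def test_degenerate_sizes_rejected(self, bundle):
        with pytest.raises(ValueError):
            generate_genesets(
                SimConfig(seed=1, geneset_size_range=(0, 5)), bundle)

    def test_empty_universe_rejected(self, bundle):
        import copy
        b = copy.copy(bundle)
        b.truth_de = dict(bundle.truth_de)
        b.truth_de["mRNA"] = bundle.truth_de["mRNA"].iloc[:0]
        with pytest.raises(ValueError, match="universe"):
            generate_genesets(SimConfig(seed=1), b)


class TestSerialization:
    def test_bundle_round_trip(self, bundle, tmp_path):
        write_bundle(bundle, tmp_path)
        back = read_bundle(tmp_path)
        for cls in bundle.counts:
            pd.testing.assert_frame_equal(bundle.counts[cls], back.counts[cls])
            pd.testing.assert_series_equal(bundle.lengths[cls], back.lengths[cls])
        pd.testing.assert_series_equal(bundle.sample_condition, back.sample_condition)

    def test_gmt_round_trip(self, tmp_path):
        sets = {"S1": {"a", "b", "c"}, "S2": {"b"}}
        p = tmp_path / "x.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets

    def test_ct_table_realizes_requested_fold_change(self):
        cfg = SimConfig(seed=9)
        ct = simulate_ct_table(cfg, {"G1": 3.0}, ct_noise_sd=0.0)
        gene = ct[ct.gene_id == "G1"]
        trt = gene[gene.condition == "treated"]["ct"].mean()
        ctrl = gene[gene.condition == "control"]["ct"].mean()
        assert ctrl - trt == pytest.approx(3.0)
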