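"""Synthetic generators: planted networks, model-exact expression, DTI data."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import gwgenkit as gk
from gwgenkit.drugspec import read_drug_tables, write_drug_tables
from gwgenkit.identify import build_regression, fit_constrained
from gwgenkit.network import MIRNA_MODES


class TestCandidateGeneration:
    def test_zero_spurious_fraction_means_candidates_equal_truth(self):
        net, truth = gk.generate_candidate_gwgen(
            spurious_fraction=0.0, seed=3
        )
        assert net.edge_keys() == truth.true_edges

    def test_seeded_generation_is_deterministic(self):
        a = gk.generate_candidate_gwgen(
            n_protein=10, n_gene=20, n_lncRNA=5, n_miRNA=5,
            density=0.1, spurious_fraction=0.5, seed=1,
        )
        b = gk.generate_candidate_gwgen(
            n_protein=10, n_gene=20, n_lncRNA=5, n_miRNA=5,
            density=0.1, spurious_fraction=0.5, seed=1,
        )
        assert a[0].edge_keys() == b[0].edge_keys()
        assert a[1].abilities == b[1].abilities

    def test_spurious_share_matches_requested_fraction(self):
        # Monte-Carlo over 20 seeds: the spurious share of candidate edges
        # is binomial around 0.5
        shares = []
        for seed in range(20):
            net, truth = gk.generate_candidate_gwgen(
                density=0.3, spurious_fraction=0.5, seed=seed
            )
            shares.append(1 - len(truth.true_edges) / len(net))
        n_edges = 60  # order of magnitude of candidate edges per draw
        tol = 3 * 0.5 / np.sqrt(20 * n_edges)
        assert abs(np.mean(shares) - 0.5) < tol

    def test_mirna_abilities_nonnegative_and_coefficients_nonpositive(self):
        _, truth = gk.generate_candidate_gwgen(seed=7, spurious_fraction=0.3)
        mirna_modes = {m.value for m in MIRNA_MODES}
        seen = 0
        for key, value in truth.abilities.items():
            if key[2] in mirna_modes:
                seen += 1
                assert value >= 0
                assert truth.regression_coefficient(key) <= 0
        assert seen > 0

    def test_parameter_domain_errors(self):
        with pytest.raises(ValueError):
            gk.generate_candidate_gwgen(n_protein=0)
        with pytest.raises(ValueError):
            gk.generate_candidate_gwgen(density=1.5)


class TestExpressionSimulation:
    def test_single_tf_gene_is_direct_evaluation(self, single_gene_system):
        # g = alpha * t + lambda with alpha=2, lambda=1 and zero noise
        net, truth = single_gene_system
        expr = gk.simulate_expression(truth, net, 50, seed=1)
        g, t = expr.row("G1"), expr.row("TF1")
        np.testing.assert_allclose(g, 2.0 * t + 1.0, rtol=0, atol=1e-12)

    def test_noiseless_regression_recovers_minus_gamma_exactly(self):
        # closed-form LSQ oracle: one gene, one miRNA repressor, no noise
        from gwgenkit.network import GWGEN, Edge, EdgeMode, Node, NodeKind
        from gwgenkit.simulate import GroundTruth

        net = GWGEN.build(
            [
                Node("G1", NodeKind.GENE),
                Node("TF1", NodeKind.TF),
                Node("M1", NodeKind.MIRNA),
            ],
            [
                Edge("TF1", "G1", EdgeMode.TF_GENE),
                Edge("M1", "G1", EdgeMode.MIRNA_GENE),
                Edge("TF1", "M1", EdgeMode.TF_MIRNA),
            ],
        )
        truth = GroundTruth(
            true_edges={k.key for k in net.iter_edges()},
            abilities={
                ("TF1", "G1", "tf->gene"): 1.5,
                ("M1", "G1", "miRNA->gene"): 0.8,
                ("TF1", "M1", "tf->miRNA"): 1.0,
            },
            basal={"G1": 2.0, "M1": 0.5},
            noise_sd=0.0,
            generation_order=["M1"],
        )
        expr = gk.simulate_expression(truth, net, 40, seed=2)
        est = fit_constrained(build_regression("G1", net, expr))
        coef = est.coefficients()
        assert coef["M1"] == pytest.approx(-0.8, abs=1e-8)
        assert coef["TF1"] == pytest.approx(1.5, abs=1e-8)
        assert est.basal == pytest.approx(2.0, abs=1e-8)

    def test_true_model_residual_matches_injected_noise(self):
        # refitting the planted model on 1000 samples leaves residuals with
        # mean ~ 0 and sd ~ noise_sd
        net, truth = gk.generate_candidate_gwgen(
            spurious_fraction=0.0, noise_sd=0.1, seed=11
        )
        expr = gk.simulate_expression(truth, net, 1000, seed=12)
        resid = []
        for node in net.nodes.values():
            if node.kind.value == "TF" or node.id in truth.driver_proteins:
                continue
            prob = build_regression(node.id, net, expr)
            theta = np.array(
                [
                    truth.regression_coefficient(c.edge.key)
                    for c in prob.columns[:-1]
                ]
                + [truth.basal[node.id]]
            )
            resid.extend(prob.response - prob.design @ theta)
        resid = np.asarray(resid)
        assert abs(resid.mean()) < 0.01
        assert resid.std() == pytest.approx(0.1, rel=0.1)

    def test_identifiability_precondition_enforced(self, small_study):
        net, truth, _ = small_study
        with pytest.raises(ValueError, match="identifiability"):
            gk.simulate_expression(truth, net, 3, seed=0)


class TestDTIDataset:
    def test_separable_rule_admits_perfect_linear_classifier(self):
        spec = gk.DTIDatasetSpec(
            n_drugs=30, n_targets=30, drug_dim=20, target_dim=25,
            n_pairs=400, label_noise=0.0, seed=5,
        )
        data = gk.generate_dti_dataset(spec)
        clf = LogisticRegression(max_iter=5000, C=1e6).fit(
            data.features, data.labels
        )
        assert clf.score(data.features, data.labels) == 1.0

    def test_seeded_spec_regenerates_identical_labels(self):
        spec = gk.DTIDatasetSpec(n_pairs=200, drug_dim=10, target_dim=10,
                                 n_drugs=20, n_targets=20, seed=9)
        a, b = gk.generate_dti_dataset(spec), gk.generate_dti_dataset(spec)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.features, b.features)

    def test_label_noise_flip_rate(self):
        base = dict(n_drugs=200, n_targets=200, drug_dim=5, target_dim=5,
                    n_pairs=10_000, seed=21)
        clean = gk.generate_dti_dataset(gk.DTIDatasetSpec(**base))
        noisy = gk.generate_dti_dataset(
            gk.DTIDatasetSpec(label_noise=0.1, **base)
        )
        flip_rate = np.mean(clean.labels != noisy.labels)
        assert flip_rate == pytest.approx(0.1, abs=3 * 0.3 / np.sqrt(10_000))

    def test_requested_pairs_bounded_by_universe(self):
        with pytest.raises(ValueError, match="exist"):
            gk.generate_dti_dataset(
                gk.DTIDatasetSpec(n_drugs=3, n_targets=3, n_pairs=100)
            )

    def test_class_ratio_honored(self):
        spec = gk.DTIDatasetSpec(n_drugs=50, n_targets=50, drug_dim=8,
                                 target_dim=8, n_pairs=900,
                                 negative_ratio=2.0, seed=3)
        data = gk.generate_dti_dataset(spec)
        assert data.labels.sum() == 300


class TestDrugPanel:
    def test_sulforaphane_bindings_and_side_effect(self, drug_tables):
        biomarkers = {"IKK", "STAT3", "PPARg", "ETS1", "FAS"}
        assert biomarkers <= drug_tables.bindings["Sulforaphane"]
        assert (
            len(drug_tables.bindings["Sulforaphane"] - biomarkers) == 23
        )

    def test_biotin_regulation_and_ld50(self, drug_tables):
        assert drug_tables.regulation[("Biotin", "IKK")] == -1.214
        assert drug_tables.regulation[("Biotin", "STAT3")] == 1.075
        assert drug_tables.regulation[("Biotin", "PPARg")] == 0.969
        assert drug_tables.regulation[("Biotin", "ETS1")] == -0.986
        assert ("Biotin", "FAS") not in drug_tables.regulation
        assert drug_tables.toxicity["Biotin"] == 2.058

    def test_panel_round_trips_through_tsv(self, drug_tables, tmp_path):
        write_drug_tables(drug_tables, tmp_path)
        back = read_drug_tables(tmp_path)
        assert back.regulation == drug_tables.regulation
        assert back.toxicity == drug_tables.toxicity
        assert back.sensitivity == drug_tables.sensitivity
        assert back.bindings == drug_tables.bindings
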