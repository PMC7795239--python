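"""Principal network projection: H assembly, SVD, energies, scores, core."""

import numpy as np
import pytest

import gwgenkit as gk
from gwgenkit.network import GWGEN, Edge, EdgeMode, Node, NodeKind
from gwgenkit.pnp import (
    NetworkMatrix,
    build_network_matrix,
    decompose,
    energy_rank,
    extract_core,
    project_scores,
    run_pnp,
)


def _toy_real_network():
    nodes = [
        Node("PA", NodeKind.PROTEIN), Node("PB", NodeKind.PROTEIN),
        Node("G1", NodeKind.GENE), Node("T1", NodeKind.TF),
        Node("L1", NodeKind.LNCRNA), Node("M1", NodeKind.MIRNA),
    ]
    edges = [
        Edge("PA", "PB", EdgeMode.PPI, 1.5),
        Edge("T1", "G1", EdgeMode.TF_GENE, 2.0),
        Edge("L1", "G1", EdgeMode.LNCRNA_GENE, -0.7),
        Edge("M1", "G1", EdgeMode.MIRNA_GENE, -0.4),
        Edge("T1", "M1", EdgeMode.TF_MIRNA, 1.1),
    ]
    return GWGEN.build(nodes, edges)


class TestBuildNetworkMatrix:
    def test_ppi_ability_is_placed_symmetrically(self):
        net = GWGEN.build(
            [Node("A", NodeKind.PROTEIN), Node("B", NodeKind.PROTEIN)],
            [Edge("A", "B", EdgeMode.PPI, 1.5)],
        )
        m = build_network_matrix(net)
        a, b = m.row_index.index("A"), m.row_index.index("B")
        ca, cb = m.col_index.index("A"), m.col_index.index("B")
        assert m.H[a, cb] == 1.5 and m.H[b, ca] == 1.5
        assert m.H[a, ca] == 0.0 and m.H[b, cb] == 0.0

    def test_directed_ability_single_cell(self):
        net = GWGEN.build(
            [Node("T", NodeKind.TF), Node("G", NodeKind.GENE)],
            [Edge("T", "G", EdgeMode.TF_GENE, 2.0)],
        )
        m = build_network_matrix(net)
        assert m.H.shape == (1, 1)
        assert m.H[0, 0] == 2.0

    def test_nonzeros_count_directed_plus_twice_ppi(self):
        net = _toy_real_network()
        m = build_network_matrix(net)
        n_ppi = sum(1 for e in net.iter_edges() if e.mode is EdgeMode.PPI)
        n_dir = len(net) - n_ppi
        assert np.count_nonzero(m.H) == n_dir + 2 * n_ppi

    def test_block_ordering_rows_and_columns(self):
        m = build_network_matrix(_toy_real_network())
        assert m.row_index == ["PA", "PB", "G1", "L1", "M1"]
        # columns: ppi proteins with TFs, then lncRNAs, then miRNAs
        assert m.col_index == ["PA", "PB", "T1", "L1", "M1"]


class TestDecomposeAndEnergies:
    def test_identity_has_unit_singular_values(self):
        pnp = decompose(NetworkMatrix(np.eye(3), list("abc"), list("xyz")))
        np.testing.assert_allclose(pnp.singular_values, 1.0)

    def test_rank_one_matrix_has_single_nonzero_singular_value(self):
        u, w = np.arange(1.0, 5.0), np.arange(1.0, 4.0)
        pnp = decompose(
            NetworkMatrix(np.outer(u, w), [f"r{i}" for i in range(4)],
                          [f"c{i}" for i in range(3)])
        )
        assert np.sum(pnp.singular_values > 1e-12) == 1

    def test_svd_reconstructs_random_matrix(self):
        rng = np.random.default_rng(0)
        H = rng.standard_normal((20, 15))
        pnp = decompose(
            NetworkMatrix(H, [f"r{i}" for i in range(20)],
                          [f"c{i}" for i in range(15)])
        )
        recon = pnp.left_vectors @ np.diag(pnp.singular_values) @ pnp.right_vectors.T
        assert np.linalg.norm(recon - H) / np.linalg.norm(H) < 1e-10
        assert (np.diff(pnp.singular_values) <= 1e-12).all()

    def test_energies_sum_to_one(self):
        rng = np.random.default_rng(1)
        H = rng.standard_normal((8, 5))
        pnp = decompose(NetworkMatrix(H, list("abcdefgh"), list("vwxyz")))
        assert pnp.energies.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "values,threshold,expected",
        [
            ((1.0, 0.0, 0.0), 0.85, 1),
            ((1.0, 0.0, 0.0), 0.05, 1),
            ((1.0, 1.0, 1.0, 1.0), 0.85, 4),
            ((1.0, 1.0, 1.0, 1.0), 0.75, 3),
        ],
    )
    def test_energy_rank_minimality(self, values, threshold, expected):
        v = np.asarray(values)
        H = np.diag(v)
        pnp = decompose(
            NetworkMatrix(H, [f"r{i}" for i in range(len(v))],
                          [f"c{i}" for i in range(len(v))])
        )
        assert energy_rank(pnp, threshold) == expected

    def test_threshold_one_keeps_all_nonzero_directions(self):
        v = np.array([2.0, 1.0, 0.5, 0.0])
        pnp = decompose(
            NetworkMatrix(np.diag(v), [f"r{i}" for i in range(4)],
                          [f"c{i}" for i in range(4)])
        )
        assert energy_rank(pnp, 1.0) == 3

    def test_zero_matrix_has_undefined_energy_rank(self):
        pnp = decompose(NetworkMatrix(np.zeros((3, 3)), list("abc"), list("xyz")))
        with pytest.raises(ValueError, match="zero"):
            energy_rank(pnp)


class TestProjectionScores:
    def test_zero_row_scores_zero(self):
        H = np.array([[1.0, 2.0], [0.0, 0.0]])
        pnp = decompose(NetworkMatrix(H, ["a", "b"], ["x", "y"]))
        scores = project_scores(pnp, 1)
        assert scores["b"] == 0.0
        assert scores["a"] > 0.0

    def test_full_rank_scores_equal_squared_row_norms(self):
        rng = np.random.default_rng(2)
        H = rng.standard_normal((10, 6))
        names = [f"r{i}" for i in range(10)]
        pnp = decompose(NetworkMatrix(H, names, [f"c{i}" for i in range(6)]))
        scores = project_scores(pnp, 6)
        for i, name in enumerate(names):
            assert scores[name] == pytest.approx(float(H[i] @ H[i]), abs=1e-8)

    def test_scores_match_bruteforce_projection(self):
        rng = np.random.default_rng(3)
        H = rng.standard_normal((30, 20))
        names = [f"r{i:02d}" for i in range(30)]
        pnp = decompose(NetworkMatrix(H, names, [f"c{i}" for i in range(20)]))
        n_top = energy_rank(pnp, 0.85)
        scores = project_scores(pnp, n_top)
        _, _, Vt = np.linalg.svd(H)
        for i, name in enumerate(names):
            brute = float(np.sum((H[i] @ Vt[:n_top].T) ** 2))
            assert scores[name] == pytest.approx(brute, abs=1e-8)

    def test_ranking_invariant_under_square_root(self):
        rng = np.random.default_rng(4)
        H = rng.standard_normal((12, 7))
        names = [f"r{i}" for i in range(12)]
        pnp = decompose(NetworkMatrix(H, names, [f"c{i}" for i in range(7)]))
        scores = project_scores(pnp, 3)
        by_sq = sorted(names, key=lambda n: (-scores[n], n))
        by_rt = sorted(names, key=lambda n: (-np.sqrt(scores[n]), n))
        assert by_sq == by_rt


class TestExtractCore:
    def test_large_top_k_reproduces_whole_network(self):
        net = _toy_real_network()
        pnp = decompose(build_network_matrix(net))
        scores = project_scores(pnp, energy_rank(pnp, 0.85))
        core = extract_core(net, scores, top_k=100)
        assert core.edge_keys() == net.edge_keys()
        assert set(core.nodes) == set(net.nodes)

    def test_top_one_keeps_single_highest_scorer_without_edges(self):
        net = _toy_real_network()
        pnp = decompose(build_network_matrix(net))
        scores = project_scores(pnp, energy_rank(pnp, 0.85))
        core = extract_core(net, scores, top_k=1)
        assert len(core.nodes) == 1
        assert len(core) == 0
        top = max(scores, key=lambda n: (scores[n], n))
        assert top in core.nodes

    def test_induced_edges_match_bruteforce_filter(self, small_study):
        net, _, expr = small_study
        real = gk.prune_network(net, expr)
        if len(real) == 0:
            pytest.skip("empty pruned network in this draw")
        pnp, core = run_pnp(real, top_k=6)
        kept = set(core.nodes)
        brute = {
            e.key for e in real.iter_edges()
            if e.source in kept and e.target in kept
        }
        assert core.edge_keys() == brute

    def test_monotone_growth_with_top_k(self):
        net = _toy_real_network()
        pnp = decompose(build_network_matrix(net))
        scores = project_scores(pnp, energy_rank(pnp, 0.85))
        previous: set = set()
        for k in range(1, len(net.nodes) + 1):
            kept = set(extract_core(net, scores, top_k=k).nodes)
            assert previous <= kept
            previous = kept

    def test_invalid_top_k(self):
        net = _toy_real_network()
        with pytest.raises(ValueError):
            extract_core(net, {}, top_k=0)
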