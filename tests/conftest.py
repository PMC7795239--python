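import logging

import numpy as np
import pandas as pd
import pytest

import gwgenkit as gk
from gwgenkit.expression import ExpressionMatrix
from gwgenkit.network import GWGEN, Edge, EdgeMode, Node, NodeKind
from gwgenkit.simulate import GroundTruth

logging.getLogger("gwgenkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def drug_tables():
    return gk.t2d_candidate_drug_tables()


@pytest.fixture(scope="session")
def desired():
    return gk.t2d_desired_regulation()


@pytest.fixture(scope="session")
def small_study():
    """A small seeded candidate network + planted truth + expression."""
    net, truth = gk.generate_candidate_gwgen(
        n_protein=6, n_gene=8, n_lncRNA=3, n_miRNA=3, n_tf=4,
        density=0.3, spurious_fraction=0.5, noise_sd=0.1, seed=42,
    )
    expr = gk.simulate_expression(truth, net, 120, seed=43)
    return net, truth, expr


@pytest.fixture()
def single_gene_system():
    """One gene regulated by one TF (alpha=2, basal=1), no noise."""
    net = GWGEN.build(
        [Node("G1", NodeKind.GENE), Node("TF1", NodeKind.TF)],
        [Edge("TF1", "G1", EdgeMode.TF_GENE)],
    )
    truth = GroundTruth(
        true_edges={("TF1", "G1", "tf->gene")},
        abilities={("TF1", "G1", "tf->gene"): 2.0},
        basal={"G1": 1.0},
        noise_sd=0.0,
    )
    return net, truth


def make_expression(values: dict[str, list[float]], groups=None) -> ExpressionMatrix:
    frame = pd.DataFrame(values).T
    frame.columns = [f"S{i + 1}" for i in range(frame.shape[1])]
    n = frame.shape[1]
    if groups is None:
        groups = ["control"] * (n // 2) + ["disease"] * (n - n // 2)
    return ExpressionMatrix(frame, pd.Series(groups, index=frame.columns))
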