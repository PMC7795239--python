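"""Disease/control core-network comparison and gene-set over-representation.

The two core networks are partitioned into common, disease-only and
control-only nodes and edges; each node additionally gets an expression
direction label (higher/lower in disease, by pseudo-counted log2 fold of
group means).  Over-representation of user-supplied gene sets is tested by
the one-sided hypergeometric tail with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, GeneSetCollection
from .network import GWGEN

HIGHER = "higher-in-disease"
LOWER = "lower-in-disease"
UNCHANGED = "unchanged"

DEFAULT_MIN_ABS_LOG2FC = 0.5


@dataclass
class ComparisonResult:
    """Set partition of two core networks plus per-node direction labels."""

    common_edges: set[tuple[str, str, str]]
    disease_only_edges: set[tuple[str, str, str]]
    control_only_edges: set[tuple[str, str, str]]
    common_nodes: set[str]
    disease_only_nodes: set[str]
    control_only_nodes: set[str]
    direction: dict[str, str] | None = None


def diff_networks(core_disease: GWGEN, core_control: GWGEN) -> ComparisonResult:
    """Exact partition of both cores by edge identity (endpoints + mode)."""
    d_edges, c_edges = core_disease.edge_keys(), core_control.edge_keys()
    d_nodes, c_nodes = set(core_disease.nodes), set(core_control.nodes)
    return ComparisonResult(
        common_edges=d_edges & c_edges,
        disease_only_edges=d_edges - c_edges,
        control_only_edges=c_edges - d_edges,
        common_nodes=d_nodes & c_nodes,
        disease_only_nodes=d_nodes - c_nodes,
        control_only_nodes=c_nodes - d_nodes,
    )


def expression_direction(
    expr: ExpressionMatrix,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    nodes: set[str] | None = None,
) -> dict[str, str]:
    """Label nodes higher/lower in disease by pseudo-counted log2 fold.

    The statistic is log2((mean_disease + 1) / (mean_control + 1)); labels
    flip to higher/lower only when its magnitude reaches ``min_abs_log2fc``.
    """
    means = expr.group_means()
    if nodes is not None:
        means = means.loc[[n for n in means.index if n in nodes]]
    lfc = np.log2((means["disease"] + 1.0) / (means["control"] + 1.0))
    out = {}
    for node, value in lfc.items():
        if value >= min_abs_log2fc:
            out[node] = HIGHER
        elif value <= -min_abs_log2fc:
            out[node] = LOWER
        else:
            out[node] = UNCHANGED
    return out


def enrich(
    nodes: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    For a universe of M nodes, a set of K members (restricted to the
    universe) and a selection of n nodes with k overlapping, the p-value is
    P(X >= k) for X ~ Hypergeometric(M, K, n).  Benjamini-Hochberg q-values
    are reported alongside the raw p-values.
    """
    if not universe:
        raise ValueError("empty universe")
    if not nodes <= universe:
        raise ValueError("selection must be a subset of the universe")
    M, n = len(universe), len(nodes)
    records = []
    for name in sets.names():
        members = set(sets[name]) & universe
        K = len(members)
        k = len(members & nodes)
        # survival function at k-1 gives the inclusive upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        records.append(
            {"set": name, "set_size": K, "overlap": k, "p_value": min(p, 1.0)}
        )
    df = pd.DataFrame(records)
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.set_index("set")


def compare_cores(
    core_disease: GWGEN,
    core_control: GWGEN,
    expr: ExpressionMatrix | None = None,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
) -> ComparisonResult:
    """Partition the cores and, given expression data, label directions."""
    result = diff_networks(core_disease, core_control)
    if expr is not None:
        union = result.common_nodes | result.disease_only_nodes | result.control_only_nodes
        result.direction = expression_direction(
            expr, min_abs_log2fc, nodes={n for n in union if n in expr}
        )
    return result
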