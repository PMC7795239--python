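"""Model/Results facade for network system identification.

``NetworkSystemModel`` pairs a candidate GWGEN with expression data;
``fit()`` runs constrained least-squares identification and AIC order
detection for every target entity and returns a ``NetworkSystemResults``
holding the per-target estimates, the pruned (real) network, and principal
network projection helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .expression import ExpressionMatrix
from .io import align_network_to_expression
from .network import GWGEN, NodeKind
from .order import OrderDetection, detect_order, prune_network
from .pnp import DEFAULT_ENERGY, DEFAULT_TOP_K, PNPResult, run_pnp


class NetworkSystemModel:
    """Regression models of every entity in a candidate GWGEN.

    Each protein is regressed on products with its candidate interactors;
    each gene/lncRNA/miRNA on its candidate TF, lncRNA and (self-multiplied)
    miRNA regulators, with miRNA coefficients constrained non-positive.
    """

    def __init__(self, network: GWGEN, expression: ExpressionMatrix):
        self.network = align_network_to_expression(network, expression)
        self.expression = expression

    @classmethod
    def from_files(cls, edge_path, expr_path, groups_path) -> "NetworkSystemModel":
        from .io import read_edge_table, read_expression_table

        return cls(
            read_edge_table(edge_path),
            read_expression_table(expr_path, groups_path),
        )

    def fit(self) -> "NetworkSystemResults":
        detections: dict[str, OrderDetection] = {}
        for node in self.network.nodes_of_kind(
            NodeKind.PROTEIN, NodeKind.GENE, NodeKind.LNCRNA, NodeKind.MIRNA
        ):
            detections[node.id] = detect_order(
                node.id, self.network, self.expression
            )
        real = prune_network(self.network, self.expression)
        return NetworkSystemResults(self, detections, real)


@dataclass
class NetworkSystemResults:
    """Identified abilities, detected orders and the pruned real GWGEN."""

    model: NetworkSystemModel
    detections: dict[str, OrderDetection]
    real_network: GWGEN
    _pnp: PNPResult | None = field(default=None, repr=False)

    def abilities(self) -> pd.DataFrame:
        """One row per surviving edge with its identified ability."""
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "mode": e.mode.value,
                "ability": e.ability,
            }
            for e in sorted(self.real_network.iter_edges(), key=lambda e: e.key)
        ]
        return pd.DataFrame(rows)

    def orders(self) -> pd.DataFrame:
        """Per-target detected order, residual variance and AIC."""
        rows = []
        for target, det in sorted(self.detections.items()):
            rows.append(
                {
                    "target": target,
                    "order": det.aic.order,
                    "omega": det.aic.omega,
                    "aic": det.aic.aic,
                    "basal": det.estimate.basal,
                }
            )
        return pd.DataFrame(rows).set_index("target")

    def pnp(
        self,
        threshold: float = DEFAULT_ENERGY,
        top_k: int = DEFAULT_TOP_K,
    ) -> tuple[PNPResult, GWGEN]:
        """Principal network projection of the real GWGEN -> core GWGEN."""
        pnp, core = run_pnp(self.real_network, threshold, top_k)
        self._pnp = pnp
        return pnp, core

    def summary(self) -> str:
        n_cand = len(self.model.network)
        n_real = len(self.real_network)
        orders = self.orders()
        lines = [
            "Network system identification",
            f"  entities fitted:    {len(self.detections)}",
            f"  candidate edges:    {n_cand}",
            f"  surviving edges:    {n_real} "
            f"({100 * n_real / max(n_cand, 1):.1f}%)",
            f"  mean detected order: {orders['order'].mean():.2f}",
            f"  samples:            {self.model.expression.n_samples}",
        ]
        return "\n".join(lines)
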