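"""System order detection by AIC minimization and false-positive pruning.

The true number of interactions/regulations of each entity (its system
order) is detected by minimizing AIC = log(Omega) + 2*(order+1)/N, with
Omega = SSE/N the residual variance of the constrained fit.  Regulators are
ranked by the magnitude of their full-model coefficient and nested models of
every order are refit; edges outside the AIC-minimizing model are treated as
false positives and removed, yielding the real GWGEN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix
from .identify import (
    AbilityEstimate,
    RegressionProblem,
    build_regression,
    fit_constrained,
)
from .network import GWGEN, Edge, EdgeMode, NodeKind

logger = logging.getLogger(__name__)

#: floor applied to the residual variance of a perfect fit (log(0) guard)
OMEGA_FLOOR = 1e-12


@dataclass(frozen=True)
class AICValue:
    """AIC of one fitted model: order, residual variance and the criterion."""

    order: int
    omega: float
    aic: float


def compute_aic(sse: float, order: int, n_samples: int) -> AICValue:
    """AIC = log(SSE/N) + 2*(order+1)/N, natural logarithm.

    A zero SSE (perfect fit) is floored at ``OMEGA_FLOOR`` so the criterion
    stays finite; parsimony then decides among perfect fits via the penalty.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    omega = sse / n_samples
    if omega <= OMEGA_FLOOR:
        logger.warning("sse ~ 0 for order %d; flooring omega at %g", order, OMEGA_FLOOR)
        omega = OMEGA_FLOOR
    aic = float(np.log(omega) + 2.0 * (order + 1) / n_samples)
    return AICValue(order, omega, aic)


@dataclass
class OrderDetection:
    """Outcome of the nested AIC search for one target."""

    target_id: str
    estimate: AbilityEstimate  # refit at the AIC-minimizing order
    aic: AICValue
    retained: list[Edge]
    searched: list[AICValue]  # AIC per nested order 0..K


def detect_order(
    target_id: str,
    network: GWGEN,
    expr: ExpressionMatrix,
    problem: RegressionProblem | None = None,
) -> OrderDetection:
    """Detect a target's system order by backward one-by-one AIC search.

    Starting from the full constrained fit, regulators are removed one at a
    time — always the one with the smallest standardized coefficient
    magnitude (|coefficient| * column scale) in the *current* refit — down
    to the empty model, and the AIC-minimizing member of this nested family
    is returned (ties resolved toward smaller order).  Refitting after each
    removal keeps the ranking meaningful when regressor columns are
    correlated, which the self-multiplied miRNA product columns routinely
    are.
    """
    if problem is None:
        problem = build_regression(target_id, network, expr)
    n = problem.n_samples
    k_max = problem.order
    col_scale = problem.design[:, :-1].std(axis=0)

    keep = list(range(k_max))
    best: tuple[AICValue, AbilityEstimate, list[int]] | None = None
    searched: list[AICValue] = []
    while True:
        k = len(keep)
        sub = problem.subproblem(keep)
        est = fit_constrained(sub)
        aic = compute_aic(est.sse, k, n)
        searched.append(aic)
        # smaller orders come later in the backward sweep and replace the
        # incumbent on AIC ties, so ties resolve toward parsimony
        if best is None or aic.aic < best[0].aic + 1e-15:
            best = (aic, est, list(keep))
        if not keep:
            break
        weakest = int(np.argmin(np.abs(est.theta[:-1]) * col_scale[keep]))
        keep.pop(weakest)
    assert best is not None
    aic, est, keep = best
    retained = [problem.columns[i].edge for i in keep]
    searched.reverse()  # order 0..K, matching the nested family
    return OrderDetection(target_id, est, aic, retained, searched)


def prune_network(network: GWGEN, expr: ExpressionMatrix) -> GWGEN:
    """Apply order detection to every target entity; assemble the real GWGEN.

    Surviving edges carry their refit abilities.  An undirected ppi edge
    makes a claim about both endpoints' models, so it survives only if both
    endpoints' detected models retain it; the stored ability is the mean of
    the two endpoint estimates.
    """
    ppi_hits: dict[tuple[str, str, str], list[float]] = {}
    directed: list[Edge] = []
    detections: dict[str, OrderDetection] = {}
    targets = network.nodes_of_kind(
        NodeKind.PROTEIN, NodeKind.GENE, NodeKind.LNCRNA, NodeKind.MIRNA
    )
    for node in targets:
        det = detect_order(node.id, network, expr)
        detections[node.id] = det
        coeffs = det.estimate.theta[:-1]
        for edge, coef in zip(det.retained, coeffs):
            if edge.mode is EdgeMode.PPI:
                ppi_hits.setdefault(edge.key, []).append(float(coef))
            else:
                directed.append(edge.with_ability(float(coef)))

    real = GWGEN()
    for key, abilities in ppi_hits.items():
        if len(abilities) < 2:  # retained by only one endpoint's model
            continue
        src, tgt, _ = key
        real.add_node(network.nodes[src])
        real.add_node(network.nodes[tgt])
        real.add_edge(Edge(src, tgt, EdgeMode.PPI, float(np.mean(abilities))))
    for e in directed:
        real.add_node(network.nodes[e.source])
        real.add_node(network.nodes[e.target])
        real.add_edge(e)
    # keep isolated detected targets (order 0) out of the edge set but in
    # the node set only if some surviving edge touches them -- the real
    # GWGEN is an edge-supported network
    logger.info(
        "pruned %d candidate edges to %d surviving edges",
        len(network), len(real),
    )
    return real
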