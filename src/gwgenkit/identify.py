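"""System identification: constrained least-squares estimation of
interaction and regulation abilities.

Each entity of the candidate GWGEN defines one linear regression.  For a
protein target q the regressors are the elementwise products p_q[n]*p_r[n]
over its candidate interactors r; for a gene/lncRNA/miRNA target the
regressors are candidate TF expressions t_u[n], lncRNA expressions l_v[n]
and the products m_w[n]*(target expression)[n] for candidate miRNA
repressors; a trailing all-ones column carries the basal level lambda.
miRNA-regulation coefficients are constrained to be non-positive (miRNA
repression enters the model negatively), so the fit is a box-constrained
convex least-squares problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .expression import ExpressionMatrix
from .network import GWGEN, Edge, EdgeMode, MIRNA_MODES, NodeKind

logger = logging.getLogger(__name__)

#: convergence tolerance of the box-constrained solver
SOLVER_TOL = 1e-12

BASAL = "<basal>"


class IdentifiabilityError(ValueError):
    """Regressor count + 1 would reach the sample count (overfit regime)."""


@dataclass
class ColumnMeta:
    """Provenance of one design column: the candidate edge and its class."""

    regulator: str
    mode: EdgeMode | None  # None for the basal column
    edge: Edge | None

    @property
    def is_mirna(self) -> bool:
        return self.mode in MIRNA_MODES


@dataclass
class RegressionProblem:
    """One entity's linear regression y = Phi theta + eps.

    ``design`` is N x (O+1) with the basal all-ones column last;
    ``mirna_mask`` flags the sign-constrained (miRNA-regulation) columns.
    """

    target_id: str
    response: np.ndarray
    design: np.ndarray
    columns: list[ColumnMeta]
    truncated: list[str] | None = None  # regulators dropped for identifiability

    @property
    def n_samples(self) -> int:
        return self.response.shape[0]

    @property
    def order(self) -> int:
        return self.design.shape[1] - 1

    @property
    def mirna_mask(self) -> np.ndarray:
        return np.array([c.is_mirna for c in self.columns], dtype=bool)

    def subproblem(self, keep: list[int]) -> "RegressionProblem":
        """Restrict to a subset of regulator columns (basal always kept)."""
        basal = self.design.shape[1] - 1
        idx = [*keep, basal]
        return RegressionProblem(
            self.target_id,
            self.response,
            self.design[:, idx],
            [self.columns[i] for i in idx],
            self.truncated,
        )


@dataclass
class AbilityEstimate:
    """Fitted coefficients for one entity's regression.

    ``theta`` holds the interaction/regulation abilities in column order with
    the basal level last; entries under the miRNA mask are the *regression*
    coefficients (-gamma, -tau, -psi), hence <= 0.
    """

    target_id: str
    theta: np.ndarray
    sse: float
    columns: list[ColumnMeta]
    active_constraints: np.ndarray
    rank_deficient: bool = False

    @property
    def order(self) -> int:
        return len(self.theta) - 1

    @property
    def basal(self) -> float:
        return float(self.theta[-1])

    def coefficients(self) -> dict[str, float]:
        return {
            c.regulator: float(t)
            for c, t in zip(self.columns[:-1], self.theta[:-1])
        }


def _regulator_edges(
    target_id: str, network: GWGEN
) -> list[Edge]:
    """Candidate regulator edges of a target, in deterministic order."""
    kind = network.nodes[target_id].kind
    edges = []
    for e in network.edges_into(target_id):
        if kind is NodeKind.PROTEIN:
            if e.mode is EdgeMode.PPI:
                edges.append(e)
        elif e.mode is not EdgeMode.PPI:
            edges.append(e)
    return edges


def build_regression(
    target_id: str,
    network: GWGEN,
    expr: ExpressionMatrix,
    max_regulators: int | None = None,
) -> RegressionProblem:
    """Assemble the design matrix for one target entity.

    When the candidate regulator count would reach ``N - 1`` (the overfit
    regime), the candidates are pre-truncated to the ``N - 2`` regressors
    most absolutely correlated with the response, and the dropped ids are
    recorded on the problem.
    """
    if target_id not in expr:
        raise KeyError(f"target {target_id!r} not in expression matrix")
    y = expr.row(target_id)
    n = y.shape[0]
    edges = _regulator_edges(target_id, network)
    for e in edges:
        reg = e.other(target_id) if e.mode is EdgeMode.PPI else e.source
        if reg not in expr:
            raise KeyError(f"regulator {reg!r} not in expression matrix")

    cols: list[np.ndarray] = []
    metas: list[ColumnMeta] = []
    for e in edges:
        if e.mode is EdgeMode.PPI:
            reg = e.other(target_id)
            col = y * expr.row(reg)
        elif e.mode in MIRNA_MODES:
            reg = e.source
            col = expr.row(reg) * y
        else:
            reg = e.source
            col = expr.row(reg)
        cols.append(col)
        metas.append(ColumnMeta(reg, e.mode, e))

    truncated = None
    limit = n - 2 if max_regulators is None else min(max_regulators, n - 2)
    if len(cols) > limit:
        ss = np.std(y)
        corrs = []
        for col in cols:
            cs = np.std(col)
            if ss == 0 or cs == 0:
                corrs.append(0.0)
            else:
                corrs.append(abs(np.corrcoef(col, y)[0, 1]))
        keep = np.argsort(np.asarray(corrs))[::-1][:limit]
        keep = sorted(keep)
        truncated = [metas[i].regulator for i in range(len(cols)) if i not in set(keep)]
        logger.warning(
            "target %s: %d candidate regulators >= N-1=%d, truncating to the "
            "%d most response-correlated",
            target_id, len(cols), n - 1, limit,
        )
        cols = [cols[i] for i in keep]
        metas = [metas[i] for i in keep]

    cols.append(np.ones(n))
    metas.append(ColumnMeta(BASAL, None, None))
    design = np.column_stack(cols)
    if design.shape[1] > n:
        raise IdentifiabilityError(
            f"target {target_id!r}: {design.shape[1]} parameters for {n} samples"
        )
    return RegressionProblem(target_id, y, design, metas, truncated)


def fit_constrained(problem: RegressionProblem) -> AbilityEstimate:
    """Minimize 0.5*||Phi theta - y||^2 s.t. theta_j <= 0 on miRNA columns.

    Unconstrained columns are solved by ordinary least squares whenever no
    sign constraint exists or none is active; otherwise the box-constrained
    problem is solved by ``scipy.optimize.lsq_linear``.  A rank-deficient
    design yields the minimum-norm solution with a warning flag.
    """
    phi, y = problem.design, problem.response
    mask = problem.mirna_mask
    n, p = phi.shape
    rank = np.linalg.matrix_rank(phi) if p else 0
    rank_deficient = rank < p

    theta_ols, _, _, _ = np.linalg.lstsq(phi, y, rcond=None)
    if not mask.any() or (theta_ols[mask] <= 0).all():
        theta = theta_ols
        active = np.zeros(p, dtype=bool)
    else:
        ub = np.where(mask, 0.0, np.inf)
        lb = np.full(p, -np.inf)
        res = lsq_linear(phi, y, bounds=(lb, ub), tol=SOLVER_TOL, method="bvls"
                         if not rank_deficient else "trf")
        theta = res.x
        active = mask & np.isclose(theta, 0.0, atol=1e-10)
    resid = y - phi @ theta
    sse = float(resid @ resid)
    if rank_deficient:
        logger.warning(
            "target %s: rank-deficient design (rank %d < %d); minimum-norm "
            "solution returned", problem.target_id, rank, p,
        )
    return AbilityEstimate(
        problem.target_id, theta, sse, problem.columns, active, rank_deficient
    )


def identify_all(
    network: GWGEN, expr: ExpressionMatrix
) -> dict[str, AbilityEstimate]:
    """Fit the constrained regression of every target entity in the network."""
    out = {}
    targets = network.nodes_of_kind(
        NodeKind.PROTEIN, NodeKind.GENE, NodeKind.LNCRNA, NodeKind.MIRNA
    )
    for node in targets:
        problem = build_regression(node.id, network, expr)
        out[node.id] = fit_constrained(problem)
    return out
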