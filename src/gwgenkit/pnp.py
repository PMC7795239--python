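"""Principal network projection (PNP): core-network extraction by SVD.

The identified abilities of the real GWGEN are assembled into a network
matrix H whose rows are target entities (proteins, genes, lncRNAs, miRNAs)
and whose columns are regulators (proteins-in-ppi together with TFs, then
lncRNAs, then miRNAs).  H is decomposed by SVD; the leading singular
structure carrying at least 85% of the squared-singular-value energy is
retained, each node's row is projected onto those right singular vectors,
and nodes are scored by their summed squared projections.  The top-scoring
nodes induce the core GWGEN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GWGEN, EdgeMode, NodeKind

#: energy threshold of the retained singular structure
DEFAULT_ENERGY = 0.85
#: number of top-scoring nodes kept in the core network
DEFAULT_TOP_K = 3000

_ROW_KIND_ORDER = (NodeKind.PROTEIN, NodeKind.GENE, NodeKind.LNCRNA, NodeKind.MIRNA)


@dataclass
class NetworkMatrix:
    """The PNP ability matrix H with its row/column node index maps."""

    H: np.ndarray
    row_index: list[str]
    col_index: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape

    def row_of(self, node_id: str) -> np.ndarray:
        return self.H[self.row_index.index(node_id)]


@dataclass
class PNPResult:
    """SVD of H, singular-value energies, and node projection scores."""

    matrix: NetworkMatrix
    singular_values: np.ndarray
    left_vectors: np.ndarray   # S: rows x r
    right_vectors: np.ndarray  # D: cols x r
    energies: np.ndarray       # E_i = v_i^2 / sum v^2
    n_retained: int | None = None
    projections: np.ndarray | None = None  # Z: rows x I
    scores: dict[str, float] | None = None


def build_network_matrix(real: GWGEN) -> NetworkMatrix:
    """Assemble H from the real GWGEN's identified abilities.

    Rows: proteins, genes, lncRNAs, miRNAs (sorted within kind).  Columns:
    proteins participating in ppi together with TFs, then lncRNAs, then
    miRNAs that act as regulators.  An undirected ppi ability kappa appears
    at both (A-row, B-col) and (B-row, A-col); all other cells are zero.
    """
    if len(real) == 0:
        raise ValueError("real network has no edges")
    rows: list[str] = []
    for kind in _ROW_KIND_ORDER:
        rows.extend(n.id for n in real.nodes_of_kind(kind))

    ppi_proteins = set()
    tf_cols, lnc_cols, mir_cols = set(), set(), set()
    for e in real.iter_edges():
        if e.mode is EdgeMode.PPI:
            ppi_proteins.update((e.source, e.target))
        else:
            kind = real.nodes[e.source].kind
            if kind is NodeKind.TF:
                tf_cols.add(e.source)
            elif kind is NodeKind.LNCRNA:
                lnc_cols.add(e.source)
            elif kind is NodeKind.MIRNA:
                mir_cols.add(e.source)
    cols = sorted(ppi_proteins | tf_cols) + sorted(lnc_cols) + sorted(mir_cols)

    row_pos = {nid: i for i, nid in enumerate(rows)}
    col_pos = {nid: i for i, nid in enumerate(cols)}
    H = np.zeros((len(rows), len(cols)))
    for e in real.iter_edges():
        ability = 0.0 if e.ability is None else float(e.ability)
        if e.mode is EdgeMode.PPI:
            H[row_pos[e.source], col_pos[e.target]] = ability
            H[row_pos[e.target], col_pos[e.source]] = ability
        else:
            H[row_pos[e.target], col_pos[e.source]] = ability
    return NetworkMatrix(H, rows, cols)


def decompose(matrix: NetworkMatrix) -> PNPResult:
    """SVD of H with singular values in descending order.

    ``H = S diag(v) D^T`` reconstructs H to floating-point accuracy; the
    energies ``E_i = v_i^2 / sum(v^2)`` sum to one whenever H is nonzero.
    """
    H = matrix.H
    if H.shape[0] < 1 or H.shape[1] < 1:
        raise ValueError("H must have at least one row and column")
    S, v, Dt = np.linalg.svd(H, full_matrices=False)
    total = float(np.sum(v**2))
    energies = v**2 / total if total > 0 else np.zeros_like(v)
    return PNPResult(matrix, v, S, Dt.T, energies)


def energy_rank(pnp: PNPResult, threshold: float = DEFAULT_ENERGY) -> int:
    """Minimal I with cumulative energy >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if float(np.sum(pnp.singular_values**2)) == 0.0:
        raise ValueError("all-zero network matrix: energy rank undefined")
    cum = np.cumsum(pnp.energies)
    # tolerate rounding at exactly-attained thresholds (e.g. threshold 1.0)
    idx = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return min(idx, int(np.count_nonzero(pnp.singular_values > 0)))


def project_scores(pnp: PNPResult, n_retained: int) -> dict[str, float]:
    """Node scores S(a) = sum_b Z(a,b)^2 over the top retained vectors.

    Z(a, b) is the projection of the a-th row of H on the b-th right
    singular vector.  At full rank this equals the squared row norm.
    """
    if n_retained > pnp.right_vectors.shape[1]:
        raise ValueError("n_retained exceeds the number of singular vectors")
    D_top = pnp.right_vectors[:, :n_retained]
    Z = pnp.matrix.H @ D_top
    scores = (Z**2).sum(axis=1)
    pnp.n_retained = n_retained
    pnp.projections = Z
    pnp.scores = dict(zip(pnp.matrix.row_index, map(float, scores)))
    return pnp.scores


def extract_core(
    real: GWGEN, scores: dict[str, float], top_k: int = DEFAULT_TOP_K
) -> GWGEN:
    """Induce the core GWGEN on the ``top_k`` highest-scoring nodes.

    Projection scores cover the row-nodes of H; regulator nodes that only
    appear as columns (e.g. TFs with no incoming edges) rank with score 0,
    so a large enough ``top_k`` reproduces the full network.  Score ties at
    the boundary break by lexicographic node id, making the result
    deterministic.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    full = {nid: scores.get(nid, 0.0) for nid in real.nodes}
    ranked = sorted(full.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = {nid for nid, _ in ranked[:top_k]}
    return real.induced_subnetwork(keep)


def run_pnp(
    real: GWGEN,
    threshold: float = DEFAULT_ENERGY,
    top_k: int = DEFAULT_TOP_K,
) -> tuple[PNPResult, GWGEN]:
    """Full PNP pipeline: matrix, SVD, energy rank, scores, core network."""
    pnp = decompose(build_network_matrix(real))
    n_retained = energy_rank(pnp, threshold)
    scores = project_scores(pnp, n_retained)
    core = extract_core(real, scores, top_k)
    return pnp, core
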