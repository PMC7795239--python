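"""Synthetic data with planted ground truth for every pipeline stage.

Candidate networks are generated with a planted true subnetwork plus
spurious edges; expression is generated so that it satisfies the
interactive/regulatory model equations *exactly* (the regression residual of
the true model equals the injected Gaussian noise), which makes noiseless
parameter recovery an exact oracle for the identification stage.  A DTI
feature generator plants a linearly separable binding rule, and a bundled
drug-screening fixture carries the published tables for nine T2D candidate
compounds.

Generation scheme
-----------------
TF expressions and "driver" protein expressions are exogenous i.i.d.
positive draws.  Every other entity is a target whose value is obtained in
closed form from its model equation: the equations are linear in the
target's own expression, so e.g. a gene with TF/lncRNA/miRNA regulators is

    g = (sum(alpha*t) + sum(beta*l) + lambda + eps) / (1 + sum(gamma*m))

which satisfies  g = sum(alpha*t) + sum(beta*l) - sum(gamma*m*g) + lambda
+ eps  identically.  lncRNA<->miRNA cross-regulation is kept acyclic by an
interleaved generation order; responsive proteins interact only with driver
proteins so the bilinear protein equations also solve in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drugspec import DrugSpecTables
from .expression import CONTROL, DISEASE, ExpressionMatrix
from .network import GWGEN, Edge, EdgeMode, MIRNA_MODES, Node, NodeKind

logger = logging.getLogger(__name__)

#: exogenous regulator draws: |Normal(1, 0.5^2)|, positive and unit-scale
REGULATOR_MEAN = 1.0
REGULATOR_SD = 0.5
#: driver-protein expression cap, so the protein closed form stays well-posed
DRIVER_CAP = 3.0
#: bound on sum(|kappa| * partner expression) for responsive proteins
PPI_STABILITY = 0.8

#: baseline basal level of lncRNA/miRNA targets: unit scale, so their
#: transcriptional drive dominates and they vary like real regulators do
BASAL_BASE = (0.5, 1.5)
#: basal range of genes and proteins: both are pure sinks in the generated
#: topology, and substantial basal expression keeps the additive data noise
#: a small fraction of their value even under strong miRNA repression
GENE_BASAL = (3.0, 6.0)
PROTEIN_BASAL = (3.0, 6.0)
#: minimum magnitude of the guaranteed TF->lncRNA/miRNA drive; a regulator
#: whose expression barely varies makes its product regressors degenerate
DRIVE_MIN = 1.0
#: high quantile of an exogenous regulator draw (|N(1, 0.5^2)| ~ q97.5);
#: basal levels carry a margin covering the worst case of the *negative*
#: linear regulation only, so simulated expression rarely goes negative
#: while positively regulated targets keep their full dynamic range
REGULATOR_HI = 2.2

DEFAULT_NOISE_SD = 0.1


@dataclass
class GroundTruth:
    """The planted partition of a candidate network.

    ``abilities`` stores the model-convention ability per true edge: for
    miRNA-regulation edges this is gamma/tau/psi >= 0 (which enters the
    regression with a negative sign); everything else is the signed ability
    itself.  ``basal`` is the lambda of every modeled target.
    """

    true_edges: set[tuple[str, str, str]]
    abilities: dict[tuple[str, str, str], float]
    basal: dict[str, float]
    noise_sd: float
    driver_proteins: set[str] = field(default_factory=set)
    generation_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for key, value in self.abilities.items():
            if key[2] in {m.value for m in MIRNA_MODES} and value < 0:
                raise ValueError(f"miRNA ability must be >= 0: {key}")

    def regression_coefficient(self, edge_key: tuple[str, str, str]) -> float:
        """Planted coefficient in regression convention (miRNA entries <= 0)."""
        value = self.abilities[edge_key]
        if edge_key[2] in {m.value for m in MIRNA_MODES}:
            return -value
        return value


def _interleave(lnc: list[str], mir: list[str]) -> list[str]:
    """Alternate lncRNA and miRNA ids so cross-class regulation is acyclic."""
    order: list[str] = []
    for i in range(max(len(lnc), len(mir))):
        if i < len(lnc):
            order.append(lnc[i])
        if i < len(mir):
            order.append(mir[i])
    return order


def generate_candidate_gwgen(
    n_protein: int = 10,
    n_gene: int = 20,
    n_lncRNA: int = 5,
    n_miRNA: int = 5,
    density: float = 0.1,
    spurious_fraction: float = 0.5,
    seed: int = 0,
    n_tf: int | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    ability_low: float = -2.0,
    ability_high: float = 2.0,
    ability_min: float = 0.3,
) -> tuple[GWGEN, GroundTruth]:
    """Generate a candidate GWGEN containing a planted true subnetwork.

    Each admissible regulator-target pair becomes a candidate edge with
    probability ``density``; a candidate edge is spurious (present in the
    candidate network, absent from the truth) with probability
    ``spurious_fraction``.  Abilities of true edges are uniform in
    [ability_low, ability_high] except miRNA-regulation abilities, drawn in
    [0, ability_high]; a drawn magnitude below ``ability_min`` is pushed up
    to it (an edge whose ability is ~0 is indistinguishable from no edge).
    Protein-interaction abilities are rescaled where needed to keep the
    bilinear protein equations well-posed.
    """
    if min(n_protein, n_gene, n_lncRNA, n_miRNA) < 1:
        raise ValueError("entity counts must be >= 1")
    if not (0 < density < 1):
        raise ValueError("density must be in (0, 1)")
    if not (0 <= spurious_fraction < 1):
        raise ValueError("spurious_fraction must be in [0, 1)")
    if n_tf is None:
        n_tf = max(2, n_gene // 4)
    rng = np.random.default_rng(seed)

    width = 3
    proteins = [f"P{i + 1:0{width}d}" for i in range(n_protein)]
    genes = [f"G{i + 1:0{width}d}" for i in range(n_gene)]
    tfs = [f"TF{i + 1:0{width}d}" for i in range(n_tf)]
    lncs = [f"L{i + 1:0{width}d}" for i in range(n_lncRNA)]
    mirs = [f"M{i + 1:0{width}d}" for i in range(n_miRNA)]

    n_driver = max(1, n_protein // 3)
    drivers, responsive = proteins[:n_driver], proteins[n_driver:]

    nodes = (
        [Node(p, NodeKind.PROTEIN) for p in proteins]
        + [Node(g, NodeKind.GENE) for g in genes]
        + [Node(t, NodeKind.TF) for t in tfs]
        + [Node(l, NodeKind.LNCRNA) for l in lncs]
        + [Node(m, NodeKind.MIRNA) for m in mirs]
    )
    order = _interleave(lncs, mirs)
    rank = {nid: i for i, nid in enumerate(order)}

    def draw_ability(mode: EdgeMode) -> float:
        if mode in MIRNA_MODES:
            value = float(rng.uniform(0.0, ability_high))
            return max(value, ability_min)
        value = float(rng.uniform(ability_low, ability_high))
        if abs(value) < ability_min:
            value = ability_min if value >= 0 else -ability_min
        return value

    edges: list[Edge] = []
    true_edges: set[tuple[str, str, str]] = set()
    abilities: dict[tuple[str, str, str], float] = {}

    def consider(source: str, target: str, mode: EdgeMode) -> None:
        if rng.random() >= density:
            return
        edge = Edge(source, target, mode)
        edges.append(edge)
        if rng.random() >= spurious_fraction:
            true_edges.add(edge.key)
            abilities[edge.key] = draw_ability(mode)

    # ppi: responsive x driver (bipartite keeps the protein system closed-form)
    for q in responsive:
        for r in drivers:
            consider(q, r, EdgeMode.PPI)
    # gene targets <- TFs, lncRNAs, miRNAs
    for g in genes:
        for t in tfs:
            consider(t, g, EdgeMode.TF_GENE)
        for l in lncs:
            consider(l, g, EdgeMode.LNCRNA_GENE)
        for m in mirs:
            consider(m, g, EdgeMode.MIRNA_GENE)
    # lncRNA / miRNA targets <- TFs and lower-rank lncRNAs/miRNAs; every
    # lncRNA/miRNA gets at least one true TF regulator so that, as a
    # regulator itself, its expression varies even in the noiseless limit
    for target in order:
        tgt_kind = NodeKind.LNCRNA if target in set(lncs) else NodeKind.MIRNA
        tf_mode = (
            EdgeMode.TF_LNCRNA
            if tgt_kind is NodeKind.LNCRNA
            else EdgeMode.TF_MIRNA
        )
        for t in tfs:
            consider(t, target, tf_mode)
        if not any(
            k in true_edges
            for k in ((t, target, tf_mode.value) for t in tfs)
        ):
            t = tfs[int(rng.integers(len(tfs)))]
            key = (t, target, tf_mode.value)
            if key not in {e.key for e in edges}:
                edges.append(Edge(t, target, tf_mode))
            true_edges.add(key)
            magnitude = float(rng.uniform(max(DRIVE_MIN, ability_min), ability_high))
            negative = ability_low < 0 and rng.random() < 0.5
            abilities[key] = -magnitude if negative else magnitude
        for source in order:
            if rank[source] >= rank[target]:
                continue
            src_is_lnc = source.startswith("L")
            if tgt_kind is NodeKind.LNCRNA:
                mode = (
                    EdgeMode.LNCRNA_LNCRNA if src_is_lnc else EdgeMode.MIRNA_LNCRNA
                )
            else:
                mode = (
                    EdgeMode.LNCRNA_MIRNA if src_is_lnc else EdgeMode.MIRNA_MIRNA
                )
            consider(source, target, mode)

    # rescale each responsive protein's interaction abilities so the
    # closed-form denominator 1 - sum(kappa * p_driver) stays positive
    for q in responsive:
        keys = [
            k for k in true_edges
            if k[2] == EdgeMode.PPI.value and q in (k[0], k[1])
        ]
        total = sum(abs(abilities[k]) for k in keys) * DRIVER_CAP
        if total > PPI_STABILITY:
            scale = PPI_STABILITY / total
            for k in keys:
                abilities[k] *= scale

    # basal levels: a unit-scale baseline plus a margin covering the
    # target's worst-case signed linear regulation, so simulated expression
    # rarely goes negative; miRNA terms only shrink values toward zero and
    # need no margin.  ``hi`` tracks a high quantile of each entity's value.
    linear_modes = {
        EdgeMode.TF_GENE.value, EdgeMode.TF_LNCRNA.value,
        EdgeMode.TF_MIRNA.value, EdgeMode.LNCRNA_GENE.value,
        EdgeMode.LNCRNA_LNCRNA.value, EdgeMode.LNCRNA_MIRNA.value,
    }
    hi: dict[str, float] = {t: REGULATOR_HI for t in tfs}
    hi.update({p: min(REGULATOR_HI, DRIVER_CAP) for p in drivers})
    basal: dict[str, float] = {}

    def assign_basal(target: str, base: tuple[float, float]) -> None:
        margin = sum(
            abs(abilities[k]) * hi[k[0]]
            for k in true_edges
            if k[1] == target and k[2] in linear_modes and abilities[k] < 0
        )
        positive = sum(
            abilities[k] * hi[k[0]]
            for k in true_edges
            if k[1] == target and k[2] in linear_modes and abilities[k] > 0
        )
        basal[target] = float(rng.uniform(*base)) + margin
        hi[target] = basal[target] + positive

    for p in responsive:
        basal[p] = float(rng.uniform(*PROTEIN_BASAL))
        hi[p] = basal[p] / (1.0 - PPI_STABILITY)
    for nid in order:
        assign_basal(nid, BASAL_BASE)
    for g in genes:
        assign_basal(g, GENE_BASAL)

    network = GWGEN.build(nodes, edges)
    truth = GroundTruth(
        true_edges=true_edges,
        abilities=abilities,
        basal=basal,
        noise_sd=noise_sd,
        driver_proteins=set(drivers),
        generation_order=order,
    )
    return network, truth


def simulate_expression(
    truth: GroundTruth,
    network: GWGEN,
    n_samples: int,
    seed: int = 0,
) -> ExpressionMatrix:
    """Generate expression satisfying the planted model equations exactly.

    TFs and driver proteins are exogenous i.i.d. positive draws; every other
    entity's value comes from its (closed-form solved) model equation with
    i.i.d. Normal(0, noise_sd^2) noise.  Simulated values that land negative
    are clipped to zero and counted in the log.
    """
    max_indeg = max(
        (len(network.edges_into(n.id)) for n in network.nodes.values()),
        default=0,
    )
    if n_samples <= max_indeg + 1:
        raise ValueError(
            f"n_samples={n_samples} must exceed max candidate in-degree + 1 "
            f"= {max_indeg + 1} (identifiability)"
        )
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}

    def exogenous() -> np.ndarray:
        return np.abs(rng.normal(REGULATOR_MEAN, REGULATOR_SD, n_samples))

    tfs = [n.id for n in network.nodes_of_kind(NodeKind.TF)]
    proteins = [n.id for n in network.nodes_of_kind(NodeKind.PROTEIN)]
    genes = [n.id for n in network.nodes_of_kind(NodeKind.GENE)]

    for t in tfs:
        values[t] = exogenous()
    for p in proteins:
        if p in truth.driver_proteins:
            values[p] = np.minimum(exogenous(), DRIVER_CAP)

    clipped = 0

    def emit(target: str, linear: np.ndarray, repress: np.ndarray) -> None:
        nonlocal clipped
        eps = rng.normal(0.0, truth.noise_sd, n_samples) if truth.noise_sd else 0.0
        raw = (linear + truth.basal[target] + eps) / repress
        neg = raw < 0
        clipped += int(np.count_nonzero(neg))
        values[target] = np.where(neg, 0.0, raw)

    def true_regulations(target: str) -> list[tuple[str, str, float]]:
        """(regulator, mode, ability) for the target's *true* incoming edges."""
        out = []
        for e in network.edges_into(target):
            if e.key not in truth.true_edges:
                continue
            reg = e.other(target) if e.mode is EdgeMode.PPI else e.source
            out.append((reg, e.mode.value, truth.abilities[e.key]))
        return out

    # responsive proteins: p = (lambda + eps) / (1 - sum kappa * p_driver)
    for p in proteins:
        if p in truth.driver_proteins:
            continue
        denom = np.ones(n_samples)
        for reg, _, kappa in true_regulations(p):
            denom = denom - kappa * values[reg]
        emit(p, np.zeros(n_samples), denom)

    # lncRNAs and miRNAs in interleaved (acyclic) generation order
    for target in truth.generation_order:
        if target not in network.nodes:
            continue
        linear = np.zeros(n_samples)
        denom = np.ones(n_samples)
        for reg, mode, ability in true_regulations(target):
            if mode in {m.value for m in MIRNA_MODES}:
                denom = denom + ability * values[reg]
            else:
                linear = linear + ability * values[reg]
        emit(target, linear, denom)

    # genes last: their regulators (TFs, lncRNAs, miRNAs) are all emitted
    for g in genes:
        linear = np.zeros(n_samples)
        denom = np.ones(n_samples)
        for reg, mode, ability in true_regulations(g):
            if mode == EdgeMode.MIRNA_GENE.value:
                denom = denom + ability * values[reg]
            else:
                linear = linear + ability * values[reg]
        emit(g, linear, denom)

    if clipped:
        logger.warning("clipped %d negative simulated values to 0", clipped)

    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    frame = pd.DataFrame(
        {s: {nid: values[nid][i] for nid in values} for i, s in enumerate(samples)}
    )
    frame = frame.loc[sorted(frame.index)]
    half = n_samples // 2
    group = pd.Series(
        [CONTROL] * half + [DISEASE] * (n_samples - half), index=samples
    )
    return ExpressionMatrix(frame, group)


def simulate_study(
    n_samples_control: int,
    n_samples_disease: int,
    seed: int = 0,
    **network_kwargs,
) -> tuple[GWGEN, GroundTruth, GroundTruth, ExpressionMatrix]:
    """Two-group study: one candidate network, group-specific truths.

    The disease truth perturbs the control truth by removing a fraction of
    true edges and redrawing the abilities of another fraction, emulating
    rewiring between condition-specific networks.
    """
    rng = np.random.default_rng(seed)
    network, truth_control = generate_candidate_gwgen(
        seed=int(rng.integers(2**31)), **network_kwargs
    )
    # perturb: drop 30% of true edges, redraw 30% of the remaining abilities
    keys = sorted(truth_control.true_edges)
    n_drop = int(0.3 * len(keys))
    drop = set(
        tuple(keys[i]) for i in rng.choice(len(keys), n_drop, replace=False)
    )
    abilities = {
        k: v for k, v in truth_control.abilities.items() if k not in drop
    }
    for k in list(abilities):
        if rng.random() < 0.3:
            if k[2] in {m.value for m in MIRNA_MODES}:
                abilities[k] = float(rng.uniform(0.0, 2.0))
            else:
                abilities[k] = float(rng.uniform(-2.0, 2.0))
    truth_disease = GroundTruth(
        true_edges=set(abilities),
        abilities=abilities,
        basal=dict(truth_control.basal),
        noise_sd=truth_control.noise_sd,
        driver_proteins=set(truth_control.driver_proteins),
        generation_order=list(truth_control.generation_order),
    )
    expr_control = simulate_expression(
        truth_control, network, n_samples_control, seed=int(rng.integers(2**31))
    )
    expr_disease = simulate_expression(
        truth_disease, network, n_samples_disease, seed=int(rng.integers(2**31))
    )
    merged = pd.concat(
        [expr_control.values, expr_disease.values], axis=1
    )
    merged.columns = [f"C{i + 1:04d}" for i in range(n_samples_control)] + [
        f"D{i + 1:04d}" for i in range(n_samples_disease)
    ]
    group = pd.Series(
        [CONTROL] * n_samples_control + [DISEASE] * n_samples_disease,
        index=merged.columns,
    )
    expr = ExpressionMatrix(merged, group)
    return network, truth_control, truth_disease, expr


@dataclass
class DTIDatasetSpec:
    """Parameters of the synthetic drug-target interaction dataset."""

    n_drugs: int = 100
    n_targets: int = 100
    drug_dim: int = 363
    target_dim: int = 996
    n_pairs: int = 5000
    label_noise: float = 0.0
    negative_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.drug_dim, self.target_dim) < 1:
            raise ValueError("feature dimensions must be >= 1")
        if self.negative_ratio <= 0:
            raise ValueError("negative:positive ratio must be > 0")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label flip probability must be in [0, 0.5)")


@dataclass
class DTIDataset:
    """Labeled drug-target pairs with concatenated [drug, target] features."""

    features: np.ndarray  # n_pairs x (drug_dim + target_dim)
    labels: np.ndarray    # binary
    pairs: list[tuple[int, int]]
    drug_dim: int
    target_dim: int


def generate_dti_dataset(spec: DTIDatasetSpec) -> DTIDataset:
    """Plant a linear binding rule in concatenated descriptor space.

    A latent weight vector scores each candidate pair by its concatenated
    features; positives are the highest-scoring pairs and negatives the
    lowest-scoring ones at the requested negative:positive ratio, with the
    ambiguous mid-score band excluded — mirroring how binding databases are
    turned into benchmarks (confident binders vs confident non-binders).
    The clean labels are therefore linearly separable with a margin;
    ``label_noise`` then flips labels i.i.d.
    """
    universe = spec.n_drugs * spec.n_targets
    if spec.n_pairs > universe:
        raise ValueError(
            f"requested {spec.n_pairs} pairs but only {universe} exist"
        )
    rng = np.random.default_rng(spec.seed)
    drugs = rng.normal(size=(spec.n_drugs, spec.drug_dim))
    targets = rng.normal(size=(spec.n_targets, spec.target_dim))
    n_candidates = min(2 * spec.n_pairs, universe)
    flat = rng.choice(universe, size=n_candidates, replace=False)
    pairs = [(int(i // spec.n_targets), int(i % spec.n_targets)) for i in flat]
    X = np.hstack(
        [
            drugs[[i for i, _ in pairs]],
            targets[[j for _, j in pairs]],
        ]
    )
    w = rng.normal(size=X.shape[1]) / np.sqrt(X.shape[1])
    scores = X @ w
    n_pos = int(round(spec.n_pairs / (1.0 + spec.negative_ratio)))
    n_neg = spec.n_pairs - n_pos
    ranked = np.argsort(scores)
    chosen = np.concatenate([ranked[:n_neg], ranked[-n_pos:]])
    labels = np.concatenate(
        [np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)]
    )
    perm = rng.permutation(spec.n_pairs)
    chosen, labels = chosen[perm], labels[perm]
    X = X[chosen]
    pairs = [pairs[i] for i in chosen]
    if spec.label_noise > 0:
        flips = rng.random(spec.n_pairs) < spec.label_noise
        labels = np.where(flips, 1 - labels, labels)
    return DTIDataset(X, labels, pairs, spec.drug_dim, spec.target_dim)


# --- bundled drug-screening fixture ---------------------------------------

_BIOMARKERS = ("IKK", "STAT3", "PPARg", "ETS1", "FAS")

#: published screening panel for nine T2D candidate compounds: biomarker
#: bindings, count of additional core-network bindings (side effect),
#: per-biomarker regulation abilities, LD50 (mol/kg) and EC50
_T2D_PANEL: dict[str, dict] = {
    "Anisomycin": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1", "FAS"),
        "side_effect": 37,
        "regulation": (0.822, 0.809, 3.622, 5.507, -0.184),
        "ld50": 3.535,
        "ec50": -1.099,
    },
    "Sulforaphane": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1", "FAS"),
        "side_effect": 23,
        "regulation": (-0.029, 0.079, 0.075, 0.089, -0.059),
        "ld50": 3.110,
        "ec50": -0.008,
    },
    "Memantine": {
        "binds": ("IKK", "STAT3"),
        "side_effect": 11,
        "regulation": (-0.997, 0.707, None, None, None),
        "ld50": 2.346,
        "ec50": -0.383,
    },
    "Trimetozine": {
        "binds": ("IKK", "STAT3", "PPARg"),
        "side_effect": 14,
        "regulation": (-0.724, 0.650, 0.489, None, None),
        "ld50": 2.148,
        "ec50": -0.851,
    },
    "Biotin": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1"),
        "side_effect": 19,
        "regulation": (-1.214, 1.075, 0.969, -0.986, None),
        "ld50": 2.058,
        "ec50": -0.249,
    },
    "Gabexate": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1"),
        "side_effect": 31,
        "regulation": (-1.324, -0.942, 1.237, -2.151, None),
        "ld50": 1.999,
        "ec50": -0.229,
    },
    "Famotidine": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1"),
        "side_effect": 25,
        "regulation": (-0.693, 0.356, -1.004, -0.119, None),
        "ld50": 1.952,
        "ec50": -0.548,
    },
    "Cilostazol": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1"),
        "side_effect": 26,
        "regulation": (-0.570, -1.622, 0.387, -1.222, None),
        "ld50": 1.889,
        "ec50": -0.141,
    },
    "Acetylcysteine": {
        "binds": ("IKK", "STAT3", "PPARg", "ETS1", "FAS"),
        "side_effect": 41,
        "regulation": (-0.788, 0.645, -0.620, 1.923, -1.000),
        "ld50": 1.294,
        "ec50": -0.554,
    },
}


def t2d_candidate_drug_tables() -> DrugSpecTables:
    """The published nine-compound T2D screening panel.

    Binding targets beyond the five biomarkers are anonymous in the
    published panel, so they are represented here by synthetic placeholder
    target ids (one per counted extra binding); the biomarker bindings,
    side-effect counts, regulation abilities, LD50 and EC50 values are the
    published ones.
    """
    regulation: dict[tuple[str, str], float] = {}
    toxicity: dict[str, float] = {}
    sensitivity: dict[str, float] = {}
    bindings: dict[str, set[str]] = {}
    for drug, info in _T2D_PANEL.items():
        binds = set(info["binds"])
        extras = {
            f"{drug}_offtarget_{k + 1:02d}" for k in range(info["side_effect"])
        }
        bindings[drug] = binds | extras
        toxicity[drug] = info["ld50"]
        sensitivity[drug] = info["ec50"]
        for biomarker, value in zip(_BIOMARKERS, info["regulation"]):
            if value is not None:
                regulation[(drug, biomarker)] = value
    return DrugSpecTables(regulation, toxicity, sensitivity, bindings)


def t2d_desired_regulation():
    """Reverse the pathogenic biomarker expression: IKK/ETS1/FAS down,
    STAT3/PPARg up."""
    from .drugspec import DesiredRegulation

    return DesiredRegulation.from_dict(
        {"IKK": "down", "STAT3": "up", "PPARg": "up", "ETS1": "down", "FAS": "down"}
    )
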