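"""Readers and writers for the package's text formats.

Networks travel as tab-separated edge lists (``source  target  mode
[ability]``), expression as a TSV matrix plus a sample->group TSV, gene sets
as standard GMT, drug screening tables as TSV, and results as JSON.  Reading
then writing any supported file is idempotent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionError, ExpressionMatrix, GeneSetCollection
from .network import GWGEN, Edge, EdgeMode, NetworkError, Node, NodeKind

logger = logging.getLogger(__name__)

#: node kind implied by each end of each edge mode, used to infer kinds when
#: reading a bare edge table
_KIND_BY_MODE = {
    EdgeMode.PPI: (NodeKind.PROTEIN, NodeKind.PROTEIN),
    EdgeMode.TF_GENE: (NodeKind.TF, NodeKind.GENE),
    EdgeMode.TF_LNCRNA: (NodeKind.TF, NodeKind.LNCRNA),
    EdgeMode.TF_MIRNA: (NodeKind.TF, NodeKind.MIRNA),
    EdgeMode.LNCRNA_GENE: (NodeKind.LNCRNA, NodeKind.GENE),
    EdgeMode.LNCRNA_LNCRNA: (NodeKind.LNCRNA, NodeKind.LNCRNA),
    EdgeMode.LNCRNA_MIRNA: (NodeKind.LNCRNA, NodeKind.MIRNA),
    EdgeMode.MIRNA_GENE: (NodeKind.MIRNA, NodeKind.GENE),
    EdgeMode.MIRNA_LNCRNA: (NodeKind.MIRNA, NodeKind.LNCRNA),
    EdgeMode.MIRNA_MIRNA: (NodeKind.MIRNA, NodeKind.MIRNA),
}


def read_edge_table(path: str | Path) -> GWGEN:
    """Read a GWGEN from a TSV edge list.

    Columns ``source``, ``target``, ``mode`` are required; an optional
    ``ability`` column carries identified abilities.  Node kinds are inferred
    from edge modes; an id used inconsistently across modes is an error.
    ``ppi`` rows are canonicalized (``source < target``) and duplicate edges
    collapse to one.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise NetworkError(f"{path}: edge table is empty")
    required = {"source", "target", "mode"}
    if not required.issubset(df.columns):
        raise NetworkError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    net = GWGEN()
    for _, row in df.iterrows():
        try:
            mode = EdgeMode(row["mode"])
        except ValueError:
            raise NetworkError(f"{path}: unknown mode {row['mode']!r}") from None
        src_kind, tgt_kind = _KIND_BY_MODE[mode]
        net.add_node(Node(str(row["source"]), src_kind))
        net.add_node(Node(str(row["target"]), tgt_kind))
        ability = None
        if "ability" in df.columns and pd.notna(row["ability"]) and row["ability"] != "":
            ability = float(row["ability"])
        net.add_edge(Edge(str(row["source"]), str(row["target"]), mode, ability))
    return net


def write_edge_table(net: GWGEN, path: str | Path) -> None:
    """Write a GWGEN as a TSV edge list (sorted, hence byte-stable)."""
    rows = []
    has_ability = any(e.ability is not None for e in net.iter_edges())
    for e in sorted(net.iter_edges(), key=lambda e: e.key):
        row = {"source": e.source, "target": e.target, "mode": e.mode.value}
        if has_ability:
            row["ability"] = "" if e.ability is None else repr(float(e.ability))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_table(
    path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Read an entity x sample expression TSV and a sample->group TSV.

    The groups file has columns ``sample`` and ``group`` (control/disease).
    Every matrix sample must be labeled; extra labeled samples are an error
    too, so the two files cannot silently drift apart.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(groups.columns):
        raise ExpressionError(f"{groups_path}: need columns sample, group")
    group = groups.set_index("sample")["group"]
    matrix_samples = set(map(str, values.columns))
    labeled = set(group.index)
    if matrix_samples != labeled:
        raise ExpressionError(
            f"sample mismatch between {path} and {groups_path}: "
            f"matrix-only={sorted(matrix_samples - labeled)}, "
            f"groups-only={sorted(labeled - matrix_samples)}"
        )
    values.columns = values.columns.map(str)
    return ExpressionMatrix(values, group)


def write_expression_table(
    expr: ExpressionMatrix, path: str | Path, groups_path: str | Path
) -> None:
    # %.17g round-trips IEEE doubles exactly
    expr.values.to_csv(path, sep="\t", float_format="%.17g")
    pd.DataFrame(
        {"sample": expr.group.index, "group": expr.group.values}
    ).to_csv(groups_path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, members (tab-separated)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ExpressionError(
                    f"{path}:{lineno}: GMT line has fewer than 3 fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            coll.add(name, members, desc)
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.names():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *coll[name]]) + "\n")


def align_network_to_expression(
    net: GWGEN, expr: ExpressionMatrix
) -> GWGEN:
    """Drop network nodes absent from the expression matrix, with a warning.

    Coverage gaps between a mined network and a measured dataset are routine;
    erroring out would make every real dataset unusable.
    """
    missing = [nid for nid in net.nodes if nid not in expr]
    if not missing:
        return net
    logger.warning(
        "dropping %d network node(s) absent from expression data: %s",
        len(missing),
        ", ".join(sorted(missing)[:10]) + ("..." if len(missing) > 10 else ""),
    )
    return net.induced_subnetwork(set(net.nodes) - set(missing))


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
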