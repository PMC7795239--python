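"""End-to-end pipeline: identify -> prune -> project -> compare (-> drugs).

Each stage logs its seed and timing; any stage error aborts the run with a
stage-labeled message.  Results are written as JSON/TSV under the
configured output directory.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from .compare import compare_cores, enrich
from .config import RunConfig
from .drugspec import DesiredRegulation, read_drug_tables, select_combination
from .io import (
    read_edge_table,
    read_expression_table,
    read_gene_sets,
    write_edge_table,
    write_json,
)
from .model import NetworkSystemModel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - start)
            return result
        return inner
    return wrap


@_stage("identify")
def _identify(edge_path, expr, group):
    network = read_edge_table(edge_path)
    model = NetworkSystemModel(network, expr.subset(group))
    return model.fit()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the result bundle.

    Returns a summary dictionary (also written as ``run.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed: %d", config.seed)
    if not (config.expression and config.groups):
        raise StageError("stage 'identify' failed: expression/groups paths missing")
    try:
        expr = read_expression_table(config.expression, config.groups)
    except Exception as exc:
        raise StageError(f"stage 'identify' failed: {exc}") from exc

    summary: dict = {"seed": config.seed}
    cores = {}
    for group, edge_path in (
        ("disease", config.edges_disease),
        ("control", config.edges_control),
    ):
        if edge_path is None:
            continue
        results = _identify(edge_path, expr, group)
        write_edge_table(results.real_network, out_dir / f"real_{group}.tsv")
        pnp, core = results.pnp(config.energy_threshold, config.top_k)
        write_edge_table(core, out_dir / f"core_{group}.tsv")
        write_json(
            dict(sorted(pnp.scores.items())), out_dir / f"scores_{group}.json"
        )
        cores[group] = core
        summary[group] = {
            "candidate_edges": len(results.model.network),
            "real_edges": len(results.real_network),
            "core_nodes": len(core.nodes),
            "retained_singular_vectors": pnp.n_retained,
        }

    if len(cores) == 2:
        comparison = compare_cores(
            cores["disease"], cores["control"], expr, config.min_abs_log2fc
        )
        payload = {
            "common_edges": sorted(comparison.common_edges),
            "disease_only_edges": sorted(comparison.disease_only_edges),
            "control_only_edges": sorted(comparison.control_only_edges),
            "direction": comparison.direction,
        }
        write_json(payload, out_dir / "comparison.json")
        summary["comparison"] = {
            "common_edges": len(comparison.common_edges),
            "disease_only_edges": len(comparison.disease_only_edges),
            "control_only_edges": len(comparison.control_only_edges),
        }
        if config.gene_sets:
            sets = read_gene_sets(config.gene_sets)
            universe = set(cores["disease"].nodes) | set(cores["control"].nodes)
            nodes = set(cores["disease"].nodes) - set(cores["control"].nodes)
            table = enrich(nodes, sets, universe)
            table.to_csv(out_dir / "enrichment.tsv", sep="\t")
            summary["enrichment_sets"] = len(table)

    if config.drug_tables_dir:
        desired = DesiredRegulation.from_dict(config.desired_regulation)
        diagnostics: list[dict] = []
        try:
            tables = read_drug_tables(config.drug_tables_dir)
            combo = select_combination(
                tables, desired, config.max_combination_size, diagnostics
            )
        except Exception as exc:
            raise StageError(f"stage 'drug-select' failed: {exc}") from exc
        write_json(
            {
                "drugs": list(combo.drugs),
                "aggregate_regulation": combo.aggregate_regulation,
                "total_side_effect": combo.total_side_effect,
                "ld50": combo.ld50,
                "ec50": combo.ec50,
                "evaluated_subsets": diagnostics,
            },
            out_dir / "combination.json",
        )
        summary["combination"] = list(combo.drugs)

    write_json(summary, out_dir / "run.json")
    return summary
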