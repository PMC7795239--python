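"""Drug design specifications and multiple-molecule combination selection.

Candidate drugs (predicted to bind biomarkers in the core network) are
screened on four specifications: regulation ability (signed L1000-style
perturbation response; positive = upregulation), toxicity (LD50 in mol/kg,
larger = less toxic), sensitivity (EC50, smaller = more potent) and side
effect (the number of core-network binding targets other than the desired
biomarkers).  A multiple-molecule targeting drug is a drug subset whose
member-summed regulation drives every biomarker in its desired direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"

DESIRED = "desired"
UNWANTED = "unwanted"
ABSENT = "absent"


@dataclass
class DrugSpecTables:
    """Screening tables for a panel of candidate drugs.

    ``regulation`` maps (drug, gene) -> signed regulation ability;
    ``bindings`` maps drug -> set of bound targets in the core network;
    ``toxicity`` maps drug -> LD50; ``sensitivity`` maps drug -> EC50.
    """

    regulation: dict[tuple[str, str], float] = field(default_factory=dict)
    toxicity: dict[str, float] = field(default_factory=dict)
    sensitivity: dict[str, float] = field(default_factory=dict)
    bindings: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug in self.bindings:
            if drug not in self.toxicity:
                raise ValueError(f"drug {drug!r} has no LD50 entry")
            if drug not in self.sensitivity:
                raise ValueError(f"drug {drug!r} has no EC50 entry")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.bindings)

    def regulation_of(self, drug: str, gene: str) -> float | None:
        return self.regulation.get((drug, gene))


@dataclass(frozen=True)
class DesiredRegulation:
    """Desired direction (up/down) per biomarker."""

    directions: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError("desired regulation must be nonempty")
        names = [b for b, _ in self.directions]
        if len(set(names)) != len(names):
            raise ValueError("each biomarker may appear only once")
        for _, d in self.directions:
            if d not in (UP, DOWN):
                raise ValueError(f"direction must be 'up' or 'down', got {d!r}")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "DesiredRegulation":
        return cls(tuple(d.items()))

    @property
    def biomarkers(self) -> list[str]:
        return [b for b, _ in self.directions]

    def direction(self, biomarker: str) -> str:
        return dict(self.directions)[biomarker]

    def flipped(self) -> "DesiredRegulation":
        return DesiredRegulation(
            tuple((b, UP if d == DOWN else DOWN) for b, d in self.directions)
        )


@dataclass
class DrugCombination:
    """A selected drug subset with its aggregate screening quantities."""

    drugs: tuple[str, ...]
    aggregate_regulation: dict[str, float]
    total_side_effect: int
    ld50: dict[str, float]
    ec50: dict[str, float]


def side_effect_count(
    drug: str, tables: DrugSpecTables, biomarkers: set[str]
) -> int:
    """Number of the drug's bound targets excluding the desired biomarkers."""
    if drug not in tables.bindings:
        raise KeyError(f"unknown drug {drug!r}")
    return len(tables.bindings[drug] - set(biomarkers))


def _matches(value: float, direction: str) -> bool:
    # zero regulation cannot drive a direction, hence never "desired"
    if direction == UP:
        return value > 0
    return value < 0


def regulation_flags(
    drug: str, tables: DrugSpecTables, desired: DesiredRegulation
) -> dict[str, str]:
    """Per-biomarker status: desired / unwanted sign, or absent if unbound."""
    if drug not in tables.bindings:
        raise KeyError(f"unknown drug {drug!r}")
    flags = {}
    for biomarker in desired.biomarkers:
        if biomarker not in tables.bindings[drug]:
            flags[biomarker] = ABSENT
            continue
        value = tables.regulation_of(drug, biomarker)
        if value is None:
            flags[biomarker] = ABSENT
            continue
        if value == 0.0:
            logger.warning(
                "drug %s has exactly zero regulation on %s; flagged unwanted",
                drug, biomarker,
            )
            flags[biomarker] = UNWANTED
        else:
            flags[biomarker] = (
                DESIRED if _matches(value, desired.direction(biomarker))
                else UNWANTED
            )
    return flags


def filter_candidates(
    tables: DrugSpecTables,
    desired: DesiredRegulation,
    min_ld50: float | None = None,
    max_ec50: float | None = None,
    max_side_effect: int | None = None,
    allow_unwanted: bool = True,
) -> list[str]:
    """Screen drugs on the four specifications and rank the survivors.

    Survivors are sorted by LD50 descending (least toxic first), then side
    effect ascending, then EC50 ascending, then drug id — a deterministic
    total order.
    """
    biomarkers = set(desired.biomarkers)
    survivors = []
    for drug in tables.drugs:
        if min_ld50 is not None and tables.toxicity[drug] < min_ld50:
            continue
        if max_ec50 is not None and tables.sensitivity[drug] > max_ec50:
            continue
        se = side_effect_count(drug, tables, biomarkers)
        if max_side_effect is not None and se > max_side_effect:
            continue
        if not allow_unwanted:
            flags = regulation_flags(drug, tables, desired)
            if any(v == UNWANTED for v in flags.values()):
                continue
        survivors.append(drug)
    return sorted(
        survivors,
        key=lambda d: (
            -tables.toxicity[d],
            side_effect_count(d, tables, biomarkers),
            tables.sensitivity[d],
            d,
        ),
    )


def combination_feasible(
    drugs: tuple[str, ...], tables: DrugSpecTables, desired: DesiredRegulation
) -> tuple[bool, dict[str, float]]:
    """Check coverage + net-direction feasibility; return aggregate regulation.

    Feasible means every biomarker is bound by at least one member and the
    member-summed regulation ability has the desired sign for every
    biomarker (net-effect reasoning: a member's small unwanted regulation
    may be outweighed by another member).
    """
    aggregate: dict[str, float] = {}
    for biomarker in desired.biomarkers:
        values = [
            tables.regulation_of(d, biomarker)
            for d in drugs
            if biomarker in tables.bindings[d]
            and tables.regulation_of(d, biomarker) is not None
        ]
        if not values:
            return False, aggregate
        total = float(sum(values))
        aggregate[biomarker] = total
        if not _matches(total, desired.direction(biomarker)):
            return False, aggregate
    return True, aggregate


def select_combination(
    tables: DrugSpecTables,
    desired: DesiredRegulation,
    max_size: int = 2,
    diagnostics: list[dict] | None = None,
) -> DrugCombination:
    """Exhaustively search drug subsets of size <= max_size.

    Among feasible subsets the winner has minimal size, then minimal total
    side effect, then maximal minimum LD50, then minimal total EC50, then
    lexicographically smallest ids.  Raises if nothing is feasible.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    biomarkers = set(desired.biomarkers)
    best: tuple | None = None
    best_combo: DrugCombination | None = None
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(tables.drugs, size):
            feasible, aggregate = combination_feasible(subset, tables, desired)
            total_se = sum(
                side_effect_count(d, tables, biomarkers) for d in subset
            )
            if diagnostics is not None:
                diagnostics.append(
                    {
                        "drugs": list(subset),
                        "feasible": feasible,
                        "aggregate_regulation": dict(aggregate),
                        "total_side_effect": total_se,
                    }
                )
            if not feasible:
                continue
            key = (
                size,
                total_se,
                -min(tables.toxicity[d] for d in subset),
                sum(tables.sensitivity[d] for d in subset),
                subset,
            )
            if best is None or key < best:
                best = key
                best_combo = DrugCombination(
                    subset,
                    aggregate,
                    total_se,
                    {d: tables.toxicity[d] for d in subset},
                    {d: tables.sensitivity[d] for d in subset},
                )
        if best_combo is not None:
            break  # minimal size found; larger sizes cannot win
    if best_combo is None:
        raise ValueError(
            f"no feasible drug combination of size <= {max_size} covers "
            f"{sorted(biomarkers)}"
        )
    return best_combo


# --- TSV round-trip -------------------------------------------------------

def tables_to_frames(tables: DrugSpecTables) -> dict[str, pd.DataFrame]:
    reg = pd.DataFrame(
        [
            {"drug": d, "gene": g, "ability": v}
            for (d, g), v in sorted(tables.regulation.items())
        ]
    )
    props = pd.DataFrame(
        [
            {
                "drug": d,
                "ld50": tables.toxicity[d],
                "ec50": tables.sensitivity[d],
            }
            for d in tables.drugs
        ]
    )
    binds = pd.DataFrame(
        [
            {"drug": d, "target": t}
            for d in tables.drugs
            for t in sorted(tables.bindings[d])
        ]
    )
    return {"regulation": reg, "properties": props, "bindings": binds}


def write_drug_tables(tables: DrugSpecTables, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, frame in tables_to_frames(tables).items():
        frame.to_csv(directory / f"{name}.tsv", sep="\t", index=False)


def read_drug_tables(directory) -> DrugSpecTables:
    from pathlib import Path

    directory = Path(directory)
    reg = pd.read_csv(directory / "regulation.tsv", sep="\t")
    props = pd.read_csv(directory / "properties.tsv", sep="\t")
    binds = pd.read_csv(directory / "bindings.tsv", sep="\t")
    tables = DrugSpecTables(
        regulation={
            (r.drug, r.gene): float(r.ability) for r in reg.itertuples()
        },
        toxicity={r.drug: float(r.ld50) for r in props.itertuples()},
        sensitivity={r.drug: float(r.ec50) for r in props.itertuples()},
        bindings={
            d: set(g["target"]) for d, g in binds.groupby("drug")
        },
    )
    return tables
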