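"""Order-of-magnitude ligand availability budget.

Compares the number of free agonist molecules in a small sample volume over
the culture (a 45 x 45 x 5 um box, ~10 pL) with the number bound to cell
surface receptors in the same volume, for a sparse box (one cell) versus a
dense box (a cluster of cells).  If free ligand outnumbers bound ligand by
tens to hundreds of times, receptor uptake by neighbors cannot appreciably
deplete the local agonist concentration, ruling out ligand competition as
the cause of density-dependent activation differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "BudgetScenario",
    "free_ligand_count",
    "bound_ligand_count",
    "free_to_bound_ratio",
    "scenario_table",
    "dense_scenario",
    "sparse_scenario",
]

AVOGADRO = 6.02214076e23
_L_PER_UM3 = 1e-15


@dataclass(frozen=True)
class BudgetScenario:
    """Sample-volume geometry, agonist level and receptor assumptions.

    receptors_per_cell and kd are order-of-magnitude assumptions and must
    be stated for any reported run; defaults are 5000 receptors and
    kd = 100 nM.
    """

    concentration_nM: float
    n_cells: int
    box_side_um: float = 45.0
    box_height_um: float = 5.0
    receptors_per_cell: float = 5000.0
    kd_nM: float = 100.0

    def __post_init__(self) -> None:
        if self.concentration_nM < 0:
            raise ValueError("concentration_nM must be non-negative")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        for name in ("box_side_um", "box_height_um", "receptors_per_cell", "kd_nM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def volume_um3(self) -> float:
        return self.box_side_um**2 * self.box_height_um

    @property
    def volume_L(self) -> float:
        return self.volume_um3 * _L_PER_UM3


def dense_scenario(concentration_nM: float = 100.0, **kwargs) -> BudgetScenario:
    """Default dense box: a 9-cell cluster fills the sample volume."""
    return BudgetScenario(concentration_nM=concentration_nM, n_cells=9, **kwargs)


def sparse_scenario(concentration_nM: float = 100.0, **kwargs) -> BudgetScenario:
    """Default sparse box: a single cell in the sample volume."""
    return BudgetScenario(concentration_nM=concentration_nM, n_cells=1, **kwargs)


def free_ligand_count(scenario: BudgetScenario) -> float:
    """Free agonist molecules in solution in the box: C * V * N_A."""
    return scenario.concentration_nM * 1e-9 * scenario.volume_L * AVOGADRO


def bound_ligand_count(scenario: BudgetScenario) -> float:
    """Receptor-bound agonist molecules in the box at equilibrium occupancy
    C / (C + Kd), capped at full occupancy."""
    occupancy = scenario.concentration_nM / (scenario.concentration_nM + scenario.kd_nM)
    occupancy = min(occupancy, 1.0)
    return scenario.n_cells * scenario.receptors_per_cell * occupancy


def free_to_bound_ratio(scenario: BudgetScenario) -> float:
    """Free/bound molecule ratio; inf (unbounded) when nothing is bound."""
    bound = bound_ligand_count(scenario)
    if bound == 0:
        return float("inf")
    return free_ligand_count(scenario) / bound


def scenario_table(scenarios: dict[str, BudgetScenario]) -> pd.DataFrame:
    """Tidy (scenario, free, bound, ratio) table for a set of named scenarios."""
    rows = []
    for name, sc in scenarios.items():
        rows.append(
            {
                "scenario": name,
                "volume_pL": sc.volume_L * 1e12,
                "free_molecules": free_ligand_count(sc),
                "bound_molecules": bound_ligand_count(sc),
                "free_to_bound": free_to_bound_ratio(sc),
            }
        )
    return pd.DataFrame(rows)
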