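"""Scenario grids: the full simulation parameter space and subsets of it.

A :class:`ScenarioGrid` is a thin wrapper over a pandas DataFrame with one
row per scenario and columns exactly::

    n_co, r, gamma_ca, gamma_co, phi, theta, m, k, rr_AA, mode, alpha

:func:`build_canonical_grid` constructs the full Cartesian product of the
canonical simulation levels (4 x 3^9 = 78732 raw combinations).  Scenarios
whose risk parameters force a penetrance above 1 are "unphysical" and are
excluded from the physical subset (5832 of them, leaving 72900); scenarios
with rr_AA = 1 are null models (19683, counted once per inheritance mode).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .design import ConfusionMatrix, Scenario, StudyDesign
from .disease import MODES, DiseaseModel, is_physical

GRID_COLUMNS = [
    "n_co",
    "r",
    "gamma_ca",
    "gamma_co",
    "phi",
    "theta",
    "m",
    "k",
    "rr_AA",
    "mode",
    "alpha",
]

#: Canonical simulation levels for each parameter.
CANONICAL_LEVELS: dict[str, tuple] = {
    "r": (1, 2, 4),
    "gamma_ca": (0, 1, 4),
    "gamma_co": (0, 1, 4),
    "phi": (0.6, 0.8, 1.0),
    "theta": (0.6, 0.8, 1.0),
    "rr_AA": (1.0, 1.4, 3.0, 9.0),
    "n_co": (200, 1000, 5000),
    "m": (0.05, 0.10, 0.30),
    "k": (0.001, 0.01, 0.30),
    "mode": MODES,
}


@dataclass(eq=False)
class ScenarioGrid:
    """A collection of scenarios, stored as a parameter table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GRID_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"grid table missing columns: {missing}")
        self.table = self.table[GRID_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def scenario(self, i: int) -> Scenario:
        """Materialise row ``i`` as a :class:`~silverpower.design.Scenario`."""
        row = self.table.iloc[i]
        return Scenario(
            design=StudyDesign(
                n_co=float(row.n_co),
                r=float(row.r),
                gamma_ca=float(row.gamma_ca),
                gamma_co=float(row.gamma_co),
            ),
            confusion=ConfusionMatrix(phi=float(row.phi), theta=float(row.theta)),
            disease=DiseaseModel(
                m=float(row.m), k=float(row.k), rr_AA=float(row.rr_AA), mode=row["mode"]
            ),
            alpha=float(row.alpha),
        )

    def __iter__(self) -> Iterator[Scenario]:
        return (self.scenario(i) for i in range(len(self)))

    def physical_mask(self) -> np.ndarray:
        """Boolean mask of scenarios with all penetrances <= 1.

        Physicality depends only on (m, k, rr_AA, mode), so the check runs
        once per unique risk-parameter combination.
        """
        risk = self.table[["m", "k", "rr_AA", "mode"]]
        uniq = risk.drop_duplicates()
        ok = {
            tuple(row): is_physical(row.m, row.k, row.rr_AA, row.mode)
            for row in uniq.itertuples(index=False)
        }
        return np.array([ok[tuple(row)] for row in risk.itertuples(index=False)])

    def null_mask(self) -> np.ndarray:
        """Boolean mask of null scenarios (rr_AA = 1)."""
        return (self.table["rr_AA"] == 1.0).to_numpy()

    def subset(self, mask: np.ndarray) -> "ScenarioGrid":
        return ScenarioGrid(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    def physical(self) -> "ScenarioGrid":
        return self.subset(self.physical_mask())

    def nulls(self) -> "ScenarioGrid":
        return self.subset(self.null_mask())

    @classmethod
    def from_product(cls, levels: dict, alpha: float = 0.05) -> "ScenarioGrid":
        """Cartesian product of per-parameter level lists."""
        keys = [c for c in GRID_COLUMNS if c != "alpha"]
        lv = {k: list(np.atleast_1d(levels[k])) for k in keys}
        rows = [dict(zip(keys, combo)) for combo in itertools.product(*(lv[k] for k in keys))]
        table = pd.DataFrame(rows)
        table["alpha"] = alpha
        return cls(table)

    @classmethod
    def from_scenarios(cls, scenarios: list[Scenario]) -> "ScenarioGrid":
        rows = []
        for s in scenarios:
            rows.append(
                {
                    "n_co": s.design.n_co,
                    "r": s.design.r,
                    "gamma_ca": s.design.gamma_ca,
                    "gamma_co": s.design.gamma_co,
                    "phi": s.confusion.phi,
                    "theta": s.confusion.theta,
                    "m": s.disease.m,
                    "k": s.disease.k,
                    "rr_AA": s.disease.rr_AA,
                    "mode": s.disease.mode,
                    "alpha": s.alpha,
                }
            )
        return cls(pd.DataFrame(rows))


def build_canonical_grid(alpha: float = 0.05) -> ScenarioGrid:
    """The full canonical grid: 78732 raw combinations (4 x 3^9)."""
    return ScenarioGrid.from_product(CANONICAL_LEVELS, alpha=alpha)
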