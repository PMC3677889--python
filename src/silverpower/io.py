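"""Serialization: scenarios, grids and result tables.

Two plain-text formats:

* one scenario — flat ``key=value`` lines (keys are the grid columns);
* a grid or result table — RFC-4180-style CSV, '.' decimal radix, with
  ``# key=value`` comment headers carrying the tool version and master seed
  so any row can be re-run exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from . import __version__
from .design import ConfusionMatrix, Scenario, StudyDesign
from .disease import DiseaseModel
from .grids import GRID_COLUMNS, ScenarioGrid

_FLOAT_KEYS = [c for c in GRID_COLUMNS if c != "mode"]


def scenario_to_text(scenario: Scenario) -> str:
    """Flat key=value representation of one scenario."""
    row = ScenarioGrid.from_scenarios([scenario]).table.iloc[0]
    return "".join(f"{key}={row[key]}\n" for key in GRID_COLUMNS)


def scenario_from_text(text: str) -> Scenario:
    """Parse the key=value format; raises with the offending line number."""
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in GRID_COLUMNS:
            raise ValueError(f"line {lineno}: unknown parameter {key!r}")
        try:
            values[key] = val.strip() if key == "mode" else float(val)
        except ValueError as err:
            raise ValueError(f"line {lineno}: bad value for {key}: {val!r}") from err
    missing = [k for k in GRID_COLUMNS if k not in values and k != "alpha"]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    return Scenario(
        design=StudyDesign(
            n_co=values["n_co"],
            r=values["r"],
            gamma_ca=values["gamma_ca"],
            gamma_co=values["gamma_co"],
        ),
        confusion=ConfusionMatrix(phi=values["phi"], theta=values["theta"]),
        disease=DiseaseModel(
            m=values["m"], k=values["k"], rr_AA=values["rr_AA"], mode=values["mode"]
        ),
        alpha=float(values.get("alpha", 0.05)),
    )


def read_scenario(path) -> Scenario:
    return scenario_from_text(Path(path).read_text())


def read_grid(path) -> ScenarioGrid:
    """Read a scenario grid from CSV (comment headers allowed)."""
    try:
        return ScenarioGrid(pd.read_csv(path, comment="#"))
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed grid file {path}: {err}") from err


def write_grid(grid: ScenarioGrid, path) -> None:
    write_results(grid.table, path)


def write_results(table: pd.DataFrame, path, seed: int | None = None, **metadata) -> None:
    """Write a result table as CSV with reproducibility headers.

    Headers record the tool version, the master seed and any extra metadata
    as ``# key=value`` comment lines above the column header.
    """
    buf = _io.StringIO()
    buf.write(f"# tool=silverpower {__version__}\n")
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    for key, val in metadata.items():
        buf.write(f"# {key}={val}\n")
    table.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results` (lossless round-trip)."""
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed results file {path}: {err}") from err
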