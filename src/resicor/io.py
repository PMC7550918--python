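"""Readers and writers for the package's text formats.

Supported formats
-----------------
* Energy matrix / activity CSV or TSV: header ``compound,RES###,...`` resp.
  ``compound,pIC50``; decimal point, no thousands separators. A write/read
  round trip reproduces every value bit-identically (floats are serialized
  with ``repr``).
* Per-frame decomposition contribution files in the style written by MM-PBSA
  decomposition tools: whitespace-delimited, first column a frame index/time,
  header of residue labels, one row per frame; frames are averaged on read.
* Site maps: CSV with ``site,residue`` columns, one row per membership.
* Reports: CSV or JSON, full-precision values plus 2-decimal "rounded" fields
  matching the display convention of published tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    COMPONENT_COLUMNS,
    ActivityTable,
    EnergyComponentTable,
    EnergyMatrix,
    SiteMap,
)
from .errors import DomainError, ParseError, StructuralError
from .residues import ResidueID

_SEP = {"csv": ",", "tsv": "\t"}

#: Multiplier converting an IC50 in the given unit to molar.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


def pic50_from_ic50(ic50: float, unit: str) -> float:
    """pIC50 = -log10(IC50 in molar).

    >>> pic50_from_ic50(1e-7, "M")
    7.0
    >>> pic50_from_ic50(1.0, "nM")
    9.0
    """
    if unit not in _UNIT_TO_MOLAR:
        raise DomainError(f"unknown IC50 unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)}")
    if not (ic50 > 0):
        raise DomainError(f"IC50 must be strictly positive, got {ic50!r}")
    return -math.log10(ic50 * _UNIT_TO_MOLAR[unit])


def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    if dialect not in _SEP:
        raise DomainError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file does not exist: {path}")
    try:
        return pd.read_csv(path, sep=_SEP[dialect], dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty input file: {path}") from exc


def _to_float(cell: str, *, row: str, col: str, path: Path) -> float:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(
            f"{path}: non-numeric value {cell!r} at row {row!r}, column {col!r}"
        ) from exc


def read_energy_matrix(
    path: str | Path, dialect: str = "csv", fill_missing: float | None = None
) -> EnergyMatrix:
    """Read a compounds x residues energy table.

    Missing cells are an error unless ``fill_missing`` is given (decomposition
    tools omit residues with no contact; silent zero-filling would corrupt
    correlations, so the fill is explicit).
    """
    path = Path(path)
    raw = _read_table(path, dialect)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a compound column plus residue columns")
    residue_labels = list(raw.columns[1:])
    residues = []
    for lab in residue_labels:
        try:
            residues.append(ResidueID.parse(lab))
        except ParseError as exc:
            raise ParseError(f"{path}: bad residue column header {lab!r}: {exc}") from exc
    compounds = [str(c) for c in raw.iloc[:, 0]]
    values = np.empty((len(compounds), len(residues)), dtype=float)
    for i, comp in enumerate(compounds):
        for j, lab in enumerate(residue_labels):
            cell = raw.iloc[i, j + 1]
            if fill_missing is not None and (
                cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == ""
            ):
                values[i, j] = fill_missing
            else:
                values[i, j] = _to_float(cell, row=comp, col=lab, path=path)
    return EnergyMatrix.from_arrays(compounds, residues, values)


def write_energy_matrix(matrix: EnergyMatrix, path: str | Path, dialect: str = "csv") -> None:
    if dialect not in _SEP:
        raise DomainError(f"unknown dialect {dialect!r}")
    sep = _SEP[dialect]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(["compound", *(str(r) for r in matrix.residues)]) + "\n")
        for comp in matrix.compounds:
            row = [comp] + [repr(matrix.value(comp, r)) for r in matrix.residues]
            fh.write(sep.join(row) + "\n")


def read_activity_table(path: str | Path, unit: str = "pIC50", dialect: str = "csv") -> ActivityTable:
    """Read a compound,value table; IC50 values are converted to pIC50."""
    path = Path(path)
    raw = _read_table(path, dialect)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected columns compound,value")
    compounds = [str(c) for c in raw.iloc[:, 0]]
    if len(set(compounds)) != len(compounds):
        dup = next(c for c in compounds if compounds.count(c) > 1)
        raise ParseError(f"{path}: duplicate compound {dup!r}")
    values = {}
    col = raw.columns[1]
    for comp, cell in zip(compounds, raw.iloc[:, 1]):
        v = _to_float(cell, row=comp, col=str(col), path=path)
        values[comp] = v if unit == "pIC50" else pic50_from_ic50(v, unit)
    return ActivityTable(values)


def write_activity_table(activities: ActivityTable, path: str | Path, dialect: str = "csv") -> None:
    sep = _SEP[dialect]
    with Path(path).open("w") as fh:
        fh.write(sep.join(["compound", "pIC50"]) + "\n")
        for comp in activities.compounds:
            fh.write(sep.join([comp, repr(activities[comp])]) + "\n")


def read_component_table(path: str | Path, dialect: str = "csv") -> EnergyComponentTable:
    path = Path(path)
    raw = _read_table(path, dialect)
    missing = [c for c in COMPONENT_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: component table missing columns {missing}")
    compounds = [str(c) for c in raw.iloc[:, 0]]
    data = {}
    for col in COMPONENT_COLUMNS:
        data[col] = [
            _to_float(cell, row=comp, col=col, path=path)
            for comp, cell in zip(compounds, raw[col])
        ]
    return EnergyComponentTable(pd.DataFrame(data, index=compounds))


def read_site_map(path: str | Path, dialect: str = "csv") -> SiteMap:
    path = Path(path)
    raw = _read_table(path, dialect)
    if not {"site", "residue"} <= set(raw.columns):
        raise ParseError(f"{path}: site map needs columns site,residue")
    sites: dict[str, list[ResidueID]] = {}
    for _, row in raw.iterrows():
        sites.setdefault(str(row["site"]), []).append(ResidueID.parse(str(row["residue"])))
    return SiteMap(sites)


def read_decomp_contrib(
    paths: Sequence[str | Path],
    compound_ids: Sequence[str],
    aggregate: str = "mean",
) -> EnergyMatrix:
    """Read per-frame decomposition contribution files, one per compound.

    Each file is whitespace-delimited: a header row of residue labels (its
    first token names the frame/time column) and one row per frame whose first
    column is the frame index or time. The returned matrix holds the per-file
    frame average (arithmetic mean by default, matching the convention of
    averaging MM-PBSA snapshots; ``aggregate="median"`` is available).
    """
    if len(paths) != len(compound_ids):
        raise DomainError(
            f"{len(paths)} files but {len(compound_ids)} compound identifiers"
        )
    if aggregate not in {"mean", "median"}:
        raise DomainError(f"unknown aggregate {aggregate!r}")
    residues_ref: tuple[ResidueID, ...] | None = None
    rows = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise ParseError(f"input file does not exist: {path}")
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if len(lines) < 2:
            raise ParseError(f"{path}: no frames found")
        header = lines[0].split()
        residues = tuple(ResidueID.parse(lab) for lab in header[1:])
        if residues_ref is None:
            residues_ref = residues
        elif residues != residues_ref:
            diff = set(residues) ^ set(residues_ref)
            raise StructuralError(
                f"{path}: residue set differs from first file (mismatch: "
                + ", ".join(str(r) for r in sorted(diff))
                + ")"
            )
        frames = []
        for ln in lines[1:]:
            parts = ln.split()
            if len(parts) != len(residues) + 1:
                raise ParseError(f"{path}: row has {len(parts)} fields, expected {len(residues) + 1}")
            frames.append([float(x) for x in parts[1:]])
        arr = np.asarray(frames, dtype=float)
        rows.append(arr.mean(axis=0) if aggregate == "mean" else np.median(arr, axis=0))
    assert residues_ref is not None
    return EnergyMatrix.from_arrays(list(compound_ids), residues_ref, np.vstack(rows))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _round2(x: float) -> float:
    return round(float(x), 2)


def _result_payload(result) -> dict:
    """JSON-able payload for a profile or cluster result."""
    from .correlation import (  # local import to avoid a cycle
        ClusterResult,
        ComponentCorrelationProfile,
        ResidueCorrelationProfile,
    )

    if isinstance(result, ResidueCorrelationProfile):
        if not result.r:
            raise DomainError("cannot write an empty correlation profile")
        return {
            "kind": "residue_correlation_profile",
            "n": result.n,
            "residues": [str(r) for r in result.r],
            "r": {str(res): float(v) for res, v in result.r.items()},
            "r_rounded": {str(res): _round2(v) for res, v in result.r.items()},
            "undefined": [str(r) for r in result.undefined],
        }
    if isinstance(result, ComponentCorrelationProfile):
        return {
            "kind": "component_correlation_profile",
            "n": result.n,
            "r": {k: float(v) for k, v in result.r.items()},
            "r_rounded": {k: _round2(v) for k, v in result.r.items()},
        }
    if isinstance(result, ClusterResult):
        payload = {
            "kind": "cluster_result",
            "residues": [str(r) for r in result.residues_sorted],
            "per_compound_sum": {c: float(v) for c, v in result.per_compound_sum.items()},
            "r": float(result.r),
            "r_rounded": _round2(result.r),
            "n": result.n,
            "p_value": result.p_value,
            "ci": (
                None
                if result.ci_low is None
                else [float(result.ci_low), float(result.ci_high)]
            ),
            "cv": (
                None
                if result.cv_q2 is None
                else {"q2": float(result.cv_q2), "rmse": float(result.cv_rmse)}
            ),
        }
        return payload
    raise DomainError(f"cannot write a report for {type(result).__name__}")


def write_report(result, path: str | Path, format: str = "json") -> None:
    """Serialize a profile or cluster result to ``path`` as csv or json."""
    payload = _result_payload(result)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        if payload["kind"] == "cluster_result":
            with path.open("w") as fh:
                fh.write("field,value\n")
                fh.write(f"residues,{';'.join(payload['residues'])}\n")
                fh.write(f"r,{payload['r']!r}\n")
                fh.write(f"r_rounded,{payload['r_rounded']}\n")
                for comp, v in payload["per_compound_sum"].items():
                    fh.write(f"sum[{comp}],{v!r}\n")
        else:
            keys = payload["r"].keys()
            with path.open("w") as fh:
                fh.write("name,r,r_rounded\n")
                for k in keys:
                    fh.write(f"{k},{payload['r'][k]!r},{payload['r_rounded'][k]}\n")
    else:
        raise DomainError(f"unknown report format {format!r}")


def dataclass_to_jsonable(obj):
    """Recursively convert dataclasses / numpy / pandas objects for json.dumps."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: dataclass_to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(c): dataclass_to_jsonable(obj[c]) for c in obj.columns}
    if isinstance(obj, ResidueID):
        return str(obj)
    if isinstance(obj, (frozenset, set, tuple, list)):
        items = [dataclass_to_jsonable(v) for v in obj]
        if isinstance(obj, (frozenset, set)):
            items = sorted(items)
        return items
    if isinstance(obj, dict):
        return {str(dataclass_to_jsonable(k)): dataclass_to_jsonable(v) for k, v in obj.items()}
    return obj
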