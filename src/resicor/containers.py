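"""In-memory containers for decomposition-energy and activity data.

All containers are thin, validated wrappers around pandas objects:

* :class:`EnergyMatrix` — compounds x residues, per-residue binding-energy
  contributions in kJ/mol (negative = favorable).
* :class:`ActivityTable` — compound -> pIC50 (dimensionless).
* :class:`EnergyComponentTable` — compound -> MM-PBSA energy components.
* :class:`SiteMap` — SAR-site label -> residue membership.

Containers are treated as immutable once constructed; operations return new
objects or plain numpy/pandas results.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, StructuralError
from .residues import ResidueID, sorted_residues

#: Column names of an EnergyComponentTable, in canonical order.
COMPONENT_COLUMNS = (
    "vdw_kJmol",
    "elec_kJmol",
    "polar_solv_kJmol",
    "sasa_kJmol",
    "binding_kJmol",
)

#: Short component keys used in correlation profiles and reports.
COMPONENT_KEYS = ("vdw", "elec", "polar_solv", "sasa", "binding")

COMPONENT_KEY_TO_COLUMN = dict(zip(COMPONENT_KEYS, COMPONENT_COLUMNS))


def _check_unique(labels: Sequence, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise DomainError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


class EnergyMatrix:
    """A complete compounds x residues table of energy contributions (kJ/mol).

    Parameters
    ----------
    data:
        DataFrame indexed by compound identifier, one column per residue.
        Columns may be ``ResidueID`` objects or parseable labels ("TYR341").
        Every cell must be present and finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise DomainError("energy matrix must have at least one compound and one residue")
        residues = tuple(
            c if isinstance(c, ResidueID) else ResidueID.parse(str(c)) for c in data.columns
        )
        compounds = tuple(str(c) for c in data.index)
        if any(not c for c in compounds):
            raise DomainError("compound identifiers must be non-empty strings")
        _check_unique(compounds, "compound identifier")
        _check_unique(residues, "residue")
        values = data.to_numpy(dtype=float, copy=True)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DomainError(
                f"non-finite energy for compound {compounds[i]!r}, residue {residues[j]}"
            )
        self._data = pd.DataFrame(
            values, index=pd.Index(compounds, name="compound"),
            columns=[str(r) for r in residues],
        )
        self._residues = residues

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        compounds: Sequence[str],
        residues: Sequence[ResidueID | str],
        values: np.ndarray,
    ) -> "EnergyMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(compounds), len(residues)):
            raise DomainError(
                f"values shape {values.shape} does not match "
                f"{len(compounds)} compounds x {len(residues)} residues"
            )
        return cls(pd.DataFrame(values, index=list(compounds), columns=[str(r) for r in residues]))

    # -- accessors ------------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying DataFrame (string residue labels as columns)."""
        return self._data

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    @property
    def residues(self) -> tuple[ResidueID, ...]:
        return self._residues

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def value(self, compound: str, residue: ResidueID | str) -> float:
        return float(self._data.at[compound, str(residue)])

    def column(self, residue: ResidueID | str) -> np.ndarray:
        """Energy contributions of one residue across compounds."""
        key = str(residue)
        if key not in self._data.columns:
            raise DomainError(f"residue {key} is not a column of the energy matrix")
        return self._data[key].to_numpy()

    def require_residues(self, residues: Iterable[ResidueID]) -> tuple[ResidueID, ...]:
        """Validate that all residues are columns; return them in canonical order."""
        residues = tuple(residues)
        if not residues:
            raise DomainError("residue set must be non-empty")
        known = set(self._residues)
        for r in residues:
            if r not in known:
                raise DomainError(f"residue {r} is not a column of the energy matrix")
        return sorted_residues(residues)

    def subset(self, residues: Iterable[ResidueID]) -> "EnergyMatrix":
        res = self.require_residues(residues)
        return EnergyMatrix(self._data[[str(r) for r in res]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnergyMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"EnergyMatrix({n} compounds x {m} residues)"


class ActivityTable:
    """Compound -> pIC50 mapping (pIC50 = -log10 of the molar IC50)."""

    #: pIC50 outside this open interval triggers a warning (not an error).
    SANITY_RANGE = (0.0, 15.0)

    def __init__(self, values: Mapping[str, float] | pd.Series):
        series = pd.Series(values, dtype=float)
        compounds = tuple(str(c) for c in series.index)
        _check_unique(compounds, "compound identifier")
        if len(series) == 0:
            raise DomainError("activity table must be non-empty")
        if not np.all(np.isfinite(series.to_numpy())):
            bad = series.index[~np.isfinite(series.to_numpy())][0]
            raise DomainError(f"non-finite pIC50 for compound {bad!r}")
        lo, hi = self.SANITY_RANGE
        out = series[(series <= lo) | (series >= hi)]
        if len(out):
            warnings.warn(
                f"pIC50 outside the typical biological range ({lo}, {hi}) for: "
                + ", ".join(f"{c}={v:g}" for c, v in out.items()),
                UserWarning,
                stacklevel=2,
            )
        self._series = pd.Series(
            series.to_numpy(dtype=float), index=pd.Index(compounds, name="compound"),
            name="pIC50",
        )

    @property
    def series(self) -> pd.Series:
        return self._series

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(self._series.index)

    def __getitem__(self, compound: str) -> float:
        return float(self._series[compound])

    def __len__(self) -> int:
        return len(self._series)

    def aligned_to(self, compounds: Sequence[str]) -> np.ndarray:
        """pIC50 values in the given compound order.

        Pairing is always by compound identifier, never by row position.
        Raises :class:`DomainError` if any requested compound is missing.
        """
        missing = [c for c in compounds if c not in self._series.index]
        if missing:
            raise DomainError(f"compounds missing from activity table: {missing}")
        return self._series.loc[list(compounds)].to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityTable):
            return NotImplemented
        return self._series.equals(other._series)

    def __repr__(self) -> str:
        return f"ActivityTable({len(self)} compounds)"


class EnergyComponentTable:
    """Per-compound MM-PBSA energy components (kJ/mol).

    Columns: van der Waals, electrostatic, polar solvation, SASA (nonpolar
    solvation) and total binding energy.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in COMPONENT_COLUMNS if c not in data.columns]
        if missing:
            raise StructuralError(f"component table missing columns: {missing}")
        compounds = tuple(str(c) for c in data.index)
        _check_unique(compounds, "compound identifier")
        values = data[list(COMPONENT_COLUMNS)].to_numpy(dtype=float, copy=True)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DomainError(
                f"non-finite {COMPONENT_COLUMNS[j]} for compound {compounds[i]!r}"
            )
        self._data = pd.DataFrame(
            values, index=pd.Index(compounds, name="compound"), columns=list(COMPONENT_COLUMNS)
        )

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    def component(self, key: str) -> np.ndarray:
        """Values of one component across compounds; `key` is a short name
        from :data:`COMPONENT_KEYS` or a full column name."""
        col = COMPONENT_KEY_TO_COLUMN.get(key, key)
        if col not in self._data.columns:
            raise DomainError(f"unknown energy component {key!r}")
        return self._data[col].to_numpy()

    def value(self, compound: str, key: str) -> float:
        col = COMPONENT_KEY_TO_COLUMN.get(key, key)
        return float(self._data.at[compound, col])

    def __repr__(self) -> str:
        return f"EnergyComponentTable({len(self._data)} compounds)"


class SiteMap:
    """SAR-site label -> set of residues; each residue in at most one site."""

    def __init__(self, sites: Mapping[str, Iterable[ResidueID]]):
        built: dict[str, frozenset[ResidueID]] = {}
        seen: dict[ResidueID, str] = {}
        for label, members in sites.items():
            if label in built:
                raise DomainError(f"duplicate site label {label!r}")
            mset = frozenset(members)
            if not mset:
                raise DomainError(f"site {label!r} has an empty residue set")
            for r in mset:
                if r in seen:
                    raise DomainError(
                        f"residue {r} assigned to both {seen[r]!r} and {label!r}"
                    )
                seen[r] = label
            built[label] = mset
        if not built:
            raise DomainError("site map must contain at least one site")
        self._sites = built

    @property
    def sites(self) -> dict[str, frozenset[ResidueID]]:
        return dict(self._sites)

    def labels(self) -> tuple[str, ...]:
        return tuple(self._sites)

    def __getitem__(self, label: str) -> frozenset[ResidueID]:
        return self._sites[label]

    def __iter__(self):
        return iter(self._sites)

    def __len__(self) -> int:
        return len(self._sites)

    def site_of(self, residue: ResidueID) -> str | None:
        for label, members in self._sites.items():
            if residue in members:
                return label
        return None

    def __repr__(self) -> str:
        return f"SiteMap({', '.join(f'{k}:{len(v)}' for k, v in self._sites.items())})"
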