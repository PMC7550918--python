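"""Correlation of decomposition energies with inhibitory activity.

This is the numerical core of the package: Pearson product-moment correlation
of (a) individual residue energy columns, (b) MM-PBSA energy components, and
(c) cluster cumulative energies, against pIC50. Negative r means more
favorable (more negative) energy tracks higher potency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COMPONENT_KEYS, ActivityTable, EnergyComponentTable, EnergyMatrix
from .errors import DomainError
from .residues import ResidueID, sorted_residues

logger = logging.getLogger("resicor")

MIN_COMPOUNDS = 3


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise DomainError("correlation inputs must be one-dimensional")
    if len(x) != len(y):
        raise DomainError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < MIN_COMPOUNDS:
        raise DomainError(f"need at least {MIN_COMPOUNDS} observations, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("correlation inputs must be finite")
    if np.ptp(x) == 0:
        raise DomainError("first vector has zero variance")
    if np.ptp(y) == 0:
        raise DomainError("second vector has zero variance")
    return x, y


def pearson(x: Iterable[float], y: Iterable[float], method: str = "pearson") -> float:
    """Product-moment correlation of two equal-length vectors.

    Degenerate inputs (length mismatch, n < 3, zero variance) raise
    :class:`DomainError` rather than returning 0 or NaN. ``method="spearman"``
    substitutes the rank correlation for robustness studies.
    """
    x, y = _validate_pair(np.asarray(list(x)), np.asarray(list(y)))
    if method == "pearson":
        # cov / sqrt(vx * vy) in a form that is bit-symmetric in (x, y)
        xc = x - x.mean()
        yc = y - y.mean()
        r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    return float(min(1.0, max(-1.0, r)))


def columnwise_pearson(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of each column of ``values`` with ``y``.

    Returns ``(r, undefined)`` where ``undefined`` marks zero-variance columns
    (their r is NaN, never silently 0).
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != len(y):
        raise DomainError(f"matrix has {values.shape[0]} rows but activity has {len(y)}")
    if len(y) < MIN_COMPOUNDS:
        raise DomainError(f"need at least {MIN_COMPOUNDS} compounds, got {len(y)}")
    if np.ptp(y) == 0:
        raise DomainError("activity vector has zero variance")
    yc = y - y.mean()
    vc = values - values.mean(axis=0, keepdims=True)
    ss_col = np.einsum("ij,ij->j", vc, vc)
    undefined = ss_col == 0
    denom = np.sqrt(ss_col * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc.T @ yc) / denom
    r[undefined] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r, undefined


def pearson_against_rows(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation of ``x`` with every row of ``Y`` (vectorized; used by the
    permutation and bootstrap machinery). Zero-variance rows give NaN."""
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ss_rows = np.einsum("ij,ij->i", Yc, Yc)
    denom = np.sqrt(ss_rows * (xc @ xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / denom
    r[ss_rows == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class ResidueCorrelationProfile:
    """Per-residue correlation with activity.

    Attributes
    ----------
    r:
        Ordered residue -> Pearson r (matrix column order). Zero-variance
        residues are absent here and listed in ``undefined``.
    n:
        Number of compounds used.
    undefined:
        Residues whose correlation is undefined (zero-variance energy column);
        they are excluded from downstream selection.
    """

    r: dict[ResidueID, float]
    n: int
    undefined: tuple[ResidueID, ...] = ()

    def __post_init__(self) -> None:
        if self.n < MIN_COMPOUNDS:
            raise DomainError(f"profile needs n >= {MIN_COMPOUNDS}")
        for res, v in self.r.items():
            if not (-1.0 <= v <= 1.0):
                raise DomainError(f"correlation out of range for {res}: {v}")

    @property
    def residues(self) -> tuple[ResidueID, ...]:
        return tuple(self.r)

    def __getitem__(self, residue: ResidueID | str) -> float:
        if isinstance(residue, str):
            residue = ResidueID.parse(residue)
        return self.r[residue]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": [str(k) for k in self.r], "r": list(self.r.values())}
        ).set_index("residue")


@dataclass(frozen=True)
class ComponentCorrelationProfile:
    """Correlation of each MM-PBSA energy component with activity."""

    r: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if set(self.r) != set(COMPONENT_KEYS):
            raise DomainError(f"expected exactly the components {COMPONENT_KEYS}")

    def __getitem__(self, key: str) -> float:
        return self.r[key]


@dataclass(frozen=True)
class ClusterResult:
    """A residue cluster with its cumulative-energy correlation.

    ``r`` is pearson(per_compound_sum, pIC50) by construction. The optional
    fields are filled by the resampling/CV machinery.
    """

    residues: frozenset[ResidueID]
    per_compound_sum: pd.Series
    r: float
    n: int
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    cv_q2: float | None = None
    cv_rmse: float | None = None

    @property
    def residues_sorted(self) -> tuple[ResidueID, ...]:
        return sorted_residues(self.residues)

    @property
    def k(self) -> int:
        return len(self.residues)

    def with_stats(self, **kwargs) -> "ClusterResult":
        from dataclasses import replace

        return replace(self, **kwargs)


def _align(E: EnergyMatrix, A: ActivityTable) -> np.ndarray:
    """Activity vector in the matrix's compound order (paired by identifier)."""
    extra = set(A.compounds) - set(E.compounds)
    if extra:
        logger.warning(
            "activity table has %d compounds absent from the energy matrix "
            "(ignored): %s", len(extra), ", ".join(sorted(extra))
        )
    return A.aligned_to(E.compounds)


def residue_correlation_profile(
    E: EnergyMatrix, A: ActivityTable, method: str = "pearson"
) -> ResidueCorrelationProfile:
    """One correlation per residue column, paired by compound identifier.

    Thin wrapper over :class:`resicor.estimators.ResidueCorrelationSelector`.
    """
    from .estimators import ResidueCorrelationSelector

    y = _align(E, A)
    sel = ResidueCorrelationSelector(method=method).fit(E.data, y)
    r: dict[ResidueID, float] = {}
    undefined: list[ResidueID] = []
    for res, val, und in zip(E.residues, sel.correlations_, sel.undefined_):
        if und:
            logger.warning("residue %s has zero-variance energies; correlation undefined", res)
            undefined.append(res)
        else:
            r[res] = float(val)
    return ResidueCorrelationProfile(r=r, n=len(y), undefined=tuple(undefined))


def component_correlation_profile(
    C: EnergyComponentTable, A: ActivityTable, method: str = "pearson"
) -> ComponentCorrelationProfile:
    """Correlation of the five MM-PBSA energy components with pIC50."""
    y = A.aligned_to(C.compounds)
    r = {key: pearson(C.component(key), y, method=method) for key in COMPONENT_KEYS}
    return ComponentCorrelationProfile(r=r, n=len(y))


def cluster_sum(E: EnergyMatrix, residues: Iterable[ResidueID]) -> pd.Series:
    """Cumulative binding energy: per compound, the sum of the cluster's
    per-residue contributions (kJ/mol)."""
    res = E.require_residues(residues)
    return E.data[[str(r) for r in res]].sum(axis=1).rename("cluster_sum_kJmol")


def cluster_correlation(
    E: EnergyMatrix,
    residues: Iterable[ResidueID],
    A: ActivityTable,
    method: str = "pearson",
) -> ClusterResult:
    """Correlate a cluster's cumulative energy with activity."""
    sums = cluster_sum(E, residues)
    y = _align(E, A)
    r = pearson(sums.to_numpy(), y, method=method)
    return ClusterResult(
        residues=frozenset(E.require_residues(residues)),
        per_compound_sum=sums,
        r=r,
        n=len(y),
    )
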