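"""Exhaustive and greedy search for activity-correlated residue clusters.

Formalizes the manual cluster choice: enumerate (or greedily grow) residue
subsets, score each by the correlation of its cumulative energy with activity,
and rank. Objectives:

* ``most_negative_r`` (default) — smallest r, matching the favorable-binding
  sign convention;
* ``max_abs_r`` — largest absolute correlation.

Ties break toward smaller clusters, then the canonical residue order, so
output is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .containers import ActivityTable, EnergyMatrix, SiteMap
from .correlation import ClusterResult, _align, cluster_correlation, pearson_against_rows
from .errors import BudgetExceededError, DomainError
from .residues import ResidueID, sorted_residues

OBJECTIVES = ("most_negative_r", "max_abs_r")


@dataclass(frozen=True)
class SearchConfig:
    """Subset-search configuration.

    k_min, k_max:
        Cluster-size bounds (inclusive).
    objective:
        Ranking objective, see module docstring.
    site_map / site_coverage:
        When ``site_coverage`` is set, only subsets containing at least one
        residue from every site of ``site_map`` are considered.
    top_m:
        Number of ranked results returned.
    budget:
        Maximum number of subsets the exhaustive search may enumerate.
    """

    k_min: int = 1
    k_max: int = 1
    objective: str = "most_negative_r"
    site_map: SiteMap | None = None
    site_coverage: bool = False
    top_m: int = 10
    budget: int = 10**6

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise DomainError(f"invalid size bounds k_min={self.k_min}, k_max={self.k_max}")
        if self.objective not in OBJECTIVES:
            raise DomainError(f"objective must be one of {OBJECTIVES}")
        if self.top_m < 1:
            raise DomainError("top_m must be >= 1")
        if self.site_coverage and self.site_map is None:
            raise DomainError("site_coverage requires a site_map")


def _objective_value(r: float, objective: str) -> float:
    return r if objective == "most_negative_r" else -abs(r)


def _rank_key(r: float, k: int, residues: tuple[ResidueID, ...], objective: str):
    return (_objective_value(r, objective), k, residues)


def _covers_sites(residues: frozenset[ResidueID], site_map: SiteMap) -> bool:
    return all(residues & site_map[label] for label in site_map.labels())


def exhaustive_cluster_search(
    E: EnergyMatrix, A: ActivityTable, config: SearchConfig
) -> list[ClusterResult]:
    """Enumerate every subset of each size in [k_min, k_max] and rank.

    Correlations are computed vectorized per subset size. Subsets whose
    cumulative energy has zero variance have no defined correlation and are
    skipped. Raises :class:`BudgetExceededError` when the enumeration count
    would exceed ``config.budget`` (use :func:`greedy_cluster_search` then).
    """
    residues = sorted_residues(E.residues)  # canonical order: result is column-order invariant
    n_res = len(residues)
    if config.k_max > n_res:
        raise DomainError(f"k_max={config.k_max} exceeds the {n_res} residues available")
    total = sum(comb(n_res, k) for k in range(config.k_min, config.k_max + 1))
    if total > config.budget:
        raise BudgetExceededError(
            f"{total} subsets exceed the budget of {config.budget}; "
            "use greedy_cluster_search instead"
        )
    y = _align(E, A)
    X = E.data[[str(r) for r in residues]].to_numpy()  # compounds x residues
    ranked: list[tuple] = []
    for k in range(config.k_min, config.k_max + 1):
        combos = [
            c
            for c in itertools.combinations(range(n_res), k)
            if not config.site_coverage
            or _covers_sites(frozenset(residues[i] for i in c), config.site_map)
        ]
        if not combos:
            continue
        idx = np.asarray(combos, dtype=int)  # (n_subsets, k)
        sums = X[:, idx].sum(axis=2).T  # (n_subsets, compounds)
        rs = pearson_against_rows(y, sums)
        for combo, s, r in zip(combos, sums, rs):
            if np.isnan(r):
                continue
            members = sorted_residues(residues[i] for i in combo)
            ranked.append((_rank_key(float(r), k, members, config.objective), combo, s, float(r)))
    ranked.sort(key=lambda t: t[0])
    # the retained results go back through the scalar path so their r is
    # bit-identical to cluster_correlation on the same subset
    return [
        cluster_correlation(E, frozenset(residues[i] for i in combo), A)
        for _, combo, _, _ in ranked[: config.top_m]
    ]


def greedy_cluster_search(
    E: EnergyMatrix, A: ActivityTable, k: int, objective: str = "most_negative_r"
) -> ClusterResult:
    """Forward selection: grow the cluster one residue at a time, each step
    adding the residue that best improves the objective (lexicographic
    tie-break on the canonical residue order)."""
    if objective not in OBJECTIVES:
        raise DomainError(f"objective must be one of {OBJECTIVES}")
    residues = sorted_residues(E.residues)
    if not (1 <= k <= len(residues)):
        raise DomainError(f"k={k} out of range for {len(residues)} residues")
    current: set[ResidueID] = set()
    for _ in range(k):
        best: tuple | None = None
        for res in residues:
            if res in current:
                continue
            candidate = current | {res}
            try:
                r = cluster_correlation(E, candidate, A).r
            except DomainError:
                continue  # zero-variance cumulative energy: not a valid candidate
            key = (_objective_value(r, objective), res)
            if best is None or key < best[0]:
                best = (key, res)
        if best is None:
            raise DomainError("no residue yields a defined correlation at this step")
        current.add(best[1])
    return cluster_correlation(E, current, A)
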