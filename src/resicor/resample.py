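"""Significance, confidence intervals and cross-validation for cluster scores.

The published analysis reports correlations without significance or
validation statistics; this module supplies the standard machinery:

* permutation test of the cluster correlation (activity labels shuffled),
  with the smoothed estimator p = (#{extreme} + 1) / (n_perm + 1), so p is
  never exactly 0;
* percentile bootstrap CI over compound-level resamples;
* leave-one-out cross-validation of the univariate line pIC50 ~ cumulative
  energy, summarized as q2 = 1 - PRESS/SS_tot and RMSE.

Every stochastic operation is fully determined by (inputs, config.seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import ActivityTable, EnergyMatrix
from .correlation import _align, cluster_sum, pearson, pearson_against_rows
from .errors import DomainError
from .residues import ResidueID

logger = logging.getLogger("resicor")

ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class ResampleConfig:
    """Settings for the permutation test and bootstrap.

    n_perm / n_boot:
        Number of label permutations / bootstrap resamples (>= 1; >= 99
        recommended for the permutation test).
    seed:
        PRNG seed (numpy default_rng); recorded in reports.
    alternative:
        "two_sided" (|r_perm| >= |r_obs|), "less" (r_perm <= r_obs) or
        "greater" (r_perm >= r_obs).
    ci_level:
        Bootstrap CI coverage.
    """

    n_perm: int = 999
    n_boot: int = 999
    seed: int = 0
    alternative: str = "two_sided"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1:
            raise DomainError("n_perm and n_boot must be >= 1")
        if self.alternative not in ALTERNATIVES:
            raise DomainError(f"alternative must be one of {ALTERNATIVES}")
        if not (0 < self.ci_level < 1):
            raise DomainError("ci_level must be in (0, 1)")


def permutation_pvalue(
    E: EnergyMatrix,
    residues: Iterable[ResidueID],
    A: ActivityTable,
    config: ResampleConfig = ResampleConfig(),
) -> float:
    """Permutation p-value for the cluster's cumulative-energy correlation.

    Activity labels are permuted ``n_perm`` times; by the +1/(n_perm+1)
    smoothing the result is always >= 1/(n_perm + 1).
    """
    sums = cluster_sum(E, residues).to_numpy()
    y = _align(E, A)
    r_obs = pearson(sums, y)
    rng = np.random.default_rng(config.seed)
    perms = rng.permuted(np.tile(y, (config.n_perm, 1)), axis=1)
    r_perm = pearson_against_rows(sums, perms)
    r_perm = r_perm[~np.isnan(r_perm)]  # degenerate permutations carry no evidence
    if config.alternative == "two_sided":
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-15))
    elif config.alternative == "less":
        count = int(np.sum(r_perm <= r_obs + 1e-15))
    else:
        count = int(np.sum(r_perm >= r_obs - 1e-15))
    return (count + 1) / (config.n_perm + 1)


def bootstrap_ci(
    E: EnergyMatrix,
    residues: Iterable[ResidueID],
    A: ActivityTable,
    config: ResampleConfig = ResampleConfig(),
) -> tuple[float, float]:
    """Percentile bootstrap CI of the cluster correlation.

    Compounds are resampled with replacement; resamples in which either
    vector is constant have no defined correlation and are redrawn (the count
    is logged).
    """
    sums = cluster_sum(E, residues).to_numpy()
    y = _align(E, A)
    n = len(y)
    if n < 4:
        raise DomainError(f"bootstrap needs at least 4 compounds, got {n}")
    rng = np.random.default_rng(config.seed)
    stats = np.empty(config.n_boot)
    redraws = 0
    for b in range(config.n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            xs, ys = sums[idx], y[idx]
            if np.ptp(xs) > 0 and np.ptp(ys) > 0:
                break
            redraws += 1
            if redraws > 1000 * config.n_boot:
                raise DomainError("bootstrap cannot find non-degenerate resamples")
        stats[b] = pearson(xs, ys)
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    alpha = 1.0 - config.ci_level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class LooCvResult:
    """Leave-one-out predictions and summary statistics."""

    predictions: pd.Series
    q2: float
    rmse: float


def loo_cv(
    E: EnergyMatrix, residues: Iterable[ResidueID], A: ActivityTable
) -> LooCvResult:
    """Leave-one-out CV of the line pIC50 ~ cluster cumulative energy.

    For each held-out compound a univariate least-squares line is fitted on
    the remaining compounds and used to predict the held-out activity.
    q2 = 1 - PRESS / SS_tot (SS_tot about the overall activity mean);
    q2 <= 0 means no predictive value.
    """
    from .estimators import ClusterEnergyRegressor

    sums = cluster_sum(E, residues)
    y = _align(E, A)
    n = len(y)
    if n < 4:
        raise DomainError(f"leave-one-out CV needs at least 4 compounds, got {n}")
    X = sums.to_numpy().reshape(-1, 1)
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        if np.ptp(X[mask, 0]) == 0:
            raise DomainError("training fold has zero variance in cumulative energy")
        model = ClusterEnergyRegressor().fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
    press = float(np.sum((preds - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("activity vector has zero variance")
    q2 = 1.0 - press / ss_tot
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return LooCvResult(
        predictions=pd.Series(preds, index=list(E.compounds), name="pIC50_pred"),
        q2=q2,
        rmse=rmse,
    )
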