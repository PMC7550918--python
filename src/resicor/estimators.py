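"""scikit-learn estimators wrapping the correlation core.

Two fit-shaped views of the analysis:

* :class:`ResidueCorrelationSelector` — univariate feature selection keeping
  the residues whose energy correlates with activity with a chosen sign.
* :class:`ClusterEnergyRegressor` — predicts pIC50 from the cluster's
  cumulative energy via a univariate least-squares line.

Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with ``Pipeline`` and the
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .correlation import MIN_COMPOUNDS, columnwise_pearson
from .errors import DomainError

from scipy import stats


class ResidueCorrelationSelector(SelectorMixin, BaseEstimator):
    """Select features (residues) by the sign of their correlation with y.

    Parameters
    ----------
    sign : {"negative", "positive"}
        Which correlation sign to keep. With the convention that negative
        energy is favorable binding, ``"negative"`` keeps residues whose more
        favorable contributions track higher potency.
    strict_zero : bool, default True
        When True, r == 0 is excluded from both signs.
    method : {"pearson", "spearman"}

    Attributes
    ----------
    correlations_ : ndarray of shape (n_features,)
        Per-feature correlation with y (NaN where undefined).
    undefined_ : ndarray of bool
        Zero-variance features; never selected.
    support_ : ndarray of bool
        Mask of selected features.
    """

    def __init__(self, sign: str = "negative", strict_zero: bool = True, method: str = "pearson"):
        self.sign = sign
        self.strict_zero = strict_zero
        self.method = method

    def fit(self, X, y):
        if self.sign not in {"negative", "positive"}:
            raise DomainError(f"sign must be 'negative' or 'positive', got {self.sign!r}")
        X, y = validate_data(self, X, y, ensure_min_samples=MIN_COMPOUNDS, y_numeric=True)
        if np.ptp(y) == 0:
            raise DomainError("activity vector has zero variance")
        if self.method == "pearson":
            r, undefined = columnwise_pearson(X, y)
        elif self.method == "spearman":
            undefined = np.ptp(X, axis=0) == 0
            r = np.full(X.shape[1], np.nan)
            for j in np.flatnonzero(~undefined):
                r[j] = stats.spearmanr(X[:, j], y).statistic
        else:
            raise DomainError(f"unknown correlation method {self.method!r}")
        self.correlations_ = r
        self.undefined_ = undefined
        with np.errstate(invalid="ignore"):
            if self.sign == "negative":
                mask = (r < 0) if self.strict_zero else (r <= 0)
            else:
                mask = (r > 0) if self.strict_zero else (r >= 0)
        mask = mask & ~undefined & ~np.isnan(r)
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class ClusterEnergyRegressor(RegressorMixin, BaseEstimator):
    """Univariate least-squares of activity on the cluster cumulative energy.

    The design score is the row sum of the selected columns (the cluster's
    cumulative binding energy); a single slope and intercept are fitted.

    Parameters
    ----------
    columns : sequence of column labels or indices, optional
        Cluster members. With a DataFrame X, labels (e.g. ``"TYR341"``);
        otherwise integer indices. None means all columns.
    """

    def __init__(self, columns=None):
        self.columns = columns

    def _scores(self, X) -> np.ndarray:
        if self.columns is None:
            idx = np.arange(X.shape[1])
        elif all(isinstance(c, (int, np.integer)) for c in self.columns):
            idx = np.asarray(self.columns, dtype=int)
        else:
            names = list(getattr(self, "feature_names_in_", []))
            if not names:
                raise DomainError("column labels require a DataFrame input with named columns")
            missing = [str(c) for c in self.columns if str(c) not in names]
            if missing:
                raise DomainError(f"unknown columns: {missing}")
            idx = np.asarray([names.index(str(c)) for c in self.columns], dtype=int)
        if idx.size == 0:
            raise DomainError("cluster must contain at least one column")
        return X[:, idx].sum(axis=1)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=MIN_COMPOUNDS, y_numeric=True)
        s = self._scores(X)
        if np.ptp(s) == 0:
            raise DomainError("cluster cumulative energy has zero variance")
        slope, intercept = np.polyfit(s, y, 1)
        self.coef_ = np.array([slope])
        self.intercept_ = float(intercept)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.coef_[0] * self._scores(X) + self.intercept_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
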