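"""Descriptor-based 2D-QSAR baselines.

Pipeline order is fixed: variance filter (threshold 0.01, pre-standardization
variance) -> standardize to zero mean / unit variance -> Lasso feature
selection (L1 penalty chosen by internal 5-fold CV) -> RF or SVR fit at the
stated hyperparameters. PCA projection is a diagnostic, not a modeling step.
All transforms are fit on training data and reapplied to new compounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import VarianceThreshold
from sklearn.linear_model import Lasso, LassoCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .training import RegressionMetrics, pearson_r, r_squared, rmse

logger = logging.getLogger(__name__)

RF_PARAMS = {"n_estimators": 225, "max_features": None,
             "min_samples_split": 2, "random_state": 2}
SVR_PARAMS = {"kernel": "rbf", "tol": 0.0017, "epsilon": 0.1}
# The reference SVR run logs random_state=55; sklearn's deterministic SMO
# solver ignores it, so it is recorded for fidelity only.
SVR_RANDOM_STATE = 55


class EmptySelectionError(ValueError):
    """Feature selection removed every descriptor."""


@dataclass
class DescriptorTable:
    """Compounds x numeric molecular descriptors, with pIC50 labels."""

    ids: list[str]
    names: list[str]
    values: np.ndarray                 # (n_compounds, n_descriptors)
    labels: np.ndarray | None = None   # pIC50 per compound

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   labels: pd.Series | np.ndarray | None = None) -> "DescriptorTable":
        """Ingest a descriptor frame, dropping (and logging) incomplete rows."""
        keep = frame.notna().all(axis=1)
        if labels is not None:
            labels = np.asarray(labels, dtype=np.float64)
            keep &= np.isfinite(labels)
        if (~keep).any():
            logger.info("dropping %d compounds with missing descriptors",
                        int((~keep).sum()))
        frame = frame.loc[keep]
        return cls(ids=[str(i) for i in frame.index],
                   names=[str(c) for c in frame.columns],
                   values=frame.to_numpy(dtype=np.float64),
                   labels=None if labels is None else labels[keep.to_numpy()])

    @classmethod
    def read_csv(cls, path, labels_column: str | None = None) -> "DescriptorTable":
        frame = pd.read_csv(path, index_col=0)
        labels = None
        if labels_column is not None:
            labels = frame.pop(labels_column)
        return cls.from_frame(frame, labels)

    def select(self, names: list[str]) -> "DescriptorTable":
        idx = [self.names.index(n) for n in names]
        return replace(self, names=list(names), values=self.values[:, idx])


def correlation_matrix(table: DescriptorTable) -> pd.DataFrame:
    """Pairwise Pearson r between descriptors; NaN flags zero-variance columns."""
    if table.values.shape[0] < 2:
        raise ValueError("need at least two compounds")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(table.values, rowvar=False)
    variances = table.values.var(axis=0)
    corr[variances == 0, :] = np.nan
    corr[:, variances == 0] = np.nan
    np.fill_diagonal(corr, np.where(variances == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=table.names, columns=table.names)


def variance_filter(table: DescriptorTable,
                    threshold: float = 0.01) -> DescriptorTable:
    """Keep descriptors whose (pre-standardization) variance exceeds threshold."""
    selector = VarianceThreshold(threshold=threshold)
    try:
        selector.fit(table.values)
    except ValueError as err:
        raise ValueError("variance filter removed every descriptor") from err
    mask = selector.get_support()
    if not mask.any():
        raise ValueError("variance filter removed every descriptor")
    return replace(table, names=[n for n, m in zip(table.names, mask) if m],
                   values=table.values[:, mask])


def standardize(table: DescriptorTable) -> tuple[DescriptorTable, StandardScaler]:
    """Scale each descriptor to mean 0 / variance 1; returns the fitted scaler."""
    if (table.values.var(axis=0) == 0).any():
        raise ValueError("zero-variance column present; run variance_filter first")
    scaler = StandardScaler()
    values = scaler.fit_transform(table.values)
    return replace(table, values=values), scaler


def lasso_select(table: DescriptorTable, labels: np.ndarray | None = None,
                 alpha: float | None = None, cv: int = 5,
                 random_state: int = 0) -> list[str]:
    """Descriptors with nonzero Lasso coefficients.

    The L1 penalty is chosen by internal ``cv``-fold cross-validation over a
    logarithmic grid unless ``alpha`` is given explicitly; among penalties
    within one standard error of the best cross-validated error, the largest
    (sparsest) is used — the usual one-standard-error rule.
    """
    y = np.asarray(table.labels if labels is None else labels, dtype=np.float64)
    if np.var(y) == 0:
        raise ValueError("labels are constant; Lasso selection is degenerate")
    if alpha is None:
        grid = np.logspace(-4, 1, 40)
        search = LassoCV(alphas=grid, cv=cv, random_state=random_state,
                         max_iter=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(table.values, y)
        mean_mse = search.mse_path_.mean(axis=1)
        se = search.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv)
        best = int(np.argmin(mean_mse))
        within = mean_mse <= mean_mse[best] + se[best]
        alpha = float(search.alphas_[within].max())
    model = Lasso(alpha=alpha, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(table.values, y)
    selected = [n for n, c in zip(table.names, model.coef_) if c != 0.0]
    if not selected:
        raise EmptySelectionError(
            "Lasso penalty shrank every coefficient to zero")
    return selected


def pca_project(table: DescriptorTable,
                n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores and explained-variance fractions."""
    rank = min(table.values.shape[0] - 1, table.values.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(table.values)
    return scores, pca.explained_variance_ratio_


def _fit_and_score(estimator, table: DescriptorTable, y: np.ndarray):
    estimator.fit(table.values, y)
    preds = estimator.predict(table.values)
    metrics = RegressionMetrics(rmse=rmse(preds, y),
                                r_squared=r_squared(preds, y),
                                pearson_r=pearson_r(preds, y), n=len(y))
    return estimator, metrics


def fit_rf(table: DescriptorTable, labels: np.ndarray | None = None,
           **overrides):
    """Random-forest regressor at the stated hyperparameters."""
    y = np.asarray(table.labels if labels is None else labels, dtype=np.float64)
    if len(y) < 10:
        raise ValueError("need at least 10 compounds")
    params = {**RF_PARAMS, **overrides}
    return _fit_and_score(RandomForestRegressor(**params), table, y)


def fit_svr(table: DescriptorTable, labels: np.ndarray | None = None,
            **overrides):
    """RBF-kernel support-vector regressor at the stated tolerances."""
    y = np.asarray(table.labels if labels is None else labels, dtype=np.float64)
    params = {**SVR_PARAMS, **overrides}
    params.pop("random_state", None)  # deterministic solver; logged only
    logger.debug("SVR random_state recorded as %d (no solver effect)",
                 SVR_RANDOM_STATE)
    return _fit_and_score(SVR(**params), table, y)
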