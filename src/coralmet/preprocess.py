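"""Internal-standard normalization, QC-based CV filtering and scaling.

Scaling follows chemometrics convention: unit-variance (autoscaling,
column divided by its standard deviation) ahead of PCA, Pareto (divided by
the square root of the standard deviation) ahead of OPLS-DA. Standard
deviations use the n-1 denominator throughout, appropriate for the small
sample and QC counts of a typical study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import FeatureTable

__all__ = [
    "normalize_internal_standard",
    "qc_cv_filter",
    "VarianceScaler",
    "ScaledMatrix",
    "scale",
]


def normalize_internal_standard(table: FeatureTable, is_id: str) -> FeatureTable:
    """Divide every sample's intensities by that sample's internal-standard signal.

    The internal-standard feature itself becomes exactly 1 in every sample,
    making the operation idempotent. Raises if the standard is missing or
    non-positive in any sample (naming the sample).
    """
    if is_id not in table.intensities.index:
        raise ValueError(f"internal standard {is_id!r} not in table")
    is_row = table.intensities.loc[is_id]
    bad = list(is_row.index[~(is_row > 0)])
    if bad:
        raise ValueError(
            f"internal standard {is_id!r} is zero or missing in samples: {bad}"
        )
    out = table.copy()
    out.intensities = table.intensities.div(is_row, axis=1)
    return out


def qc_cv_filter(
    table: FeatureTable, max_cv: float = 0.30
) -> tuple[FeatureTable, list[str]]:
    """Keep features whose coefficient of variation across pooled-QC
    injections is below ``max_cv``; return (filtered table, removed ids).

    CV = sample SD (n-1) / mean over the QC columns. Features absent from
    every QC injection are removed.
    """
    qc_samples = table.samples_in_group("QC")
    if len(qc_samples) < 2:
        raise ValueError("QC CV filter needs at least two QC samples")
    qc = table.intensities[qc_samples]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = (mean > 0) & (cv < max_cv)
    removed = [fid for fid in table.feature_ids if not keep.loc[fid]]
    kept = [fid for fid in table.feature_ids if keep.loc[fid]]
    return table.subset_features(kept), removed


@dataclass
class ScaledMatrix:
    """A sample x feature matrix after column centering and scaling."""

    values: np.ndarray
    scaling: str  # unit_variance | pareto | none
    column_means: np.ndarray
    column_scales: np.ndarray
    constant_columns: np.ndarray  # boolean mask of zero-variance columns
    feature_ids: list[str] | None = None


class VarianceScaler(TransformerMixin, BaseEstimator):
    """Column center-and-scale transformer with chemometrics schemes.

    Parameters
    ----------
    scheme:
        ``"unit_variance"`` divides centered columns by their SD,
        ``"pareto"`` by the square root of the SD, ``"none"`` only centers.
    Constant columns are set to zero after centering and flagged in
    ``constant_columns_``.
    """

    def __init__(self, scheme: str = "unit_variance"):
        self.scheme = scheme

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        if self.scheme not in ("unit_variance", "pareto", "none"):
            raise ValueError(f"unknown scaling scheme {self.scheme!r}")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.constant_columns_ = sd == 0
        if self.scheme == "unit_variance":
            scale_ = sd.copy()
        elif self.scheme == "pareto":
            scale_ = np.sqrt(sd)
        else:
            scale_ = np.ones_like(sd)
        scale_[self.constant_columns_] = 1.0  # centered constants are already 0
        self.scale_ = scale_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = np.asarray(X, dtype=float)
        out = (X - self.mean_) / self.scale_
        out[:, self.constant_columns_] = 0.0
        return out


def scale(
    matrix: pd.DataFrame | np.ndarray, scheme: str = "unit_variance"
) -> ScaledMatrix:
    """Center and scale a sample x feature matrix (thin wrapper over
    :class:`VarianceScaler`)."""
    feature_ids = None
    if isinstance(matrix, pd.DataFrame):
        feature_ids = list(matrix.columns)
        matrix = matrix.to_numpy(float)
    scaler = VarianceScaler(scheme=scheme).fit(matrix)
    return ScaledMatrix(
        values=scaler.transform(matrix),
        scaling=scheme,
        column_means=scaler.mean_,
        column_scales=scaler.scale_,
        constant_columns=scaler.constant_columns_,
        feature_ids=feature_ids,
    )


def log_intensities(X: np.ndarray) -> np.ndarray:
    """Natural-log transform with a half-minimum-positive offset for zeros.

    Untargeted intensity data is multiplicative (log-normal-like) and spans
    orders of magnitude; log transformation before scaling keeps
    low-abundance features from being drowned out in multivariate models.
    """
    X = np.asarray(X, float)
    pos = X[X > 0]
    offset = (pos.min() / 2.0) if pos.size else 1.0
    return np.log(X + offset)


def analysis_matrix(table: FeatureTable) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample x feature matrix restricted to the two analysis groups,
    plus the binary group labels (0 for A, 1 for B)."""
    samples = table.samples_in_group("A") + table.samples_in_group("B")
    if not samples:
        raise ValueError("no analysis samples (groups A/B) in table")
    X = table.intensities[samples].T
    y = np.asarray([0 if table.sample_group[s] == "A" else 1 for s in samples])
    return X, y
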