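"""Preprocessing of the feature table and the matched-pair fold-change matrix.

The chain mirrors standard quantitative-lipidomics practice for data with
detection-limit censoring:

1. missing values and negative readings are zeroed;
2. zeros are replaced by half the smallest positive observed value of the
   feature (half-minimum imputation, a left-censoring surrogate);
3. values are log2 transformed;
4. each feature is autoscaled to zero mean, unit variance over *all*
   samples jointly (patients and controls).

The association substrate is then the **fold-change matrix**: one row per
matched patient-control pair, entries = patient minus control of the log2,
autoscaled values.

Steps 2-4 are exposed both as scikit-learn transformers (stateful ``fit`` on
a reference cohort, reusable ``transform``) and as one-shot functions on
:class:`~nrrnet.io.FeatureTable`, which is what the pipeline uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import FeatureTable, SampleMetadata, ValidationError, validate_pairing

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ScaledTable:
    """Autoscaled table: per feature, mean 0 and SD 1 over all samples."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class FoldChangeMatrix:
    """Pairs x features matrix of patient-minus-matched-control differences."""

    pair_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pair_ids, columns=self.feature_ids)


# ---------------------------------------------------------------------------
# scikit-learn transformers


class NonNegativeCleaner(TransformerMixin, BaseEstimator):
    """Replace missing and negative cells with exactly zero (stateless)."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_all_finite="allow-nan", copy=True)
        X[~np.isfinite(X)] = 0.0
        X[X < 0] = 0.0
        return X


class HalfMinimumImputer(TransformerMixin, BaseEstimator):
    """Replace zeros with half the feature's minimum positive value.

    Features with no positive value at all carry no information and are
    dropped (their indices are recorded in ``dropped_features_``).
    Input must already be cleaned: finite and non-negative.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        if (X < 0).any():
            raise ValidationError("half-minimum imputation requires a cleaned (non-negative) table")
        self.n_features_in_ = X.shape[1]
        with np.errstate(invalid="ignore"):
            pos_min = np.where(X > 0, X, np.inf).min(axis=0)
        self.keep_mask_ = np.isfinite(pos_min)
        self.dropped_features_ = np.flatnonzero(~self.keep_mask_)
        self.half_minimums_ = 0.5 * pos_min[self.keep_mask_]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, copy=True)
        X = X[:, self.keep_mask_]
        zero = X == 0
        X[zero] = np.broadcast_to(self.half_minimums_, X.shape)[zero]
        return X


class Log2Autoscaler(TransformerMixin, BaseEstimator):
    """Log2-transform then standardize each feature to mean 0, SD 1.

    Parameters
    ----------
    ddof : int
        Delta degrees of freedom of the SD. 1 (sample SD, the convention of
        R's ``scale()``) by default; the choice rescales columns uniformly
        and does not affect any correlation computed downstream.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = check_array(X)
        if (X <= 0).any():
            raise ValidationError("log2 autoscaling requires strictly positive values")
        L = np.log2(X)
        self.n_features_in_ = X.shape[1]
        mean = L.mean(axis=0)
        sd = L.std(axis=0, ddof=self.ddof)
        self.keep_mask_ = sd > 0
        self.dropped_features_ = np.flatnonzero(~self.keep_mask_)
        self.log2_means_ = mean[self.keep_mask_]
        self.log2_sds_ = sd[self.keep_mask_]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if (X <= 0).any():
            raise ValidationError("log2 autoscaling requires strictly positive values")
        L = np.log2(X[:, self.keep_mask_])
        return (L - self.log2_means_) / self.log2_sds_


# ---------------------------------------------------------------------------
# one-shot functional chain on FeatureTable


def clean_nonpositive(table: FeatureTable) -> FeatureTable:
    """Step 1: zero out missing and negative cells; everything else unchanged."""
    values = table.values.copy()
    values[~np.isfinite(values)] = 0.0
    values[values < 0] = 0.0
    return FeatureTable(list(table.sample_ids), list(table.feature_ids), values)


def impute_half_minimum(table: FeatureTable) -> FeatureTable:
    """Step 2: per feature, replace zeros by half the minimum positive value.

    All-zero features are dropped with a logged warning: they have no
    observed signal, so no imputation value exists for them.
    """
    if np.isnan(table.values).any():
        raise ValidationError("table has missing values; run clean_nonpositive first")
    imp = HalfMinimumImputer().fit(table.values)
    if imp.dropped_features_.size:
        dropped = [table.feature_ids[i] for i in imp.dropped_features_]
        logger.warning("dropping %d all-zero feature(s): %s", len(dropped), dropped)
    kept = [f for f, k in zip(table.feature_ids, imp.keep_mask_) if k]
    return FeatureTable(list(table.sample_ids), kept, imp.transform(table.values))


def log2_autoscale(table: FeatureTable, ddof: int = 1) -> ScaledTable:
    """Steps 3-4: log2 transform, then autoscale each feature to mean 0 / SD 1.

    Scaling is computed over all samples jointly (patients and controls),
    before pairing. Zero-variance features are dropped with a warning.
    """
    scaler = Log2Autoscaler(ddof=ddof).fit(table.values)
    if scaler.dropped_features_.size:
        dropped = [table.feature_ids[i] for i in scaler.dropped_features_]
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped)
    kept = [f for f, k in zip(table.feature_ids, scaler.keep_mask_) if k]
    return ScaledTable(list(table.sample_ids), kept, scaler.transform(table.values))


def paired_fold_change(
    scaled: ScaledTable, metadata: Sequence[SampleMetadata]
) -> FoldChangeMatrix:
    """Patient minus matched control, one row per complete pair."""
    pairs = validate_pairing(metadata)
    index = {s: i for i, s in enumerate(scaled.sample_ids)}
    missing = [
        s for pat, ctl in pairs.values() for s in (pat, ctl) if s not in index
    ]
    if missing:
        raise ValidationError(f"paired samples absent from scaled table: {sorted(missing)}")
    pair_ids = list(pairs)
    rows = np.stack(
        [scaled.values[index[pat]] - scaled.values[index[ctl]] for pat, ctl in pairs.values()]
    )
    return FoldChangeMatrix(pair_ids, list(scaled.feature_ids), rows)


def preprocess_table(
    table: FeatureTable, metadata: Sequence[SampleMetadata], ddof: int = 1
) -> tuple[ScaledTable, FoldChangeMatrix]:
    """Run the full chain clean -> impute -> log2+autoscale -> fold change."""
    scaled = log2_autoscale(impute_half_minimum(clean_nonpositive(table)), ddof=ddof)
    return scaled, paired_fold_change(scaled, metadata)
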