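"""Normalization and batch correction of gene-level matrices.

Three transformers with strict fit/apply (train/test) semantics so that
cross-validation folds never leak held-out information into fitted
parameters:

* :class:`StratumMinMaxScaler` — min-max scaling to [0, 1], with the min and
  max taken globally over all values of a {dataset x layer} stratum.
* :class:`DNAmMeanImputer` — per-gene training-mean imputation of missing
  methylation values (missingness outside the DNAm layer is an error).
* :class:`RankInverseNormal` — per-dataset, per-gene rank inverse normal
  transform (INT): ranks (average for ties) -> percentiles r/(n+1) ->
  standard normal quantiles. Held-out rows are mapped through the *training*
  empirical CDF by linear interpolation, clipped to [1/(n+1), n/(n+1)].

All three follow the scikit-learn estimator protocol (``fit``/``transform``,
``get_params``; fitted state in trailing-underscore attributes), with the
grouping labels passed as keyword metadata. :class:`FoldNormalizer` chains
imputation and INT as fitted inside each clock fold; thin functional wrappers
(:func:`minmax_fit` ... :func:`int_apply`) expose the same operations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .gene_matrix import GeneMatrix, concat_matrices


def _as_frame(X) -> pd.DataFrame:
    return X.values if isinstance(X, GeneMatrix) else pd.DataFrame(X)


def _strata_of(X, strata) -> pd.Series:
    if strata is None:
        if isinstance(X, GeneMatrix):
            return X.strata()
        raise ValueError("strata labels required when X is not a GeneMatrix")
    return pd.Series(list(strata), index=_as_frame(X).index)


class StratumMinMaxScaler(BaseEstimator, TransformerMixin):
    """Scale each {dataset x layer} stratum to [0, 1] by its global min/max.

    The range is computed over *all* values of the stratum (not per gene);
    applied values are clipped to [0, 1] and a constant stratum maps to 0.
    Applying to a stratum that was never fitted raises ``KeyError``.
    """

    def fit(self, X, y=None, *, strata=None):
        frame = _as_frame(X)
        labels = _strata_of(X, strata)
        self.ranges_ = {}
        for stratum in labels.unique():
            block = frame.loc[(labels == stratum).to_numpy()].to_numpy(dtype=float)
            finite = block[np.isfinite(block)]
            if finite.size == 0:
                raise ValueError(f"stratum {stratum!r} has no finite values")
            self.ranges_[stratum] = (float(finite.min()), float(finite.max()))
        return self

    def transform(self, X, *, strata=None):
        frame = _as_frame(X).copy()
        labels = _strata_of(X, strata)
        for stratum in labels.unique():
            if stratum not in self.ranges_:
                raise KeyError(f"stratum {stratum!r} was not fitted")
            lo, hi = self.ranges_[stratum]
            mask = (labels == stratum).to_numpy()
            block = frame.loc[mask].to_numpy(dtype=float)
            if hi == lo:
                scaled = np.where(np.isnan(block), np.nan, 0.0)
            else:
                scaled = np.clip((block - lo) / (hi - lo), 0.0, 1.0)
            frame.loc[mask] = scaled
        if isinstance(X, GeneMatrix):
            return GeneMatrix(frame, X.samples.copy())
        return frame


class DNAmMeanImputer(BaseEstimator, TransformerMixin):
    """Impute missing DNAm values with the per-gene mean of the training rows.

    Only rows of ``layer`` (default DNAm) are imputed; a missing value in any
    other layer raises, as does a gene whose training DNAm values are all
    missing (no mean can be fitted) when that mean is needed.
    """

    def __init__(self, layer: str = "DNAm"):
        self.layer = layer

    def _layer_mask(self, X, layers):
        if layers is None:
            if isinstance(X, GeneMatrix):
                layers = X.samples["layer"]
            else:
                raise ValueError("layer labels required when X is not a GeneMatrix")
        return (pd.Series(list(layers), index=_as_frame(X).index) == self.layer).to_numpy()

    def fit(self, X, y=None, *, layers=None):
        frame = _as_frame(X)
        mask = self._layer_mask(X, layers)
        block = frame.loc[mask]
        if len(block):
            self.means_ = block.mean(axis=0, skipna=True)
            unfittable = block.isna().all(axis=0)
            if unfittable.any() and block[block.columns[unfittable]].isna().any(axis=None):
                bad = block.columns[unfittable].tolist()
                raise ValueError(f"cannot fit imputation mean: all-missing gene column(s) {bad[:5]}")
        else:
            self.means_ = pd.Series(dtype=float)
        return self

    def transform(self, X, *, layers=None):
        frame = _as_frame(X).copy()
        mask = self._layer_mask(X, layers)
        other = frame.loc[~mask]
        if other.isna().any(axis=None):
            raise ValueError(f"missing values outside the {self.layer} layer")
        block = frame.loc[mask]
        if block.isna().any(axis=None):
            needed = block.columns[block.isna().any(axis=0)]
            no_mean = [g for g in needed if g not in self.means_.index or np.isnan(self.means_[g])]
            if no_mean:
                raise ValueError(f"no fitted imputation mean for gene(s) {no_mean[:5]}")
            frame.loc[mask] = block.fillna(self.means_)
        if isinstance(X, GeneMatrix):
            return GeneMatrix(frame, X.samples.copy())
        return frame


def _int_percentiles_fit(col: np.ndarray) -> np.ndarray:
    """Exact training percentiles: average ranks r over n samples -> r/(n+1)."""
    n = len(col)
    return rankdata(col, method="average") / (n + 1)


def _int_percentiles_apply(x: np.ndarray, train_sorted: np.ndarray) -> np.ndarray:
    """Percentiles of new values under the training empirical CDF.

    Linear interpolation between the unique training values' average-rank
    percentiles, so an exact training value reproduces its fit-time
    percentile; results are clipped to [1/(n+1), n/(n+1)].
    """
    n = len(train_sorted)
    uniq, counts = np.unique(train_sorted, return_counts=True)
    upper = np.cumsum(counts)
    avg_rank = upper - (counts - 1) / 2.0
    pct = np.interp(x, uniq, avg_rank / (n + 1))
    return np.clip(pct, 1.0 / (n + 1), n / (n + 1))


class RankInverseNormal(BaseEstimator, TransformerMixin):
    """Per-dataset per-gene rank inverse normal transform.

    ``fit_transform`` on the training rows applies the exact-rank formula
    ``z = Phi^-1(rank / (n + 1))`` (ties receive average ranks, matching the
    Spearman convention used downstream); ``transform`` maps held-out rows
    through the stored training quantile tables. Requires >= 2 training
    samples per dataset; a gene absent from the fitted table raises at apply
    time.
    """

    def fit(self, X, y=None, *, datasets=None):
        frame = _as_frame(X)
        labels = self._labels(X, datasets)
        self.tables_ = {}
        for ds in labels.unique():
            block = frame.loc[(labels == ds).to_numpy()].to_numpy(dtype=float)
            if block.shape[0] < 2:
                raise ValueError(f"dataset {ds!r} has < 2 training samples; cannot fit INT")
            if np.isnan(block).any():
                raise ValueError(f"dataset {ds!r} contains missing values; impute before INT")
            self.tables_[ds] = (frame.columns.copy(), np.sort(block, axis=0))
        return self

    @staticmethod
    def _labels(X, datasets) -> pd.Series:
        if datasets is None:
            if isinstance(X, GeneMatrix):
                return X.samples["dataset"]
            raise ValueError("dataset labels required when X is not a GeneMatrix")
        return pd.Series(list(datasets), index=_as_frame(X).index)

    def transform(self, X, *, datasets=None):
        frame = _as_frame(X).copy()
        labels = self._labels(X, datasets)
        for ds in labels.unique():
            if ds not in self.tables_:
                raise KeyError(f"dataset {ds!r} was not fitted")
            genes, table = self.tables_[ds]
            missing = [g for g in frame.columns if g not in set(genes)]
            if missing:
                raise KeyError(f"gene(s) absent from fitted INT parameters: {missing[:5]}")
            col_idx = pd.Index(genes).get_indexer(frame.columns)
            mask = (labels == ds).to_numpy()
            block = frame.loc[mask].to_numpy(dtype=float)
            out = np.empty_like(block)
            for j in range(block.shape[1]):
                out[:, j] = _int_percentiles_apply(block[:, j], table[:, col_idx[j]])
            frame.loc[mask] = norm.ppf(out)
        if isinstance(X, GeneMatrix):
            return GeneMatrix(frame, X.samples.copy())
        return frame

    def fit_transform(self, X, y=None, *, datasets=None):
        self.fit(X, datasets=datasets)
        frame = _as_frame(X).copy()
        labels = self._labels(X, datasets)
        for ds in labels.unique():
            mask = (labels == ds).to_numpy()
            block = frame.loc[mask].to_numpy(dtype=float)
            pct = np.apply_along_axis(_int_percentiles_fit, 0, block)
            frame.loc[mask] = norm.ppf(pct)
        if isinstance(X, GeneMatrix):
            return GeneMatrix(frame, X.samples.copy())
        return frame


class FoldNormalizer(BaseEstimator, TransformerMixin):
    """Imputation + INT as fitted inside one cross-validation fold.

    Min-max scaling happens once, globally, before fold construction; the
    leakage-sensitive steps (mean imputation, INT) are fitted on the fold's
    training rows only and applied to its held-out rows.
    """

    def __init__(self, impute_layer: str = "DNAm"):
        self.impute_layer = impute_layer

    def fit(self, X: GeneMatrix, y=None):
        self.imputer_ = DNAmMeanImputer(layer=self.impute_layer).fit(X)
        self.int_ = RankInverseNormal().fit(self.imputer_.transform(X))
        return self

    def transform(self, X: GeneMatrix) -> GeneMatrix:
        return self.int_.transform(self.imputer_.transform(X))

    def fit_transform(self, X: GeneMatrix, y=None) -> GeneMatrix:
        self.imputer_ = DNAmMeanImputer(layer=self.impute_layer).fit(X)
        imputed = self.imputer_.transform(X)
        self.int_ = RankInverseNormal()
        return self.int_.fit_transform(imputed)


def combine_layers(matrices: list[GeneMatrix]) -> GeneMatrix:
    """Row-concatenate per-{dataset x layer} matrices, keeping only genes
    whose values are present (non-missing) in every sample of every block."""
    combined = concat_matrices(matrices)
    present = combined.values.notna().all(axis=0)
    if not present.any():
        warnings.warn("no gene is present in all samples; combined matrix is empty")
    return GeneMatrix(combined.values.loc[:, present], combined.samples)


# -- functional wrappers -----------------------------------------------------

def minmax_fit(matrix: GeneMatrix, strata=None) -> StratumMinMaxScaler:
    return StratumMinMaxScaler().fit(matrix, strata=strata)


def minmax_apply(params: StratumMinMaxScaler, matrix: GeneMatrix, strata=None) -> GeneMatrix:
    return params.transform(matrix, strata=strata)


def impute_mean(matrix: GeneMatrix, layer: str = "DNAm") -> GeneMatrix:
    return DNAmMeanImputer(layer=layer).fit(matrix).transform(matrix)


def int_fit(matrix: GeneMatrix, datasets=None) -> RankInverseNormal:
    return RankInverseNormal().fit(matrix, datasets=datasets)


def int_apply(params: RankInverseNormal, matrix: GeneMatrix, datasets=None) -> GeneMatrix:
    return params.transform(matrix, datasets=datasets)
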