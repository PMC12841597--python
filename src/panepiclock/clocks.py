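"""Epigenetic age clocks: dataset filtering, donor-grouped folds, feature
selection, training, prediction and the cross-layer experiments.

A clock is a gradient-boosted decision-tree regressor (XGBoost with its
default hyper-parameters, frozen here as an explicit contract: 100 boosting
rounds, maximum depth 6, learning rate 0.3, squared-error loss) predicting
*scaled* age — the lifespan-relative -log(-log(.)) transform — from
gene-level epigenetic features. Single-layer clocks see profiles of one
epigenetic layer; the pan-epigenetic clock is the same architecture trained
jointly on profiles from all five clock layers.

Cross-validation is donor-grouped and age-stratified: all profiles of a
donor share one fold, and the number of profiles from donors of each age
quintile is balanced across folds. Inside each fold, mean imputation and the
inverse normal transform are fitted on the training rows only, and features
are kept when their Spearman association with age exceeds |rho| > 0.2 in
both species with the same sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from xgboost import XGBRegressor

from .age_scale import LifespanRegistry, scale_ages_by_species, unscale_ages_by_species
from .age_stats import spearman_with_p
from .gene_matrix import GeneMatrix
from .harmonize import FoldNormalizer

#: Layers entering clock construction; H3K36me3 and H3K9me3 are omitted for
#: their sparse mouse coverage.
CLOCK_LAYERS = ["DNAm", "H3K4me3", "H3K27ac", "H3K27me3", "H3K4me1"]
NON_CLOCK_LAYERS = ["H3K36me3", "H3K9me3"]

#: Cell-line and sex-specific/placental tissue labels excluded from clocks.
DEFAULT_EXCLUDED_TISSUES = [
    "prostate", "breast", "ovary", "testis", "uterus", "placenta", "cell_line",
]


@dataclass
class ClockConfig:
    """Training contract for single-layer and pan-epigenetic clocks."""

    mode: str = "pan"                       # "pan" or "single"
    layers: tuple = tuple(CLOCK_LAYERS)
    n_folds: int = 10
    n_estimators: int = 100
    max_depth: int = 6
    learning_rate: float = 0.3
    feature_rho_threshold: float = 0.2
    feature_selection: str = "pooled"       # or "union" (per-layer union)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("pan", "single"):
            raise ValueError("mode must be 'pan' or 'single'")
        if not self.layers:
            raise ValueError("layers must be non-empty")
        if self.feature_rho_threshold < 0:
            raise ValueError("feature_rho_threshold must be >= 0")
        if self.feature_selection not in ("pooled", "union"):
            raise ValueError("feature_selection must be 'pooled' or 'union'")


# ---------------------------------------------------------------------------
# dataset filtering
# ---------------------------------------------------------------------------

def filter_clock_dataset(matrix: GeneMatrix, min_libraries: int = 50,
                         excluded_tissues=tuple(DEFAULT_EXCLUDED_TISSUES),
                         excluded_layers=tuple(NON_CLOCK_LAYERS),
                         ) -> tuple[GeneMatrix, GeneMatrix]:
    """Apply the clock dataset filters.

    Drops excluded tissues (cell lines, sex-specific tissues, placenta),
    tissues represented by fewer than ``min_libraries`` libraries, and the
    non-clock layers; calorically restricted samples are moved to the second
    (withheld) output, retained for inference but never for fitting.
    """
    s = matrix.samples
    keep = ~s["tissue"].isin(list(excluded_tissues))
    keep &= ~s["layer"].isin(list(excluded_layers))
    counts = s.loc[keep, "tissue"].value_counts()
    small = counts[counts < min_libraries].index
    keep &= ~s["tissue"].isin(small)
    cr = keep & (s["diet"] == "CR")
    return matrix.subset((keep & ~cr).to_numpy()), matrix.subset(cr.to_numpy())


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(samples: pd.DataFrame, n_folds: int = 10, seed: int = 0,
               registry: LifespanRegistry | None = None) -> dict[str, int]:
    """Donor-grouped, age-quintile-balanced fold assignment.

    Donors are binned into quintiles of donor scaled age; within each
    quintile, donors are taken in decreasing order of profile count (ties
    shuffled by ``seed``) and assigned greedily to the fold currently
    holding the fewest profiles (ties to the lowest fold index). All
    profiles of a donor land in one fold.
    """
    donors = samples.groupby("donor_id").agg(
        n_profiles=("donor_id", "size"),
        age_years=("age_years", "mean"),
        species=("species", "first"),
    )
    if len(donors) < n_folds:
        raise ValueError(f"{len(donors)} donors cannot fill {n_folds} folds")
    scaled = scale_ages_by_species(donors["age_years"], donors["species"], registry)
    quintile = pd.qcut(pd.Series(scaled, index=donors.index), 5, labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    load = np.zeros(n_folds, dtype=int)
    assignment: dict[str, int] = {}
    for q in sorted(quintile.unique()):
        ids = quintile.index[quintile == q].to_numpy()
        tiebreak = rng.permutation(len(ids))
        order = sorted(range(len(ids)),
                       key=lambda i: (-donors.loc[ids[i], "n_profiles"], tiebreak[i]))
        for i in order:
            f = int(np.argmin(load))
            assignment[ids[i]] = f
            load[f] += donors.loc[ids[i], "n_profiles"]
    return assignment


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _gene_age_rho(values: pd.DataFrame, ages: np.ndarray) -> np.ndarray:
    X = values.to_numpy(dtype=float)
    age_rank = stats.rankdata(ages)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    ar = age_rank - age_rank.mean()
    gr = ranks - ranks.mean(axis=0)
    denom = np.sqrt((ar**2).sum()) * np.sqrt((gr**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom == 0, 0.0, (gr * ar[:, None]).sum(axis=0) / np.where(denom == 0, 1, denom))
    return np.clip(rho, -1.0, 1.0)


def _threshold_mask(matrix: GeneMatrix, threshold: float) -> np.ndarray:
    species = sorted(matrix.samples["species"].unique())
    rhos = []
    for sp in species:
        sub = matrix.select_species(sp)
        rhos.append(_gene_age_rho(sub.values, sub.samples["age_years"].to_numpy()))
    if len(species) == 1:
        warnings.warn("single-species training fold: feature threshold applied to one species")
        return np.abs(rhos[0]) > threshold
    r = np.vstack(rhos)
    return (np.abs(r) > threshold).all(axis=0) & (np.sign(r[0]) == np.sign(r[1]))


def select_features(matrix: GeneMatrix, threshold: float = 0.2,
                    mode: str = "pooled") -> list[str]:
    """Genes whose Spearman age association exceeds ``|rho| > threshold`` in
    both species with matching sign.

    ``mode='pooled'`` computes each species' rho over all training profiles
    of the layers being trained, pooled; ``mode='union'`` applies the filter
    within each layer separately and keeps the union of the per-layer
    selections. With a single-species training set the threshold applies to
    that species alone (a warning is emitted).
    """
    if mode == "pooled":
        keep = _threshold_mask(matrix, threshold)
    elif mode == "union":
        keep = np.zeros(len(matrix.genes), dtype=bool)
        for layer in sorted(matrix.samples["layer"].unique()):
            keep |= _threshold_mask(matrix.select_layers([layer]), threshold)
    else:
        raise ValueError(f"unknown feature-selection mode {mode!r}")
    features = matrix.genes[keep].tolist()
    if not features:
        raise ValueError(
            "no gene passed the feature threshold; reduce feature_rho_threshold"
        )
    return features


# ---------------------------------------------------------------------------
# the clock estimator
# ---------------------------------------------------------------------------

class EpigeneticClock(BaseEstimator, RegressorMixin):
    """One fold's clock: fold-fitted normalization, feature selection and a
    gradient-boosted regressor predicting scaled age.

    ``fit`` expects a min-max-scaled :class:`GeneMatrix` of training
    profiles; imputation and the inverse normal transform are fitted here so
    held-out rows passed to ``predict`` are mapped through training
    parameters only.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 6,
                 learning_rate: float = 0.3, feature_rho_threshold: float = 0.2,
                 feature_selection: str = "pooled", seed: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.feature_rho_threshold = feature_rho_threshold
        self.feature_selection = feature_selection
        self.seed = seed

    def fit(self, X: GeneMatrix, y=None, registry: LifespanRegistry | None = None):
        if y is None:
            y = scale_ages_by_species(X.samples["age_years"], X.samples["species"], registry)
        self.normalizer_ = FoldNormalizer()
        normalized = self.normalizer_.fit_transform(X)
        self.features_ = select_features(normalized, self.feature_rho_threshold,
                                         mode=self.feature_selection)
        self.layers_ = sorted(X.samples["layer"].unique())
        self.model_ = XGBRegressor(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, objective="reg:squarederror",
            random_state=self.seed, n_jobs=1,
        )
        self.model_.fit(normalized.values[self.features_].to_numpy(dtype=float), np.asarray(y))
        return self

    def predict(self, X: GeneMatrix) -> np.ndarray:
        """Predicted scaled ages for (held-out) profiles."""
        normalized = self.normalizer_.transform(X)
        return self.model_.predict(normalized.values[self.features_].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# cross-validated training / prediction
# ---------------------------------------------------------------------------

def _fold_series(samples: pd.DataFrame, folds: dict[str, int]) -> np.ndarray:
    return samples["donor_id"].map(folds).to_numpy()


def train_clock(matrix: GeneMatrix, config: ClockConfig, folds: dict[str, int],
                registry: LifespanRegistry | None = None) -> list[EpigeneticClock]:
    """Fit one :class:`EpigeneticClock` per fold on that fold's training
    profiles (min-max scaling is assumed done globally beforehand)."""
    fold_of = _fold_series(matrix.samples, folds)
    n_folds = int(np.max(fold_of)) + 1
    models = []
    for f in range(n_folds):
        train = matrix.subset(fold_of != f)
        clock = EpigeneticClock(
            n_estimators=config.n_estimators, max_depth=config.max_depth,
            learning_rate=config.learning_rate,
            feature_rho_threshold=config.feature_rho_threshold,
            feature_selection=config.feature_selection, seed=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            clock.fit(train, registry=registry)
        models.append(clock)
    return models


def _records_frame(samples: pd.DataFrame, fold: np.ndarray, predicted_scaled: np.ndarray,
                   registry: LifespanRegistry | None) -> pd.DataFrame:
    predicted_years = unscale_ages_by_species(predicted_scaled, samples["species"], registry)
    return pd.DataFrame({
        "sample_id": samples.index,
        "donor_id": samples["donor_id"].to_numpy(),
        "species": samples["species"].to_numpy(),
        "tissue": samples["tissue"].to_numpy(),
        "layer": samples["layer"].to_numpy(),
        "diet": samples["diet"].to_numpy(),
        "fold": fold,
        "predicted_scaled": predicted_scaled,
        "predicted_years": predicted_years,
        "actual_years": samples["age_years"].to_numpy(),
    }).reset_index(drop=True)


def predict_age(models: list[EpigeneticClock], matrix: GeneMatrix, folds: dict[str, int],
                withheld: GeneMatrix | None = None,
                registry: LifespanRegistry | None = None) -> pd.DataFrame:
    """Held-out predictions: each profile is predicted by the model of the
    fold its donor was held out from; withheld (e.g., calorically
    restricted) profiles are predicted by every fold's model and averaged."""
    fold_of = _fold_series(matrix.samples, folds)
    preds = np.full(matrix.n_samples, np.nan)
    for f, model in enumerate(models):
        mask = fold_of == f
        if mask.any():
            preds[mask] = model.predict(matrix.subset(mask))
    records = _records_frame(matrix.samples, fold_of, preds, registry)
    if withheld is not None and withheld.n_samples:
        stacked = np.vstack([m.predict(withheld) for m in models])
        wrec = _records_frame(withheld.samples, np.full(withheld.n_samples, -1),
                              stacked.mean(axis=0), registry)
        records = pd.concat([records, wrec], ignore_index=True)
    return records


def cross_validate_clock(matrix: GeneMatrix, config: ClockConfig,
                         withheld: GeneMatrix | None = None,
                         registry: LifespanRegistry | None = None,
                         folds: dict[str, int] | None = None,
                         ) -> tuple[list[EpigeneticClock], pd.DataFrame, dict[str, int]]:
    """Donor-grouped CV of a clock on ``matrix``; returns (models, held-out
    prediction records, fold assignment)."""
    if config.mode == "single" and len(config.layers) == 1:
        matrix = matrix.select_layers(config.layers)
    if folds is None:
        folds = make_folds(matrix.samples, config.n_folds, config.seed, registry)
    models = train_clock(matrix, config, folds, registry)
    records = predict_age(models, matrix, folds, withheld=withheld, registry=registry)
    return models, records, folds


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def donor_level(records: pd.DataFrame) -> pd.DataFrame:
    """Average predictions over tissues within each donor x layer."""
    return records.groupby(["donor_id", "layer", "species", "diet"], as_index=False).agg(
        predicted_years=("predicted_years", "mean"),
        predicted_scaled=("predicted_scaled", "mean"),
        actual_years=("actual_years", "mean"),
    )


def evaluate(records: pd.DataFrame, group_by: str = "layer", min_donors: int = 4) -> pd.Series:
    """Held-out Spearman rho between predicted and actual age per group.

    Predictions are first averaged over tissues within donor x layer
    (except for tissue grouping, where averaging is within donor x layer x
    tissue). ``group_by='overall'`` (alias ``'donor'``) pools all donor x
    layer points into a single correlation. Constant predictions give rho
    0 with a warning; groups with fewer than ``min_donors`` donors are
    excluded with a warning.
    """
    if group_by == "tissue":
        points = records.groupby(["donor_id", "layer", "tissue", "species"], as_index=False).agg(
            predicted_years=("predicted_years", "mean"), actual_years=("actual_years", "mean"))
    else:
        points = donor_level(records)
    if group_by in ("overall", "donor"):
        groups = {"overall": points}
    else:
        groups = {name: g for name, g in points.groupby(group_by)}
    out = {}
    for name, g in groups.items():
        if g["donor_id"].nunique() < min_donors:
            warnings.warn(f"group {name!r} has < {min_donors} donors; excluded")
            continue
        if g["predicted_years"].nunique() == 1:
            warnings.warn(f"group {name!r} has constant predictions; rho set to 0")
            out[name] = 0.0
            continue
        rho, _ = spearman_with_p(g["predicted_years"], g["actual_years"])
        out[name] = rho
    return pd.Series(out, name="rho").rename_axis(group_by)


# ---------------------------------------------------------------------------
# leave-one-layer-out
# ---------------------------------------------------------------------------

def leave_one_layer_out(matrix: GeneMatrix, config: ClockConfig, n_folds: int = 5,
                        registry: LifespanRegistry | None = None) -> pd.DataFrame:
    """Percent change in per-layer prediction accuracy when all profiles of
    one layer are excluded from training (5-fold CV), relative to the full
    pan-epigenetic clock under the same folds.

    Returns a frame indexed by evaluated layer with one column per left-out
    layer.
    """
    layers = [l for l in config.layers if l in set(matrix.samples["layer"])]
    cfg = replace(config, mode="pan", n_folds=n_folds)
    folds = make_folds(matrix.samples, n_folds, cfg.seed, registry)
    _, full_records, _ = cross_validate_clock(matrix, cfg, registry=registry, folds=folds)
    rho_full = evaluate(full_records, "layer")
    pct = pd.DataFrame(index=pd.Index(layers, name="evaluated_layer"),
                       columns=pd.Index(layers, name="left_out_layer"), dtype=float)
    for left_out in layers:
        rest = matrix.select_layers([l for l in layers if l != left_out])
        models = train_clock(rest, cfg, folds, registry)
        held_records = predict_age(models, rest, folds, registry=registry)
        # the left-out layer never entered training: predict with every
        # fold's model and average, as for withheld samples
        out_matrix = matrix.select_layers([left_out])
        stacked = np.vstack([m.predict(out_matrix) for m in models])
        out_records = _records_frame(out_matrix.samples,
                                     np.full(out_matrix.n_samples, -1),
                                     stacked.mean(axis=0), registry)
        rho_wo = pd.concat([evaluate(held_records, "layer"),
                            evaluate(out_records, "layer")])
        for evaluated in layers:
            if evaluated in rho_wo.index and rho_full.get(evaluated, 0) != 0:
                pct.loc[evaluated, left_out] = (
                    100.0 * (rho_wo[evaluated] - rho_full[evaluated]) / rho_full[evaluated]
                )
    return pct


# ---------------------------------------------------------------------------
# scaling rate
# ---------------------------------------------------------------------------

def zero_intercept_slope(x, y) -> float:
    """Least-squares slope of y on x through the origin: sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx2 = float((x**2).sum())
    if sx2 == 0:
        raise ValueError("zero-variance x; slope undefined")
    return float((x * y).sum() / sx2)


def scaling_rate(matrix: GeneMatrix, layer: str, sizes=range(20, 201, 20), reps: int = 10,
                 seed: int = 0, n_folds: int = 5, config: ClockConfig | None = None,
                 registry: LifespanRegistry | None = None) -> tuple[float, pd.DataFrame]:
    """How fast a single-layer clock improves with training donors.

    For each training-cohort size, donors are repeatedly sampled without
    replacement, a single-layer clock is cross-validated on the sampled
    donors, and the held-out donor-level Spearman rho recorded. The scaling
    rate is the zero-intercept OLS slope of rho on log10(donors).
    """
    config = config or ClockConfig(mode="single", layers=(layer,), n_folds=n_folds)
    sub = matrix.select_layers([layer])
    donors = sub.samples["donor_id"].unique()
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(donors):
            raise ValueError(f"cannot sample {size} donors from {len(donors)}")
        for rep in range(reps):
            chosen = rng.choice(donors, size=size, replace=False)
            cohort = sub.subset(sub.samples["donor_id"].isin(chosen).to_numpy())
            cfg = replace(config, mode="single", layers=(layer,), n_folds=n_folds,
                          seed=int(rng.integers(2**31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                _, records, _ = cross_validate_clock(cohort, cfg, registry=registry)
                rho = evaluate(records, "overall").get("overall", 0.0)
            rows.append({"layer": layer, "size": size, "rep": rep, "rho": float(rho)})
    table = pd.DataFrame(rows)
    slope = zero_intercept_slope(np.log10(table["size"]), table["rho"])
    return slope, table
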