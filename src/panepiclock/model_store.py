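"""Plain-text serialization of trained clock ensembles.

Each fold's clock is stored as an XGBoost JSON model plus TSV sidecars for
its selected features, imputation means and per-dataset INT quantile tables,
with a small JSON manifest tying the bundle together.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import xgboost

from .clocks import EpigeneticClock
from .harmonize import DNAmMeanImputer, FoldNormalizer, RankInverseNormal


class _BoosterPredictor:
    """Minimal predict-only wrapper around a deserialized Booster."""

    def __init__(self, booster: xgboost.Booster):
        self.booster = booster

    def predict(self, X):
        return self.booster.predict(xgboost.DMatrix(X))


def save_clock_models(models: list[EpigeneticClock], out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"n_folds": len(models), "folds": []}
    for f, clock in enumerate(models):
        fdir = out / f"fold_{f}"
        fdir.mkdir(exist_ok=True)
        clock.model_.get_booster().save_model(fdir / "model.json")
        (fdir / "features.txt").write_text("\n".join(clock.features_) + "\n")
        norm = clock.normalizer_
        norm.imputer_.means_.rename("mean").rename_axis("gene_id").to_csv(
            fdir / "imputer_means.tsv", sep="\t")
        datasets = []
        for ds, (genes, table) in norm.int_.tables_.items():
            safe = str(ds).replace("/", "_")
            pd.DataFrame(table, columns=genes).to_csv(fdir / f"int_{safe}.tsv",
                                                      sep="\t", index=False)
            datasets.append({"dataset": ds, "file": f"int_{safe}.tsv"})
        params = {k: getattr(clock, k) for k in
                  ("n_estimators", "max_depth", "learning_rate",
                   "feature_rho_threshold", "feature_selection", "seed")}
        manifest["folds"].append({
            "dir": f"fold_{f}", "params": params, "layers": clock.layers_,
            "datasets": datasets,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_clock_models(in_dir) -> list[EpigeneticClock]:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    models = []
    for entry in manifest["folds"]:
        fdir = src / entry["dir"]
        clock = EpigeneticClock(**entry["params"])
        booster = xgboost.Booster()
        booster.load_model(fdir / "model.json")
        clock.model_ = _BoosterPredictor(booster)
        clock.features_ = (fdir / "features.txt").read_text().split()
        clock.layers_ = entry["layers"]
        imputer = DNAmMeanImputer()
        means = pd.read_csv(fdir / "imputer_means.tsv", sep="\t", index_col=0)
        imputer.means_ = means["mean"] if "mean" in means else means.squeeze("columns")
        intx = RankInverseNormal()
        intx.tables_ = {}
        for ds_entry in entry["datasets"]:
            frame = pd.read_csv(fdir / ds_entry["file"], sep="\t")
            intx.tables_[ds_entry["dataset"]] = (frame.columns, frame.to_numpy(dtype=float))
        norm = FoldNormalizer()
        norm.imputer_ = imputer
        norm.int_ = intx
        clock.normalizer_ = norm
        models.append(clock)
    return models
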