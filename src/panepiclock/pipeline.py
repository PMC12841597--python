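"""End-to-end orchestration: simulate -> featurize -> harmonize ->
associate -> clocks -> residuals -> report.

Every stage writes TSV tables under the run directory, each with a one-line
``#`` comment header carrying the config hash, so re-running with an
identical config reproduces all outputs (byte-identically for the
deterministic stages, identically given the seed for the stochastic ones).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_stats import (
    all_layer_intersection,
    association_tables,
    cross_species_overlap,
    pairwise_layer_stats,
    significant_fraction,
)
from .clocks import (
    ClockConfig,
    cross_validate_clock,
    evaluate,
    filter_clock_dataset,
)
from .feature_io import featurize_cohort, read_gene_annotation, read_ortholog_map, read_sample_sheet
from .gene_matrix import GeneMatrix
from .harmonize import FoldNormalizer, StratumMinMaxScaler, combine_layers
from .residuals import binned_residual_curve, compute_residuals, cr_comparison, layer_sync
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "run"
    sim: SimConfig | None = None            # simulate a cohort when set
    sample_sheet: str | None = None          # otherwise read existing inputs
    annotations: dict = field(default_factory=dict)   # species -> path
    ortholog_map: str | None = None
    clock: ClockConfig = field(default_factory=ClockConfig)
    k_top: int = 1000
    fdr_levels: tuple = (0.05, 0.1, 0.2)
    q_threshold: float = 0.05
    min_libraries: int = 50
    min_sync_donors: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the logical configuration. When a cohort is simulated,
        the input paths are derived from the simulation and excluded, so the
        hash is stable across the stages that fill them in."""
        d = self.to_dict()
        if self.sim is not None:
            for key in ("sample_sheet", "annotations", "ortholog_map"):
                d.pop(key, None)
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("sim"):
            raw["sim"] = SimConfig(**raw["sim"])
        if raw.get("clock"):
            raw["clock"] = ClockConfig(**{k: tuple(v) if k == "layers" else v
                                          for k, v in raw["clock"].items()})
        for key in ("fdr_levels",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write(frame: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# panepiclock {__version__} config={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_featurize(config: RunConfig, out: Path) -> GeneMatrix:
    samples = read_sample_sheet(config.sample_sheet)
    annotations = {sp: read_gene_annotation(path, sp)
                   for sp, path in config.annotations.items()}
    ortho = read_ortholog_map(config.ortholog_map) if config.ortholog_map else None
    matrix = featurize_cohort(samples, annotations, ortho)
    matrix.to_tsv(out / "matrix_raw.tsv", out / "matrix_samples.tsv", config.config_hash())
    logger.info("featurize: %d samples x %d genes", matrix.n_samples, len(matrix.genes))
    return matrix


def stage_harmonize(config: RunConfig, matrix: GeneMatrix, out: Path) -> GeneMatrix:
    """Min-max per stratum, then whole-cohort imputation + INT (the
    non-cross-validated normalization used for the association analyses;
    clock folds refit imputation/INT internally)."""
    scaled = StratumMinMaxScaler().fit(matrix).transform(matrix)
    strata = scaled.strata()
    blocks = [scaled.subset((strata == s).to_numpy()) for s in strata.unique()]
    combined = combine_layers(blocks)
    normalized = FoldNormalizer().fit_transform(combined)
    normalized.to_tsv(out / "matrix_normalized.tsv", out / "matrix_samples.tsv",
                      config.config_hash())
    logger.info("harmonize: %d genes present in all samples", len(normalized.genes))
    return normalized


def stage_associate(config: RunConfig, normalized: GeneMatrix, out: Path) -> dict:
    h = config.config_hash()
    tables = association_tables(normalized)
    for (sp, layer), table in tables.items():
        _write(table, out / "assoc" / f"{sp}_{layer}.tsv", h)
    frac = pd.Series({f"{sp}:{layer}": significant_fraction(t, config.q_threshold)
                      for (sp, layer), t in tables.items()}, name="significant_fraction")
    _write(frac.to_frame(), out / "significant_fraction.tsv", h)
    species = sorted({sp for sp, _ in tables})
    for sp in species:
        overlaps, talks = pairwise_layer_stats(tables, sp, k=config.k_top)
        if not overlaps.empty:
            _write(overlaps, out / f"overlap_enrichment_{sp}.tsv", h, index=False)
            _write(talks, out / f"crosstalk_{sp}.tsv", h, index=False)
        sp_tables = {key: t for key, t in tables.items() if key[0] == sp}
        if len(sp_tables) > 1:
            _write(all_layer_intersection(sp_tables, config.fdr_levels).to_frame(),
                   out / f"all_layer_intersection_{sp}.tsv", h)
    if set(species) >= {"human", "mouse"}:
        layers = sorted({l for sp, l in tables})
        rows = []
        for layer in layers:
            if ("human", layer) in tables and ("mouse", layer) in tables:
                res = cross_species_overlap(tables[("human", layer)], tables[("mouse", layer)],
                                            k=config.k_top, pair=("human", "mouse"),
                                            n_tests=len(layers))
                rows.append({"layer": layer, **vars(res)})
        if rows:
            _write(pd.DataFrame(rows), out / "cross_species_overlap.tsv", h, index=False)
    return tables


def stage_clocks(config: RunConfig, matrix: GeneMatrix, out: Path) -> pd.DataFrame:
    h = config.config_hash()
    scaled = StratumMinMaxScaler().fit(matrix).transform(matrix)
    train, withheld = filter_clock_dataset(scaled, min_libraries=config.min_libraries)
    logger.info("clock filter: %d training profiles, %d withheld CR profiles",
                train.n_samples, withheld.n_samples)
    pan_cfg = dataclasses.replace(config.clock, mode="pan", seed=config.seed)
    _, pan_records, _ = cross_validate_clock(
        train, pan_cfg, withheld=withheld if withheld.n_samples else None)
    _write(pan_records, out / "pan_predictions.tsv", h, index=False)
    rows = [evaluate(pan_records[pan_records["fold"] >= 0], g).rename(f"pan_{g}")
            for g in ("layer", "species", "overall")]
    single_records = []
    for layer in pan_cfg.layers:
        if layer not in set(train.samples["layer"]):
            continue
        cfg = dataclasses.replace(config.clock, mode="single", layers=(layer,),
                                  seed=config.seed)
        _, rec, _ = cross_validate_clock(train, cfg)
        single_records.append(rec)
    if single_records:
        singles = pd.concat(single_records, ignore_index=True)
        _write(singles, out / "single_layer_predictions.tsv", h, index=False)
        rows.append(evaluate(singles, "layer").rename("single_layer"))
    summary = pd.concat(rows, axis=1)
    _write(summary, out / "clock_performance.tsv", h)
    return pan_records


def stage_residuals(config: RunConfig, pan_records: pd.DataFrame, out: Path) -> None:
    h = config.config_hash()
    table = compute_residuals(pan_records)
    _write(table, out / "residuals.tsv", h, index=False)
    for sp, sub in table.groupby("species"):
        wide = sub.pivot(index="donor_id", columns="layer", values="residual_adj").dropna()
        if len(wide) >= config.min_sync_donors and wide.shape[1] > 1:
            rho, p = layer_sync(sub[sub["donor_id"].isin(wide.index)],
                                min_shared=config.min_sync_donors)
            _write(rho, out / f"residual_sync_rho_{sp}.tsv", h)
            _write(p, out / f"residual_sync_p_{sp}.tsv", h)
            layers = rho.columns.tolist()
            if len(layers) >= 2:
                curve = binned_residual_curve(sub, layers[0], layers[1])
                _write(curve, out / f"residual_curve_{sp}_{layers[0]}_vs_{layers[1]}.tsv",
                       h, index=False)
    mice = table[table["species"] == "mouse"]
    if (mice["diet"] == "CR").any():
        rows = []
        for layer in sorted(mice["layer"].unique()):
            try:
                rows.append(cr_comparison(table, layers=(layer,)))
            except ValueError:
                continue
        histones = [l for l in mice["layer"].unique() if l != "DNAm"]
        if histones:
            try:
                rows.append({**cr_comparison(table, layers=tuple(histones)),
                             "layers": "pooled_histone"})
            except ValueError:
                pass
        if rows:
            cr = pd.DataFrame(rows)
            cr["layers"] = cr["layers"].astype(str)
            _write(cr, out / "cr_comparison.tsv", h, index=False)


def run_all(config: RunConfig) -> Path:
    """Execute every stage; a stage failure aborts naming the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        if config.sim is not None:
            stage = "simulate"
            sheet_path, _ = simulate_cohort(config.sim, out / "cohort")
            config.sample_sheet = str(sheet_path)
            config.annotations = {sp: str(out / "cohort" / f"genes_{sp}.bed")
                                  for sp in config.sim.species}
            ortho = out / "cohort" / "orthologs.tsv"
            config.ortholog_map = str(ortho) if ortho.exists() else None
        stage = "featurize"
        matrix = stage_featurize(config, out)
        stage = "harmonize"
        normalized = stage_harmonize(config, matrix, out)
        stage = "associate"
        stage_associate(config, normalized, out)
        stage = "clocks"
        pan_records = stage_clocks(config, matrix, out)
        stage = "residuals"
        stage_residuals(config, pan_records, out)
        stage = "report"
        report(out)
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise PipelineError(stage, exc) from exc
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


#: Tables the report summarizes, with the panel of the analysis they mirror.
REPORT_TABLES = {
    "assoc_correlations": "overlap_enrichment_human.tsv",
    "cross_species_overlap": "cross_species_overlap.tsv",
    "all_layer_intersection": "all_layer_intersection_human.tsv",
    "clock_performance": "clock_performance.tsv",
    "residual_sync": "residual_sync_rho_human.tsv",
    "cr_comparison": "cr_comparison.tsv",
}


def report(run_dir) -> Path:
    """Collect the headline tables into ``report/summary.tsv``; stages that
    did not run are marked "not computed" rather than silently absent.
    Re-entrant: a second call produces identical output."""
    run = Path(run_dir)
    rows = []
    for name, fname in REPORT_TABLES.items():
        path = run / fname
        rows.append({"analysis": name,
                     "table": fname if path.exists() else "not computed"})
    rep = run / "report"
    rep.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(rep / "summary.tsv", sep="\t", index=False)
    return rep / "summary.tsv"
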