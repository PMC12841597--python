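"""Synthetic multi-layer epigenetic cohorts with planted aging structure.

The generator emulates the statistical skeleton of a two-species
(human/mouse) epigenetic aging study: a subset of *informative* genes carries
a monotone age trend whose per-gene loading is shared across epigenetic
layers, with a layer-specific sign (repressive marks gain signal with age,
activating marks lose it); every donor has an aging-rate factor common to all
of their profiles; each {dataset x layer} stratum gets an additive batch
shift; and a fraction of mouse donors are calorically restricted, which
shifts their *effective* (epigenetic) age downward.

The latent signal for donor d, gene g, layer l is

    z = sign(l) * loading(g) * (scaled_age_eff(d) + rate(d)) + batch(ds, l) + noise

where scaled age is the lifespan-relative -log(-log(.)) transform. Latents
are realized as raw files the downstream readers can consume exactly:
histone layers as a single gene-spanning narrowPeak whose score column is
``z + 8`` (the peak is absent when that falls below 0, so the gene reads as
0), and DNA methylation as several CpGs inside the gene body sharing the
fraction ``sigmoid(0.4 z)``. At ``noise_sd = 0`` the readers' aggregation
recovers the latent value exactly (up to text formatting).

Everything is deterministic given the config seed; per-sample noise streams
are derived by stable hashing of the sample id, so adding samples never
reshuffles existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .age_scale import LifespanRegistry
from .gene_matrix import GeneMatrix

#: Age-trend direction per layer. Repressive marks gain signal with age;
#: among the activating marks, H3K4me1 and H3K36me3 oppose them while
#: H3K27ac and H3K4me3 empirically trend with the repressive marks in aging
#: cohorts, which is the pattern emulated here.
DEFAULT_LAYER_SIGNS = {
    "DNAm": 1, "H3K27me3": 1, "H3K9me3": 1, "H3K27ac": 1, "H3K4me3": 1,
    "H3K36me3": -1, "H3K4me1": -1,
}

DEFAULT_LAYERS = ["DNAm", "H3K4me3", "H3K27ac", "H3K27me3", "H3K4me1"]

TISSUE_POOL = ["liver", "blood", "kidney", "brain", "muscle", "heart"]

GENE_SPAN = 2_000           # bp per synthetic gene body
GENE_SPACING = 10_000       # bp between gene starts on a chromosome
HISTONE_SCORE_OFFSET = 8.0  # keeps almost all peak scores positive
HISTONE_SCORE_FLOOR = 0.0   # latent+offset below this -> peak absent
METH_SLOPE = 0.4            # logistic slope mapping latents to fractions
CPG_COVERAGE = 30

_N_AUTOSOMES = {"human": 22, "mouse": 19}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the reference cohort used throughout the test suite:
    200 donors per species, the five clock layers, 2000 genes of which 300
    carry age signal, per-gene noise of the same order as the per-gene
    signal, and a fifth of mouse donors under caloric restriction with a
    0.1-lifespan reduction in effective relative age (~0.4 mouse years).
    """

    n_genes: int = 2000
    n_informative: int = 300
    n_donors_per_species: int = 200
    species: tuple = ("human", "mouse")
    layers: tuple = tuple(DEFAULT_LAYERS)
    tissues_per_donor: int = 1
    n_datasets: int = 2
    age_range_frac: tuple = (0.05, 0.9)
    shared_loading_sd: float = 1.0
    layer_sign_map: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    batch_shift_sd: float = 0.5
    donor_rate_sd: float = 0.1
    cr_fraction: float = 0.2
    cr_offset_frac: float = 0.1
    gene_baseline_sd: float = 1.0
    cpgs_per_gene: int = 8
    seed: int = 0

    def __post_init__(self):
        if not self.layer_sign_map:
            self.layer_sign_map = {l: DEFAULT_LAYER_SIGNS[l] for l in self.layers}
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative must be <= n_genes")
        for name in ("shared_loading_sd", "noise_sd", "batch_shift_sd", "donor_rate_sd",
                     "gene_baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.cr_fraction <= 1.0:
            raise ValueError("cr_fraction must lie in [0, 1]")
        lo, hi = self.age_range_frac
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("age_range_frac must be an interval within (0, 1)")
        missing = [l for l in self.layers if l not in self.layer_sign_map]
        if missing:
            raise ValueError(f"layer_sign_map does not cover layer(s) {missing}")
        if any(s not in (-1, 1) for s in self.layer_sign_map.values()):
            raise ValueError("layer signs must be +1 or -1")
        if self.tissues_per_donor > len(TISSUE_POOL):
            raise ValueError(f"at most {len(TISSUE_POOL)} tissues supported")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("species", "layers", "age_range_frac"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthSet:
    """Machine-readable ground truth for a simulated cohort."""

    gene_loadings: pd.Series          # per human gene id; 0 for uninformative
    informative_gene_ids: set
    donor_rate_factors: pd.Series     # per donor, scaled-age units
    batch_shifts: dict                # (dataset, layer) -> shift
    cr_flags: pd.Series               # per donor, bool
    true_ages_years: pd.Series        # per donor

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gene_loadings.rename("loading").rename_axis("gene_id").to_csv(
            out / "gene_loadings.tsv", sep="\t")
        donors = pd.DataFrame({
            "rate_factor": self.donor_rate_factors,
            "cr_flag": self.cr_flags,
            "age_years": self.true_ages_years,
        }).rename_axis("donor_id")
        donors.to_csv(out / "donors.tsv", sep="\t")
        rows = [(ds, layer, shift) for (ds, layer), shift in sorted(self.batch_shifts.items())]
        pd.DataFrame(rows, columns=["dataset", "layer", "shift"]).to_csv(
            out / "batch_shifts.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# raw-format writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_narrowpeak(records, path) -> Path:
    """Write peaks as 10-column narrowPeak, sorted by coordinate.

    ``records``: iterable of (chrom, start, end, score) or a frame with those
    columns. Negative coordinates raise.
    """
    if isinstance(records, pd.DataFrame):
        records = list(records[["chrom", "start", "end", "score"]].itertuples(index=False))
    records = sorted(records, key=lambda r: (str(r[0]), int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for chrom, start, end, score in records:
            if start < 0 or end <= start:
                raise ValueError(f"invalid peak interval [{start}, {end})")
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t.\t{_fmt(score)}\t.\t0\t-1\t-1\t-1\n")
    return Path(path)


def write_cpg_table(records, path) -> Path:
    """Write CpG sites as a 4-column TSV sorted by coordinate; fractions
    outside [0, 1] or negative positions raise."""
    if isinstance(records, pd.DataFrame):
        records = list(records[["chrom", "pos", "meth_fraction", "coverage"]].itertuples(index=False))
    records = sorted(records, key=lambda r: (str(r[0]), int(r[1])))
    with open(path, "w") as fh:
        for chrom, pos, frac, cov in records:
            if pos < 0:
                raise ValueError(f"negative CpG position {pos}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"methylation fraction {frac} outside [0, 1]")
            fh.write(f"{chrom}\t{int(pos)}\t{frac:.8f}\t{int(cov)}\n")
    return Path(path)


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def _gene_table(species: str, n_genes: int) -> pd.DataFrame:
    prefix = "HG" if species == "human" else "MG"
    n_chrom = _N_AUTOSOMES[species]
    idx = np.arange(n_genes)
    chrom_i = idx % n_chrom
    pos_on_chrom = idx // n_chrom
    start = 10_000 + pos_on_chrom * GENE_SPACING
    return pd.DataFrame({
        "gene_id": [f"{prefix}{i + 1:06d}" for i in idx],
        "chrom": [f"chr{c + 1}" for c in chrom_i],
        "start": start,
        "end": start + GENE_SPAN,
        "species": species,
    })


def _sample_noise(config: SimConfig, sample_id: str) -> np.ndarray:
    """Per-sample gene noise from a substream keyed by a stable hash of the
    sample id, independent of generation order."""
    sub = np.random.default_rng([config.seed, zlib.crc32(sample_id.encode())])
    return sub.normal(0.0, config.noise_sd, size=config.n_genes)


@dataclass
class _Cohort:
    """Latent cohort state shared by the in-memory and on-disk realizations."""

    config: SimConfig
    donors: pd.DataFrame       # donor_id, species, age_years, scaled_eff, rate, cr, dataset
    loadings: np.ndarray       # per gene (human order)
    informative: np.ndarray    # bool per gene
    baselines: dict            # layer -> per-gene age-constant occupancy offset
    batch_shifts: dict
    genes: dict                # species -> annotation frame
    samples: pd.DataFrame      # sample sheet (no file_path yet)


def _build_cohort(config: SimConfig) -> _Cohort:
    rng = np.random.default_rng(config.seed)
    registry = LifespanRegistry()

    loadings = np.zeros(config.n_genes)
    informative = np.zeros(config.n_genes, dtype=bool)
    if config.n_informative:
        chosen = rng.choice(config.n_genes, size=config.n_informative, replace=False)
        informative[chosen] = True
        loadings[chosen] = np.abs(rng.normal(0.0, config.shared_loading_sd, config.n_informative))

    lo, hi = config.age_range_frac
    donor_rows = []
    for sp in config.species:
        lifespan = registry[sp]
        n = config.n_donors_per_species
        rel = rng.uniform(lo, hi, size=n)
        rates = rng.normal(0.0, config.donor_rate_sd, size=n)
        cr = np.zeros(n, dtype=bool)
        if sp == "mouse" and config.cr_fraction > 0:
            n_cr = int(round(config.cr_fraction * n))
            cr[rng.choice(n, size=n_cr, replace=False)] = True
        prefix = sp[0].upper()
        for i in range(n):
            eff_rel = rel[i] - (config.cr_offset_frac if cr[i] else 0.0)
            eff_rel = max(eff_rel, 1e-3)
            donor_rows.append({
                "donor_id": f"{prefix}{i + 1:05d}",
                "species": sp,
                "age_years": rel[i] * lifespan,
                "scaled_eff": -np.log(-np.log(eff_rel)),
                "rate": rates[i],
                "cr": cr[i],
                "dataset": f"{sp}_ds{(i % config.n_datasets) + 1}",
            })
    donors = pd.DataFrame(donor_rows).set_index("donor_id")

    batch_shifts = {}
    for ds in sorted(donors["dataset"].unique()):
        for layer in config.layers:
            batch_shifts[(ds, layer)] = float(rng.normal(0.0, config.batch_shift_sd))

    # each mark has its own gene-wise occupancy pattern, constant in age:
    # this is what lets a profile's layer be recognized from data alone
    baselines = {layer: rng.normal(0.0, config.gene_baseline_sd, config.n_genes)
                 for layer in config.layers}

    tissues = TISSUE_POOL[: config.tissues_per_donor]
    sample_rows = []
    for donor_id, d in donors.iterrows():
        for tissue in tissues:
            for layer in config.layers:
                sample_rows.append({
                    "sample_id": f"{donor_id}_{tissue}_{layer}",
                    "donor_id": donor_id,
                    "species": d["species"],
                    "tissue": tissue,
                    "layer": layer,
                    "dataset": d["dataset"],
                    "age_years": d["age_years"],
                    "diet": "CR" if d["cr"] else "standard",
                })
    samples = pd.DataFrame(sample_rows)

    genes = {sp: _gene_table(sp, config.n_genes) for sp in config.species}
    return _Cohort(config, donors, loadings, informative, baselines, batch_shifts, genes,
                   samples)


def _latent(cohort: _Cohort, sample: pd.Series) -> np.ndarray:
    cfg = cohort.config
    d = cohort.donors.loc[sample["donor_id"]]
    sign = cfg.layer_sign_map[sample["layer"]]
    z = sign * cohort.loadings * (d["scaled_eff"] + d["rate"])
    z = z + cohort.baselines[sample["layer"]]
    z = z + cohort.batch_shifts[(sample["dataset"], sample["layer"])]
    return z + _sample_noise(cfg, sample["sample_id"])


def _realize(cohort: _Cohort, sample: pd.Series) -> np.ndarray:
    """Gene-level value the readers will recover from this sample's file."""
    z = _latent(cohort, sample)
    if sample["layer"] == "DNAm":
        return 1.0 / (1.0 + np.exp(-METH_SLOPE * z))
    score = z + HISTONE_SCORE_OFFSET
    return np.where(score > HISTONE_SCORE_FLOOR, score, 0.0)


def _truth(cohort: _Cohort) -> TruthSet:
    human_ids = pd.Index(_gene_table("human", cohort.config.n_genes)["gene_id"])
    return TruthSet(
        gene_loadings=pd.Series(cohort.loadings, index=human_ids),
        informative_gene_ids=set(human_ids[cohort.informative]),
        donor_rate_factors=cohort.donors["rate"].copy(),
        batch_shifts=dict(cohort.batch_shifts),
        cr_flags=cohort.donors["cr"].copy(),
        true_ages_years=cohort.donors["age_years"].copy(),
    )


def simulate_gene_matrix(config: SimConfig) -> tuple[GeneMatrix, TruthSet]:
    """Simulate a cohort directly as a gene-level matrix (human gene ids).

    Identical to reading back the files written by :func:`simulate_cohort`
    up to text formatting of the raw values; use this path when the raw-file
    round trip itself is not under study.
    """
    cohort = _build_cohort(config)
    # the common coordinate system is always human gene ids (mouse genes map
    # one-to-one by construction)
    human_ids = _gene_table("human", config.n_genes)["gene_id"].to_numpy()
    values = np.empty((len(cohort.samples), config.n_genes))
    for i, (_, sample) in enumerate(cohort.samples.iterrows()):
        values[i] = _realize(cohort, sample)
    frame = pd.DataFrame(values, index=pd.Index(cohort.samples["sample_id"], name="sample_id"),
                         columns=human_ids)
    samples = cohort.samples.copy()
    samples["file_path"] = ""
    return GeneMatrix(frame, samples), _truth(cohort)


def simulate_cohort(config: SimConfig, out_dir) -> tuple[Path, TruthSet]:
    """Write a full raw-format cohort: per-sample narrowPeak / CpG files,
    per-species gene BED annotations, a one-to-one ortholog map, the sample
    sheet, the config, and the truth set. Returns the sample-sheet path."""
    out = Path(out_dir)
    (out / "raw").mkdir(parents=True, exist_ok=True)
    cohort = _build_cohort(config)

    for sp, genes in cohort.genes.items():
        genes[["chrom", "start", "end", "gene_id"]].to_csv(
            out / f"genes_{sp}.bed", sep="\t", index=False, header=False)
    if "mouse" in cohort.genes and "human" in cohort.genes:
        pd.DataFrame({
            "mouse_gene": cohort.genes["mouse"]["gene_id"],
            "human_gene": cohort.genes["human"]["gene_id"],
        }).to_csv(out / "orthologs.tsv", sep="\t", index=False)

    paths = []
    for _, sample in cohort.samples.iterrows():
        sp_genes = cohort.genes[sample["species"]]
        vals = _realize(cohort, sample)
        fname = out / "raw" / f"{sample['sample_id']}.tsv"
        if sample["layer"] == "DNAm":
            c = cohort.config.cpgs_per_gene
            offsets = (np.arange(1, c + 1) * GENE_SPAN) // (c + 1)
            recs = pd.DataFrame({
                "chrom": np.repeat(sp_genes["chrom"].to_numpy(), c),
                "pos": np.repeat(sp_genes["start"].to_numpy(), c) + np.tile(offsets, len(sp_genes)),
                "meth_fraction": np.repeat(vals, c),
                "coverage": CPG_COVERAGE,
            })
            write_cpg_table(recs, fname)
        else:
            fname = fname.with_suffix(".narrowPeak")
            present = vals > 0
            recs = pd.DataFrame({
                "chrom": sp_genes.loc[present, "chrom"].to_numpy(),
                "start": sp_genes.loc[present, "start"].to_numpy(),
                "end": sp_genes.loc[present, "end"].to_numpy(),
                "score": vals[present],
            })
            write_narrowpeak(recs, fname)
        paths.append(str(fname))

    samples = cohort.samples.copy()
    samples["file_path"] = paths
    sheet_path = out / "samples.tsv"
    samples.to_csv(sheet_path, sep="\t", index=False)
    config.to_yaml(out / "sim_config.yaml")
    truth = _truth(cohort)
    truth.write(out / "truth")
    return sheet_path, truth
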