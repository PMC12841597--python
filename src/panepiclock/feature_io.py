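"""Genomic format readers and gene-level signal aggregation.

Per-sample raw profiles (ChIP-seq peak calls in narrowPeak, per-CpG
methylation tables from WGBS) are summarized to one continuous value per
gene: the mean narrowPeak score of all peaks overlapping the gene body, or
the mean methylation fraction of all CpGs inside it. Genes without any
overlapping feature get 0. Mouse genes are then renamed to their one-to-one
human orthologs so every profile lives in a single human-gene coordinate
system.

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
inclusive) is converted on read. Strand is ignored: gene bodies are treated
as unstranded intervals, and the overlap rule is any >= 1 bp intersection,
unweighted by length.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from .gene_matrix import GeneMatrix, validate_sample_sheet

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal_value", "p_value", "q_value", "peak",
]
CPG_COLUMNS = ["chrom", "pos", "meth_fraction", "coverage"]

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$")


def is_autosome(chrom: str) -> bool:
    """True for numerically named chromosomes (``chr7``/``7``); sex
    chromosomes, mitochondria and scaffolds are excluded."""
    return _AUTOSOME_RE.match(str(chrom)) is not None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> pd.DataFrame:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Returns a frame with :data:`NARROWPEAK_COLUMNS`; coordinates stay
    0-based half-open. Malformed lines raise ``ValueError`` naming the line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed narrowPeak line ({exc})") from None
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append(
                (fields[0], start, end, fields[3], score, fields[5],
                 float(fields[6]), float(fields[7]), float(fields[8]), int(fields[9]))
            )
    return pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)


def read_cpg_table(path) -> pd.DataFrame:
    """Read a 4-column CpG TSV: chrom, pos (0-based), meth_fraction, coverage."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: CpG table requires 4 columns, got {len(fields)}")
            try:
                pos, frac, cov = int(fields[1]), float(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed CpG line ({exc})") from None
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{path}:{lineno}: methylation fraction {frac} outside [0, 1]")
            if pos < 0:
                raise ValueError(f"{path}:{lineno}: negative position {pos}")
            rows.append((fields[0], pos, frac, cov))
    return pd.DataFrame(rows, columns=CPG_COLUMNS)


def read_gene_annotation(path, species: str, fmt: str | None = None) -> pd.DataFrame:
    """Read gene-body annotations from BED (0-based half-open) or GTF/GFF3
    (1-based inclusive, converted on read).

    Non-autosomal records are dropped. Returns columns
    ``gene_id, chrom, start, end, species``; duplicate gene ids raise.
    """
    path = str(path)
    if fmt is None:
        lowered = path.lower()
        if lowered.endswith((".gtf", ".gff", ".gff3")):
            fmt = "gtf"
        elif lowered.endswith(".bed"):
            fmt = "bed"
        else:
            raise ValueError(f"cannot infer annotation format from {path!r}; pass fmt=")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED gene annotation requires 4 columns")
                chrom, start, end, gene_id = fields[0], int(fields[1]), int(fields[2]), fields[3]
            else:
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GTF/GFF3 requires 9 columns")
                if fields[2] != "gene":
                    continue
                chrom = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])  # to 0-based half-open
                m = re.search(r'gene_id[ =]+"?([^";]+)"?', fields[8])
                if m is None:
                    m = re.search(r"ID=(?:gene:)?([^;]+)", fields[8])
                if m is None:
                    raise ValueError(f"{path}:{lineno}: no gene_id in attributes")
                gene_id = m.group(1)
            if not is_autosome(chrom):
                continue
            rows.append((gene_id, chrom, start, end, species))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "species"])
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene_id(s) in {path}: {dups[:5].tolist()}")
    return genes


def read_ortholog_map(path) -> pd.DataFrame:
    """Read a two-column one-to-one ortholog TSV (mouse_gene, human_gene)."""
    ortho = pd.read_csv(path, sep="\t", comment="#")
    if ortho.shape[1] < 2:
        raise ValueError("ortholog map needs two columns: source gene, human gene")
    ortho = ortho.iloc[:, :2]
    ortho.columns = ["source_gene", "human_gene"]
    if ortho["source_gene"].duplicated().any() or ortho["human_gene"].duplicated().any():
        raise ValueError("ortholog map is not one-to-one")
    return ortho


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _interval_mean(genes: pd.DataFrame, feat_chrom, feat_start, feat_end, feat_value) -> np.ndarray:
    """Mean feature value over features overlapping each gene body.

    Sweep per chromosome with sorted endpoints and prefix sums: a feature
    [s, e) overlaps gene [gs, ge) iff s < ge and e > gs, so the overlap count
    is #(s < ge) - #(e <= gs) (valid because features are non-empty).
    O((n + m) log n); genes with no overlapping feature get 0.
    """
    out = np.zeros(len(genes), dtype=float)
    if len(feat_chrom) == 0 or len(genes) == 0:
        return out
    feats = pd.DataFrame(
        {"chrom": np.asarray(feat_chrom), "start": np.asarray(feat_start, dtype=np.int64),
         "end": np.asarray(feat_end, dtype=np.int64), "value": np.asarray(feat_value, dtype=float)}
    )
    for chrom, sub in feats.groupby("chrom", sort=False):
        gmask = (genes["chrom"] == chrom).to_numpy()
        if not gmask.any():
            continue
        gs = genes.loc[gmask, "start"].to_numpy(dtype=np.int64)
        ge = genes.loc[gmask, "end"].to_numpy(dtype=np.int64)
        s_sorted = np.sort(sub["start"].to_numpy())
        e_sorted = np.sort(sub["end"].to_numpy())
        v_by_start = sub["value"].to_numpy()[np.argsort(sub["start"].to_numpy(), kind="stable")]
        v_by_end = sub["value"].to_numpy()[np.argsort(sub["end"].to_numpy(), kind="stable")]
        cum_s = np.concatenate([[0.0], np.cumsum(v_by_start)])
        cum_e = np.concatenate([[0.0], np.cumsum(v_by_end)])
        n_lo = np.searchsorted(s_sorted, ge, side="left")   # features starting before gene end
        n_hi = np.searchsorted(e_sorted, gs, side="right")  # features ending at/before gene start
        count = n_lo - n_hi
        total = cum_s[n_lo] - cum_e[n_hi]
        vals = np.zeros(gmask.sum())
        nz = count > 0
        vals[nz] = total[nz] / count[nz]
        out[gmask] = vals
    return out


def gene_level_chip(peaks: pd.DataFrame, genes: pd.DataFrame, use_signal_value: bool = False) -> pd.Series:
    """Per-gene mean narrowPeak score over peaks overlapping the gene body.

    ``use_signal_value=True`` aggregates column 7 (signalValue) instead of
    column 5 (score). Genes with no overlapping peak are assigned 0.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    col = "signal_value" if use_signal_value else "score"
    values = _interval_mean(genes, peaks["chrom"], peaks["start"], peaks["end"], peaks[col])
    return pd.Series(values, index=pd.Index(genes["gene_id"], name="gene_id"), name="value")


def gene_level_meth(cpgs: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Per-gene mean methylation fraction over CpGs inside the gene body
    (half-open: a CpG at the gene's end coordinate is outside). Genes with
    no contained CpG are assigned 0."""
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    pos = np.asarray(cpgs["pos"], dtype=np.int64)
    values = _interval_mean(genes, cpgs["chrom"], pos, pos + 1, cpgs["meth_fraction"])
    return pd.Series(values, index=pd.Index(genes["gene_id"], name="gene_id"), name="value")


def map_orthologs(values: pd.Series, ortho: pd.DataFrame | None, species: str) -> pd.Series:
    """Rename mouse gene ids to one-to-one human orthologs.

    Mouse genes absent from the map are dropped; human vectors pass through
    unchanged. A duplicate target id after mapping raises.
    """
    if species == "human" or ortho is None:
        return values
    mapping = dict(zip(ortho["source_gene"], ortho["human_gene"]))
    keep = values.index.isin(mapping)
    mapped = values[keep].rename(index=mapping)
    if mapped.index.duplicated().any():
        raise ValueError("duplicate human gene ids after ortholog mapping")
    return mapped


def assemble_matrix(vectors: dict[str, pd.Series], samples: pd.DataFrame) -> GeneMatrix:
    """Stack per-sample gene vectors into a GeneMatrix.

    Rows follow sample-sheet order over the union of gene ids; a gene absent
    from a sample's vector is recorded as missing (NaN), distinct from 0.
    Within each {dataset x layer} stratum, genes that are zero or absent in
    *every* sample of the stratum are set to missing for that stratum (no
    peak was ever called there); genes missing everywhere are then dropped.
    """
    samples = validate_sample_sheet(samples)
    missing_samples = [s for s in samples.index if s not in vectors]
    if missing_samples:
        raise ValueError(f"no gene vector for sample(s): {missing_samples[:5]}")
    values = pd.DataFrame({sid: vectors[sid] for sid in samples.index}).T
    values.index.name = "sample_id"
    strata = list(zip(samples["dataset"], samples["layer"]))
    for stratum in sorted(set(strata)):
        rows = [i for i, s in enumerate(strata) if s == stratum]
        block = values.iloc[rows]
        all_zero = (block.fillna(0) == 0).all(axis=0)
        if all_zero.any():
            values.iloc[rows, np.flatnonzero(all_zero.to_numpy())] = np.nan
    everywhere_missing = values.isna().all(axis=0)
    if everywhere_missing.any():
        values = values.loc[:, ~everywhere_missing]
    if values.shape[1] == 0:
        warnings.warn("assembled matrix has no genes with signal in any sample")
    return GeneMatrix(values, samples)


def featurize_sample(meta: pd.Series, annotations: dict[str, pd.DataFrame],
                     ortho: pd.DataFrame | None, use_signal_value: bool = False) -> pd.Series:
    """Read one sample's raw file and aggregate to a human-gene vector."""
    genes = annotations[meta["species"]]
    if meta["layer"] == "DNAm":
        vec = gene_level_meth(read_cpg_table(meta["file_path"]), genes)
    else:
        vec = gene_level_chip(read_narrowpeak(meta["file_path"]), genes, use_signal_value)
    return map_orthologs(vec, ortho, meta["species"])


def featurize_cohort(samples: pd.DataFrame, annotations: dict[str, pd.DataFrame],
                     ortho: pd.DataFrame | None, use_signal_value: bool = False) -> GeneMatrix:
    """Aggregate every sample in the sheet and assemble the cohort matrix."""
    samples = validate_sample_sheet(samples)
    vectors = {
        sid: featurize_sample(row, annotations, ortho, use_signal_value)
        for sid, row in samples.iterrows()
    }
    return assemble_matrix(vectors, samples)
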