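"""Samples-by-genes matrix with attached sample metadata.

``GeneMatrix`` is the central exchange object of the pipeline: rows are
profiled libraries (one donor x tissue x epigenetic layer), columns are genes
in the shared (human) gene coordinate system, and a sample sheet carries the
per-library metadata (donor, species, tissue, layer, dataset, age, diet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Columns every sample sheet must provide.
SAMPLE_COLUMNS = [
    "sample_id",
    "donor_id",
    "species",
    "tissue",
    "layer",
    "dataset",
    "age_years",
    "diet",
]

HISTONE_LAYERS = ["H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "H3K36me3", "H3K9me3"]
ALL_LAYERS = ["DNAm"] + HISTONE_LAYERS

#: Repressive vs activating split used for direction-based gene-set selection.
REPRESSIVE_MARKS = ["H3K27me3", "H3K9me3", "DNAm"]
ACTIVATING_MARKS = ["H3K27ac", "H3K36me3", "H3K4me1", "H3K4me3"]


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and set ``sample_id`` as the index."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns and samples.index.name != c]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    out = samples.copy()
    if out.index.name != "sample_id":
        out = out.set_index("sample_id")
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id values: {dups[:5]}")
    return out


@dataclass
class GeneMatrix:
    """Gene-level epigenetic signal for a set of samples.

    Parameters
    ----------
    values
        Real-valued frame, index = sample_id, columns = gene ids. ``NaN``
        encodes *missing* (no measurement), which is distinct from 0
        (measured, no overlapping peaks/CpGs).
    samples
        Sample sheet indexed by sample_id, aligned row-for-row with
        ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(
            self.samples.reset_index() if self.samples.index.name == "sample_id" else self.samples
        )
        if not self.values.index.equals(self.samples.index):
            # allow constructing from unordered inputs as long as ids match
            if set(self.values.index) != set(self.samples.index):
                raise ValueError("values and sample sheet refer to different sample ids")
            self.samples = self.samples.loc[self.values.index]
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate gene ids in matrix columns")

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def strata(self) -> pd.Series:
        """(dataset, layer) stratum label per sample."""
        return pd.Series(
            list(zip(self.samples["dataset"], self.samples["layer"])),
            index=self.samples.index,
            name="stratum",
        )

    def subset(self, mask) -> "GeneMatrix":
        """Row subset by boolean mask or list of sample ids."""
        if isinstance(mask, (list, pd.Index, np.ndarray)) and not (
            len(mask) == self.n_samples and np.asarray(mask).dtype == bool
        ):
            ids = pd.Index(mask)
            return GeneMatrix(self.values.loc[ids], self.samples.loc[ids])
        m = np.asarray(mask, dtype=bool)
        return GeneMatrix(self.values.loc[m], self.samples.loc[m])

    def select_layers(self, layers) -> "GeneMatrix":
        return self.subset(self.samples["layer"].isin(list(layers)).to_numpy())

    def select_species(self, species: str) -> "GeneMatrix":
        return self.subset((self.samples["species"] == species).to_numpy())

    def copy(self) -> "GeneMatrix":
        return GeneMatrix(self.values.copy(), self.samples.copy())

    # -- serialization ---------------------------------------------------
    def to_tsv(self, values_path, samples_path, comment: str | None = None) -> None:
        """Write matrix + sample-sheet sidecar as TSV (optionally with a
        single ``#`` header comment carrying provenance)."""
        for path, frame in ((values_path, self.values), (samples_path, self.samples)):
            with open(path, "w") as fh:
                if comment:
                    fh.write(f"# {comment}\n")
                frame.to_csv(fh, sep="\t", index=True)

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "GeneMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
        samples = pd.read_csv(samples_path, sep="\t", comment="#")
        return cls(values, samples)


def concat_matrices(matrices: list[GeneMatrix]) -> GeneMatrix:
    """Row-concatenate matrices over the union of their gene columns."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    values = pd.concat([m.values for m in matrices], axis=0)
    samples = pd.concat([m.samples for m in matrices], axis=0)
    return GeneMatrix(values, samples)
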