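"""Core in-memory containers and text-table I/O.

The unit of analysis throughout the package is the protein-level abundance
matrix (proteins x samples, log2 scale) with explicit missingness, paired
with a per-sample metadata table.  Missing values are carried as NaN; the
``mask`` property exposes the boolean observed/missing view the operations
reason about.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "SampleTable",
    "read_abundance",
    "write_abundance",
    "read_gmt",
    "write_gmt",
    "LoadError",
]

#: forward-only order of preprocessing states
SCALE_TAGS = ("raw", "log2", "batch_corrected", "zscored")

REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "species",
    "biofluid",
    "timepoint_h",
    "group",
    "severity_grade",
    "outcome_cont",
    "outcome_bin",
    "injury_level",
    "batch",
)


class LoadError(ValueError):
    """Raised when an abundance/metadata pair fails cross-validation."""


@dataclasses.dataclass
class AbundanceMatrix:
    """Proteins x samples abundance with missingness.

    Parameters
    ----------
    data
        DataFrame indexed by protein id with sample ids as columns.
        NaN encodes a missing (unobserved / censored) measurement.
    scale_tag
        Position in the preprocessing chain; transitions only move
        forward along ``raw -> log2 -> batch_corrected -> zscored``.
    """

    data: pd.DataFrame
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate protein ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample ids: {dups}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value was observed."""
        return self.data.notna()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scale_tag: str | None = None) -> "AbundanceMatrix":
        tag = self.scale_tag if scale_tag is None else scale_tag
        if SCALE_TAGS.index(tag) < SCALE_TAGS.index(self.scale_tag):
            raise ValueError(
                f"scale_tag may only move forward, not {self.scale_tag!r} -> {tag!r}"
            )
        return AbundanceMatrix(data=data, scale_tag=tag)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(sample_ids)
        return AbundanceMatrix(data=self.data.loc[:, ids], scale_tag=self.scale_tag)

    def subset_proteins(self, protein_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(protein_ids)
        return AbundanceMatrix(data=self.data.loc[ids], scale_tag=self.scale_tag)


@dataclasses.dataclass
class SampleTable:
    """Per-sample metadata, one row per sample.

    Required columns: sample_id, subject_id, species, biofluid, timepoint_h,
    group, severity_grade, outcome_cont, outcome_bin, injury_level, batch.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise LoadError(f"metadata missing required columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"].tolist()
            raise LoadError(f"duplicate sample ids in metadata: {dups}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def column(self, name: str) -> pd.Series:
        return self.data.set_index("sample_id")[name]

    def aligned(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Rows reindexed to the given sample-id order."""
        return self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()

    def subset(self, mask: pd.Series | np.ndarray) -> "SampleTable":
        return SampleTable(self.data.loc[np.asarray(mask)].reset_index(drop=True))


def _cross_validate(matrix: AbundanceMatrix, samples: SampleTable) -> None:
    orphans = sorted(set(matrix.sample_ids) - set(samples.sample_ids))
    if orphans:
        raise LoadError(
            f"abundance samples missing from metadata: {orphans}"
        )


def read_abundance(path, metadata_path, scale_tag: str = "log2") -> tuple[AbundanceMatrix, SampleTable]:
    """Load an abundance TSV (rows = proteins, header = sample ids; empty
    cell = missing) and its metadata TSV, cross-validating sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df = df.astype(float)
    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    matrix = AbundanceMatrix(data=df, scale_tag=scale_tag)
    samples = SampleTable(meta)
    _cross_validate(matrix, samples)
    # metadata may cover more samples (e.g. a second species); the matrix
    # column order is authoritative for the returned table
    samples = SampleTable(samples.aligned(matrix.sample_ids))
    return matrix, samples


def write_abundance(matrix: AbundanceMatrix, path, provenance: Iterable[str] = ()) -> None:
    """Write the matrix as TSV with missing values as empty cells; optional
    ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        matrix.data.to_csv(fh, sep="\t", na_rep="")


def write_sample_table(samples: SampleTable, path, provenance: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        samples.data.to_csv(fh, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name TAB description TAB members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [m for m in fields[2:] if m]
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")
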