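"""Core data containers and TSV I/O.

The pipeline starts from a gene × library integer count matrix plus a sample
sheet assigning each library a developmental temperature (°C) and a replicate
number. Both are stored as pandas objects inside :class:`CountMatrix`, the
container every downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "read_counts_tsv",
    "read_sample_sheet",
    "read_architecture_tsv",
    "write_counts_tsv",
]

SAMPLE_COLUMNS = ("library_id", "temperature", "replicate")
ARCHITECTURE_COLUMNS = ("n_tfs", "n_mirnas", "utr5_len", "utr3_len", "intron1_len")


@dataclass
class CountMatrix:
    """Gene × library read counts with per-library metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one integer column per library.
    samples
        DataFrame indexed by ``library_id`` with columns ``temperature``
        (°C, numeric) and ``replicate`` (integer within temperature).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.copy()
        if self.samples.index.name != "library_id":
            if "library_id" in self.samples.columns:
                self.samples = self.samples.set_index("library_id")
            else:
                self.samples.index.name = "library_id"
        self.validate()

    def validate(self) -> None:
        if self.counts.shape[0] == 0:
            raise ValueError("count matrix has no genes")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(
                "count matrix columns and sample sheet libraries disagree: "
                f"{sorted(missing)[:5]}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        for col in ("temperature", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def temperatures(self) -> np.ndarray:
        """Per-library temperature vector, aligned with count columns."""
        return self.samples.loc[self.counts.columns, "temperature"].to_numpy(float)

    @property
    def design_temperatures(self) -> np.ndarray:
        """Sorted unique temperatures of the design."""
        return np.unique(self.temperatures)

    @property
    def library_totals(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.samples)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.counts.shape
        temps = ", ".join(f"{t:g}" for t in self.design_temperatures)
        return f"CountMatrix({g} genes × {s} libraries; temperatures {temps} °C)"


def read_counts_tsv(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene id) and a sample-sheet TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = read_sample_sheet(samples_path)
    return CountMatrix(counts, samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise ValueError(f"sample sheet {path} missing column {col!r}")
    return samples.set_index("library_id")


def read_architecture_tsv(path: str | Path) -> pd.DataFrame:
    """Read the per-gene regulatory-architecture table.

    Columns: gene_id, n_tfs, n_mirnas, utr5_len, utr3_len, intron1_len.
    Missing values are kept as NaN; linkage analyses use complete cases only.
    """
    arch = pd.read_csv(path, sep="\t")
    if "gene_id" not in arch.columns:
        raise ValueError(f"architecture table {path} missing column 'gene_id'")
    for col in ARCHITECTURE_COLUMNS:
        if col not in arch.columns:
            raise ValueError(f"architecture table {path} missing column {col!r}")
    return arch.set_index("gene_id")


def write_counts_tsv(matrix: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    matrix.samples.reset_index().to_csv(samples_path, sep="\t", index=False)
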