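"""Protein abundance matrices with explicit missingness.

The central container is :class:`AbundanceMatrix`: a proteins x samples
matrix of intensities (raw or log2) together with a boolean missingness
mask. Raw TMT exports encode missing quantifications as 0; the mask makes
that convention explicit so downstream arithmetic never confuses "absent"
with "zero intensity".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "read_abundance_tsv", "write_abundance_tsv"]


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity matrix with a missingness mask.

    Parameters
    ----------
    values : ndarray, shape (n_proteins, n_samples)
        Intensities. Entries at masked cells are undefined and must not be
        interpreted.
    mask : ndarray of bool, same shape
        True where the value is missing.
    protein_ids, sample_ids : list of str
        Unique row / column identifiers.
    scale : {"raw", "log2"}
        Whether ``values`` are raw intensities (non-negative where
        observed) or log2 abundances.
    """

    values: np.ndarray
    mask: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError("ids do not match matrix shape")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and np.any(self.values[~self.mask] < 0):
            raise ValueError("raw intensities must be non-negative where observed")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed(self) -> np.ndarray:
        """Values with missing cells as NaN (a copy)."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def observed_fraction(self) -> np.ndarray:
        """Per-protein fraction of observed (unmasked) samples."""
        return 1.0 - self.mask.mean(axis=1)

    def copy(self) -> "AbundanceMatrix":
        return replace(
            self,
            values=self.values.copy(),
            mask=self.mask.copy(),
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
        )

    def subset_proteins(self, keep: np.ndarray) -> "AbundanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            values=self.values[idx],
            mask=self.mask[idx],
            protein_ids=[self.protein_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, keep: np.ndarray) -> "AbundanceMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return replace(
            self,
            values=self.values[:, idx],
            mask=self.mask[:, idx],
            protein_ids=list(self.protein_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view (missing as NaN), proteins as rows."""
        return pd.DataFrame(self.observed(), index=self.protein_ids, columns=self.sample_ids)


def read_abundance_tsv(path, scale: str = "raw", zeros_missing: bool = False) -> AbundanceMatrix:
    """Read a proteins-as-rows TSV. With ``zeros_missing``, 0 cells are masked."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    if zeros_missing:
        mask |= values == 0.0
    values = np.where(mask, 0.0, values)
    return AbundanceMatrix(
        values=values,
        mask=mask,
        protein_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        scale=scale,
    )


def write_abundance_tsv(m: AbundanceMatrix, path, missing_as_zero: bool | None = None) -> None:
    """Write TSV; raw matrices default to the 0-for-missing convention."""
    if missing_as_zero is None:
        missing_as_zero = m.scale == "raw"
    if missing_as_zero:
        out = np.where(m.mask, 0.0, m.values)
        pd.DataFrame(out, index=m.protein_ids, columns=m.sample_ids).to_csv(path, sep="\t")
    else:
        m.to_frame().to_csv(path, sep="\t")
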