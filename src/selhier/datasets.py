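"""Replicate-level expression datasets over selenium conditions.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with one
row per (gene, selenite condition, replicate) and a positive ``abundance``
column (arbitrary units, qPCR-like), optionally with a ``normalized`` column
(abundance divided by the gene's mean at the no-added-selenium reference
condition).  :class:`ExpressionDataset` wraps the frame with schema
validation, per-condition summary statistics, and round-tripping CSV IO.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import hashlib

import numpy as np
import pandas as pd

__all__ = ["DatasetSchemaError", "ExpressionDataset", "read_dataset", "write_dataset"]

REQUIRED_COLUMNS = ("gene_id", "selenite_nM", "replicate", "abundance")
OPTIONAL_COLUMNS = ("normalized",)


class DatasetSchemaError(ValueError):
    """Raised when an expression table violates the dataset schema."""


@dataclass
class ExpressionDataset:
    """Validated replicate-level abundances over selenium conditions."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetSchemaError(f"missing column(s) {missing}")
        extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
        if extra:
            raise DatasetSchemaError(f"unexpected column(s) {extra}")
        if df["abundance"].isna().any() or (df["abundance"] <= 0).any():
            bad = df.index[df["abundance"].isna() | (df["abundance"] <= 0)][0]
            raise DatasetSchemaError(
                f"row {bad}, column 'abundance': values must be positive and non-missing"
            )
        if (df["selenite_nM"] < 0).any():
            bad = df.index[df["selenite_nM"] < 0][0]
            raise DatasetSchemaError(f"row {bad}, column 'selenite_nM': negative concentration")
        keys = df[["gene_id", "selenite_nM", "replicate"]]
        if keys.duplicated().any():
            bad = df.index[keys.duplicated()][0]
            raise DatasetSchemaError(
                f"row {bad}: duplicated (gene_id, selenite_nM, replicate) key"
            )
        self.df = df.reset_index(drop=True)

    # -- views --------------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene_id"].unique().tolist())

    @property
    def conditions(self) -> list[float]:
        return sorted(float(c) for c in self.df["selenite_nM"].unique())

    def gene_frame(self, gene_id: str) -> pd.DataFrame:
        out = self.df[self.df["gene_id"] == gene_id]
        if out.empty:
            raise KeyError(f"gene {gene_id!r} not in dataset")
        return out

    def condition_stats(self) -> pd.DataFrame:
        """Per gene x condition: n, mean, sd, se of the raw abundance (and of
        the normalized abundance when present)."""
        cols = ["abundance"] + (["normalized"] if "normalized" in self.df.columns else [])
        gb = self.df.groupby(["gene_id", "selenite_nM"], sort=True)
        stats = gb[cols].agg(["size", "mean", "std"])
        out = pd.DataFrame(index=stats.index)
        out["n"] = stats[("abundance", "size")].astype(int)
        for col in cols:
            out[f"{col}_mean"] = stats[(col, "mean")]
            out[f"{col}_sd"] = stats[(col, "std")].fillna(0.0)
            out[f"{col}_se"] = out[f"{col}_sd"] / np.sqrt(out["n"])
        return out.reset_index()

    def content_hash(self) -> str:
        """Stable digest of the dataset content (used to guard comparisons)."""
        df = self.df.sort_values(["gene_id", "selenite_nM", "replicate"]).reset_index(drop=True)
        payload = df[list(REQUIRED_COLUMNS)].round(12).to_csv(index=False).encode()
        return hashlib.md5(payload).hexdigest()

    # -- IO -----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionDataset":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - filesystem errors
            raise DatasetSchemaError(f"cannot read dataset {path}: {exc}") from exc
        return cls(df)


def read_dataset(path: str | Path) -> ExpressionDataset:
    """Read a dataset CSV (``gene_id,selenite_nM,replicate,abundance[,normalized]``)."""
    return ExpressionDataset.read(path)


def write_dataset(ds: ExpressionDataset, path: str | Path) -> None:
    ds.write(path)
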