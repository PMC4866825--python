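"""Titration datasets and their CSV representation.

A titration dataset holds one row per (Na⁺, Ni-NTA fraction) condition:
the mean normalized current over replicate bilayers, its SEM, and the
replicate count.  The on-disk format is a plain CSV with a fixed header:

    variant,na_mM,ni_nta_fraction,normalized_current_mean,sem,n_rep
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CSV_COLUMNS",
    "TitrationDataset",
    "read_titration_csv",
    "write_titration_csv",
]

CSV_COLUMNS = (
    "variant",
    "na_mM",
    "ni_nta_fraction",
    "normalized_current_mean",
    "sem",
    "n_rep",
)


@dataclass
class TitrationDataset:
    """Tidy collection of titration points, backed by a DataFrame."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing column(s): {missing}")
        df = self.frame.loc[:, list(CSV_COLUMNS)].reset_index(drop=True)
        for col in ("na_mM", "ni_nta_fraction", "normalized_current_mean", "sem"):
            vals = pd.to_numeric(df[col], errors="raise").astype(float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite value in column {col!r}")
            df[col] = vals
        df["n_rep"] = pd.to_numeric(df["n_rep"], errors="raise").astype(int)
        for col in ("na_mM", "sem"):
            if (df[col] < 0).any():
                raise ValueError(f"negative value in column {col!r}")
        bad = df.index[df["ni_nta_fraction"] < 0]
        if len(bad):
            raise ValueError(
                f"negative ni_nta_fraction at row {int(bad[0])}"
            )
        if (df["n_rep"] < 1).any():
            raise ValueError("n_rep must be >= 1")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TitrationDataset):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def variants(self) -> list[str]:
        return list(pd.unique(self.frame["variant"]))

    @property
    def variant_name(self) -> str:
        """The single variant this dataset covers; error if mixed."""
        names = self.variants
        if len(names) != 1:
            raise ValueError(f"dataset mixes variants: {names}")
        return names[0]

    @property
    def x_g(self) -> np.ndarray:
        return self.frame["ni_nta_fraction"].to_numpy()

    @property
    def na(self) -> np.ndarray:
        return self.frame["na_mM"].to_numpy()

    @property
    def mean_activity(self) -> np.ndarray:
        return self.frame["normalized_current_mean"].to_numpy()

    @property
    def sem(self) -> np.ndarray:
        return self.frame["sem"].to_numpy()

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        write_titration_csv(self, path)


def write_titration_csv(
    dataset: TitrationDataset, path: str | Path | io.TextIOBase
) -> None:
    """Write a dataset; shortest-exact float formatting for round-tripping."""
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def read_titration_csv(path: str | Path | io.TextIOBase) -> TitrationDataset:
    """Read a titration CSV, validating schema and values.

    Raises
    ------
    ValueError
        Missing column (named in the message) or invalid value (row
        number in the message).  CRLF and LF files parse identically.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"titration CSV missing required column(s): {missing}"
        )
    return TitrationDataset(df)
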