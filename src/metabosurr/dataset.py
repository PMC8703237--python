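"""The universal per-sample exchange object.

A :class:`CohortDataset` wraps a pandas DataFrame holding, per sample, the
metabolite concentrations, clinical variables, and cohort / family / survival
metadata. All pipeline stages consume and produce this object. On disk it is
a single UTF-8 tab-separated file with a header row and ``NA`` for missing
values; the column roles are recovered from the panel on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MetabolitePanel

#: columns with a fixed meaning; everything else is metabolite or clinical
ID_COLUMNS = ("sample_id", "cohort", "family_id", "sex", "age")
SURVIVAL_COLUMNS = ("time", "event")


@dataclass
class CohortDataset:
    """Per-sample metabolites + clinical variables + cohort metadata.

    ``df`` always contains ``sample_id`` and ``cohort``; ``family_id``,
    ``sex``, ``age``, ``time`` and ``event`` are optional. ``sex`` is coded
    1 = male, 0 = female.
    """

    df: pd.DataFrame
    metabolite_cols: list[str]
    clinical_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("sample_id", "cohort"):
            if col not in self.df.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        missing = [c for c in self.metabolite_cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"metabolite columns absent from data: {missing}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.df)

    @property
    def cohorts(self) -> list[str]:
        return list(pd.unique(self.df["cohort"]))

    def metabolites(self) -> pd.DataFrame:
        """Metabolite concentration matrix (samples x markers)."""
        return self.df[self.metabolite_cols]

    def metabolite_matrix(self) -> np.ndarray:
        return self.df[self.metabolite_cols].to_numpy(dtype=float)

    def has_survival(self) -> bool:
        return all(c in self.df.columns for c in SURVIVAL_COLUMNS)

    def replace(self, df: pd.DataFrame, metabolite_cols: list[str] | None = None,
                clinical_cols: list[str] | None = None) -> "CohortDataset":
        """A copy of this dataset around a new frame."""
        return CohortDataset(
            df=df,
            metabolite_cols=list(self.metabolite_cols if metabolite_cols is None
                                 else metabolite_cols),
            clinical_cols=list(self.clinical_cols if clinical_cols is None
                               else clinical_cols),
        )

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortDataset":
        return self.replace(self.df.loc[mask].reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as UTF-8 TSV with ``NA`` for missing values.

        Floats are written with ``repr`` precision so the round trip is
        bit-exact for float64 values.
        """
        ordered = self._ordered_columns()
        self.df[ordered].to_csv(path, sep="\t", index=False, na_rep="NA",
                                encoding="utf-8")

    def _ordered_columns(self) -> list[str]:
        cols = [c for c in ID_COLUMNS if c in self.df.columns]
        cols += self.metabolite_cols
        cols += [c for c in self.clinical_cols if c not in cols]
        cols += [c for c in SURVIVAL_COLUMNS if c in self.df.columns]
        rest = [c for c in self.df.columns if c not in cols]
        return cols + rest

    @classmethod
    def from_tsv(cls, path: str | Path, panel: MetabolitePanel,
                 clinical_cols: list[str] | None = None) -> "CohortDataset":
        """Read a dataset written by :meth:`to_tsv`.

        Metabolite columns are identified as the panel markers present in the
        file; remaining non-reserved columns are treated as clinical unless
        ``clinical_cols`` is given explicitly.
        """
        df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                         encoding="utf-8", float_precision="round_trip")
        met = [m for m in panel.names if m in df.columns]
        if clinical_cols is None:
            reserved = set(ID_COLUMNS) | set(SURVIVAL_COLUMNS) | set(met)
            clinical_cols = [c for c in df.columns if c not in reserved]
        return cls(df=df, metabolite_cols=met, clinical_cols=clinical_cols)
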