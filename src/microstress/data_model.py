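"""Sample tables and the fixed-point temporal encodings.

A :class:`SampleTable` is the flat input format of the whole pipeline:
one row per microcosm sample, five environmental feature columns
(encoded location, incubation time ×10, encoded oil type, incubation
temperature in °C, calendar month ×10), a sparse block of per-taxon
counts (``Bac_1 .. Bac_T``), plus the bottle identifier that groups
samples from the same physical microcosm — the unit held out during
grouped evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ENV_COLUMNS",
    "META_COLUMNS",
    "RawMetadata",
    "SampleTable",
    "scale_temporal",
    "read_sample_table",
    "write_sample_table",
]


class SchemaError(ValueError):
    """A required column is missing or misnamed."""


class ValidationError(ValueError):
    """Column contents violate a table invariant."""


#: environmental feature block, in canonical column order
ENV_COLUMNS = ["location_enc", "time_enc", "oil_enc", "temperature", "month_enc"]
META_COLUMNS = ["sample_id", "bottle_id"]

OIL_LABELS = ("no_oil", "crude", "diesel")


@dataclass(frozen=True)
class RawMetadata:
    """Un-encoded per-sample metadata (pre-autoencoder)."""

    latitude: float
    longitude: float
    oil_label: str
    month: int
    week: int

    def __post_init__(self):
        if self.oil_label not in OIL_LABELS:
            raise ValueError(f"oil_label must be one of {OIL_LABELS}, got {self.oil_label!r}")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.week < 0:
            raise ValueError(f"week must be >= 0, got {self.week}")


def scale_temporal(week: int, month: int) -> tuple[int, int]:
    """Fixed-point encoding of incubation week and calendar month.

    Both are multiplied by 10 (so August, month 8, encodes to 80).  The
    map is exactly invertible by integer division by 10.
    """
    if week < 0:
        raise ValueError(f"week must be >= 0, got {week}")
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return 10 * week, 10 * month


def taxa_columns(n_taxa: int) -> list[str]:
    return [f"Bac_{i}" for i in range(1, n_taxa + 1)]


class SampleTable:
    """Validated sample-by-feature table backed by a pandas DataFrame.

    Columns, in order: ``sample_id, bottle_id, location_enc, time_enc,
    oil_enc, temperature, month_enc, Bac_1, ..., Bac_T``.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        for col in META_COLUMNS + ENV_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        taxa = [c for c in df.columns if c.startswith("Bac_")]
        expected = taxa_columns(len(taxa))
        if taxa != expected:
            raise SchemaError(
                f"taxa columns must be named Bac_1..Bac_{len(taxa)} in order"
            )
        ordered = META_COLUMNS + ENV_COLUMNS + taxa
        extra = [c for c in df.columns if c not in ordered]
        if extra:
            raise SchemaError(f"unexpected columns: {extra}")
        df = df[ordered].reset_index(drop=True)
        if df[ENV_COLUMNS + taxa].isna().any().any() or df[META_COLUMNS].isna().any().any():
            raise ValidationError("missing values are not allowed")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if taxa:
            counts = df[taxa].to_numpy()
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("taxa counts must be integer-valued")
            if (counts < 0).any():
                raise ValidationError("taxa counts must be non-negative")
            df[taxa] = counts.astype(np.int64)
        for col in ENV_COLUMNS:
            df[col] = df[col].astype(float)
        df["sample_id"] = df["sample_id"].astype(str)
        df["bottle_id"] = df["bottle_id"].astype(str)
        return df

    # -- accessors -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.df)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_columns)

    @property
    def taxa_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("Bac_")]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def bottle_ids(self) -> np.ndarray:
        return self.df["bottle_id"].to_numpy()

    @property
    def env_matrix(self) -> np.ndarray:
        """The n×5 environmental feature block, canonical column order."""
        return self.df[ENV_COLUMNS].to_numpy(dtype=float)

    @property
    def counts(self) -> np.ndarray:
        """The n×T integer taxa count block."""
        return self.df[self.taxa_columns].to_numpy(dtype=np.int64)

    @property
    def oil_enc(self) -> np.ndarray:
        return self.df["oil_enc"].to_numpy(dtype=float)

    def subset(self, mask_or_index) -> "SampleTable":
        return SampleTable(self.df.loc[mask_or_index].reset_index(drop=True))

    def taxa_matrix(self, taxa_indices) -> np.ndarray:
        """Count columns for 1-based taxon indices, as float."""
        cols = [f"Bac_{i}" for i in taxa_indices]
        return self.df[cols].to_numpy(dtype=float)

    def equals(self, other: "SampleTable") -> bool:
        return self.df.equals(other.df)


def read_sample_table(path, n_taxa: int | None = None, delimiter: str = ",") -> SampleTable:
    """Read a delimited sample table; validates all invariants.

    ``n_taxa``, when given, is cross-checked against the taxa columns
    found in the header.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    table = SampleTable(df)
    if n_taxa is not None and table.n_taxa != n_taxa:
        raise SchemaError(f"expected {n_taxa} taxa columns, found {table.n_taxa}")
    return table


def write_sample_table(table: SampleTable, path, delimiter: str = ",") -> None:
    """Write a table so that :func:`read_sample_table` recovers it exactly.

    Floats are written with ``repr`` precision, so the round trip is
    value-exact; counts are written as integers.
    """
    table.df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
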