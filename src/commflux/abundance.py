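"""Genus-level abundance tables and sample metadata.

The central container is :class:`AbundanceTable`, a thin wrapper around a
samples × genera :class:`pandas.DataFrame` of non-negative counts or
proportions.  Sample metadata travels separately as a DataFrame indexed by
sample id with the columns ``subject_id, group, compartment, age, sex,
cohort`` (see :data:`METADATA_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["subject_id", "group", "compartment", "age", "sex", "cohort"]

#: row sums of a normalized table must match 1 to this tolerance
_NORMALIZED_ATOL = 1e-9


@dataclass
class AbundanceTable:
    """Samples × genera non-negative matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and genus ids as columns.
        Values are counts or relative abundances, all ``>= 0``.
    normalized:
        True when every row sums to 1 (relative abundances).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate genus ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if (values < 0).any():
            row, col = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative abundance at sample "
                f"{self.data.index[row]!r}, genus {self.data.columns[col]!r}"
            )
        if self.normalized:
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=_NORMALIZED_ATOL, rtol=0):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"normalized table row {bad!r} does not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Row-normalize counts to relative abundances.

    Idempotent on an already-normalized table.  A sample whose row sums to
    zero cannot be normalized and is reported by name.
    """
    if table.normalized:
        return table
    values = table.values
    sums = values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        names = [table.data.index[i] for i in zero]
        raise ValueError(f"cannot normalize all-zero sample(s): {names}")
    rel = values / sums[:, None]
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        normalized=True,
    )


def validate_metadata(metadata: pd.DataFrame, table: AbundanceTable | None = None) -> pd.DataFrame:
    """Check a metadata frame: required columns present, one record per sample."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if metadata.index.has_duplicates:
        raise ValueError("metadata has duplicate sample ids")
    if table is not None:
        absent = [s for s in table.sample_ids if s not in metadata.index]
        if absent:
            raise ValueError(f"samples without metadata record: {absent}")
    return metadata
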