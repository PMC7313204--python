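"""Count-table I/O, constant-sum normalization, and feature filtering.

Samples with different sequencing depths would otherwise contribute unequal
token counts to the LDA corpus, so every sample is rescaled to a common
constant (10,000 by default) with flooring to integers, and genera whose
floored counts are zero in every sample are dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountTable, RelativeAbundanceTable

DEFAULT_CONSTANT = 10_000


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (header = feature IDs, first column = sample IDs).

    The parse is lossless: ``read_count_table(write_count_table(t)) == t``.
    Raises ``ValueError`` naming the offending cell for non-integer or
    negative entries, and for duplicate sample/feature IDs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing cell at sample {df.index[i]!r}, feature {df.columns[j]!r} in {path}"
        )
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, j]!r} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r} in {path}"
        )
    values = numeric.to_numpy()
    if not np.array_equal(values, np.rint(values)):
        i, j = np.argwhere(values != np.rint(values))[0]
        raise ValueError(
            f"non-integer count {values[i, j]!r} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r} in {path}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[i]!r}, feature {df.columns[j]!r} in {path}"
        )
    return CountTable(list(df.index), list(df.columns), values.astype(np.int64))


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as TSV (tab-separated, UTF-8, no quoting)."""
    table.to_dataframe().to_csv(path, sep="\t", encoding="utf-8")


def normalize_to_constant(table: CountTable, constant: int = DEFAULT_CONSTANT) -> CountTable:
    """Rescale every sample to sum to ``constant``, flooring to integers.

    entry(i, j) = floor(counts(i, j) / rowtotal(i) * constant), computed in
    exact integer arithmetic. Each output row sums to at most ``constant``
    (flooring loses at most D-1 counts per row).
    """
    if constant < 1:
        raise ValueError("constant must be a positive integer")
    totals = table.row_totals()
    if (totals == 0).any():
        bad = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[bad]!r} has zero total count")
    scaled = (table.counts.astype(np.int64) * int(constant)) // totals[:, None]
    return CountTable(table.sample_ids, table.feature_ids, scaled)


def drop_empty_features(table: CountTable) -> CountTable:
    """Remove features whose column total is zero, preserving feature order."""
    keep = table.counts.sum(axis=0) > 0
    feature_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    return CountTable(table.sample_ids, feature_ids, table.counts[:, keep])


def to_relative_abundance(table: CountTable) -> RelativeAbundanceTable:
    """Convert counts to row-stochastic proportions (rows must be nonzero)."""
    totals = table.row_totals()
    if (totals == 0).any():
        bad = int(np.argmax(totals == 0))
        raise ValueError(f"sample {table.sample_ids[bad]!r} has zero total count")
    props = table.counts / totals[:, None]
    return RelativeAbundanceTable(table.sample_ids, table.feature_ids, props)
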