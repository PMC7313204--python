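"""In-memory containers for count and relative-abundance tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_ids(ids: list[str], kind: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {kind} IDs: {dupes[:5]}")
    return ids


@dataclass
class CountTable:
    """Sample x feature matrix of nonnegative integer read counts.

    ``counts[i, j]`` is the number of reads of feature ``feature_ids[j]``
    (a genus or a KEGG ortholog) observed in sample ``sample_ids[i]``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(list(self.sample_ids), "sample")
        self.feature_ids = _check_ids(list(self.feature_ids), "feature")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                bad = np.argwhere(rounded != counts)[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"feature {self.feature_ids[bad[1]]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class RelativeAbundanceTable:
    """Row-stochastic sample x feature proportions (each row sums to 1)."""

    sample_ids: list[str]
    feature_ids: list[str]
    proportions: np.ndarray

    _ROW_TOL: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(list(self.sample_ids), "sample")
        self.feature_ids = _check_ids(list(self.feature_ids), "feature")
        props = np.asarray(self.proportions, dtype=float)
        if props.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("proportions shape does not match IDs")
        if (props < 0).any() or (props > 1).any():
            raise ValueError("proportions must lie in [0, 1]")
        row_sums = props.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=self._ROW_TOL, rtol=0):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"row for sample {self.sample_ids[bad]!r} sums to {row_sums[bad]!r}, not 1"
            )
        self.proportions = props

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.feature_ids)
        df.index.name = "sample_id"
        return df
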