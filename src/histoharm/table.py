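"""Sample-by-feature table with aligned per-sample metadata.

The :class:`FeatureTable` is the central in-memory container of the
package: an ``n_samples x n_features`` real matrix plus a metadata frame
(sample_id, label, center, region, ...) aligned row-by-row.  All
harmonization and modelling operations consume and return this type and
are required to preserve row order and metadata alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: metadata columns given a default when absent
_META_DEFAULTS = {"label": "unknown", "center": "unknown", "region": "unknown"}


@dataclass
class FeatureTable:
    """Feature matrix with aligned sample metadata.

    Parameters
    ----------
    data
        ``n_samples x n_features`` frame; column names are the feature
        names (unique, order-significant).
    meta
        Per-sample metadata frame with at least a ``sample_id`` column;
        positionally aligned with ``data`` rows.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).reset_index(drop=True)
        self.data.columns = [str(c) for c in self.data.columns]
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(len(self.data))]}
            )
        self.meta = pd.DataFrame(self.meta).reset_index(drop=True)
        if len(self.meta) != len(self.data):
            raise ValueError(
                f"meta has {len(self.meta)} rows, data has {len(self.data)}"
            )
        if "sample_id" not in self.meta.columns:
            self.meta.insert(0, "sample_id", [f"s{i}" for i in range(len(self.data))])
        for col, default in _META_DEFAULTS.items():
            if col not in self.meta.columns:
                self.meta[col] = default
        names = list(self.data.columns)
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    # ------------------------------------------------------------------ basic
    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Feature values as a float ndarray (always a copy: pandas
        would otherwise hand back a mutable view of a single-block
        float frame)."""
        return self.data.to_numpy(dtype=float, copy=True)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.meta.copy())

    def with_matrix(self, values: np.ndarray) -> "FeatureTable":
        """New table with the same metadata/names but replaced values."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_samples, self.n_features):
            raise ValueError(
                f"shape {values.shape} != {(self.n_samples, self.n_features)}"
            )
        return FeatureTable(
            pd.DataFrame(values, columns=self.feature_names), self.meta.copy()
        )

    def take(self, indices: Sequence[int] | np.ndarray) -> "FeatureTable":
        """Row subset by positional indices (order preserved as given)."""
        idx = np.asarray(indices)
        return FeatureTable(
            self.data.iloc[idx].reset_index(drop=True),
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def labels(self, column: str = "label") -> np.ndarray:
        return self.meta[column].to_numpy()

    # ------------------------------------------------------------------ concat
    @staticmethod
    def concat(tables: Iterable["FeatureTable"]) -> "FeatureTable":
        tables = list(tables)
        names = tables[0].feature_names
        for t in tables[1:]:
            if t.feature_names != names:
                raise ValueError("feature names mismatch between tables")
        return FeatureTable(
            pd.concat([t.data for t in tables], ignore_index=True),
            pd.concat([t.meta for t in tables], ignore_index=True),
        )

    # ---------------------------------------------------------------------- io
    def to_parquet(self, path: str | Path) -> None:
        self._joined().to_parquet(path, index=False)

    def to_csv(self, path: str | Path) -> None:
        self._joined().to_csv(path, index=False)

    def _joined(self) -> pd.DataFrame:
        return pd.concat([self.meta.add_prefix("meta_"), self.data], axis=1)

    @staticmethod
    def read(path: str | Path) -> "FeatureTable":
        path = Path(path)
        if path.suffix in {".parquet", ".pq"}:
            df = pd.read_parquet(path)
        else:
            df = pd.read_csv(path)
        meta_cols = [c for c in df.columns if c.startswith("meta_")]
        meta = df[meta_cols].rename(columns={c: c[5:] for c in meta_cols})
        data = df.drop(columns=meta_cols)
        return FeatureTable(data, meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable(n_samples={self.n_samples}, n_features={self.n_features})"
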