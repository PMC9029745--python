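"""Tensorization of named radiomic feature vectors into pixel images.

A cohort radiomic table (patients x named features) is arranged on a fixed
``p1 x p2`` grid so that matrix ("tensor") discriminant methods can be
applied to it.  The default grid is 33 x 32, which holds a 1037-entry
feature vector with 19 zero-padded trailing cells.  The fill order is
row-major and is recorded in a :class:`FeatureIndexMap`, so every pixel of
a fitted model can be reported back as a named radiomic feature.

Per-feature min-max scaling to [0, 1] gives the grid pixel-image semantics;
the scaler is fit on training patients only during evaluation to avoid
information leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TensorizationError",
    "FeatureIndexMap",
    "FeatureScaler",
    "FeatureImageStack",
    "fit_scaler",
    "vector_to_image",
    "image_to_vector",
    "tensorize_table",
]


class TensorizationError(ValueError):
    """Raised for invalid grids, feature vectors, or non-numeric cells."""


@dataclass(frozen=True)
class FeatureIndexMap:
    """Bijection between feature names and grid cells (row-major fill).

    The first ``p`` cells (row-major order) hold the named features; the
    remaining ``p1*p2 - p`` cells are padding and always carry
    ``pad_value`` (0 by default).
    """

    feature_names: tuple[str, ...]
    p1: int
    p2: int
    fill_order: str = "row-major"
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.p1 < 1 or self.p2 < 1:
            raise TensorizationError("grid dimensions must be >= 1")
        if self.fill_order != "row-major":
            raise TensorizationError(f"unsupported fill order {self.fill_order!r}")
        p = len(self.feature_names)
        if p > self.p1 * self.p2:
            raise TensorizationError(
                f"{p} features do not fit a {self.p1}x{self.p2} grid"
            )
        if len(set(self.feature_names)) != p:
            raise TensorizationError("feature names must be unique")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_cells(self) -> int:
        return self.p1 * self.p2

    @property
    def n_padded(self) -> int:
        return self.n_cells - self.n_features

    def cell_of(self, name: str) -> tuple[int, int]:
        """Grid cell (row, col) occupied by feature ``name``."""
        try:
            flat = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return divmod(flat, self.p2)

    def name_of(self, row: int, col: int) -> str | None:
        """Feature name at cell (row, col); ``None`` for padded cells."""
        if not (0 <= row < self.p1 and 0 <= col < self.p2):
            raise TensorizationError(f"cell ({row}, {col}) outside grid")
        flat = row * self.p2 + col
        if flat >= self.n_features:
            return None
        return self.feature_names[flat]

    def to_json(self, path: str | Path | None = None) -> str:
        records = [
            {"feature": name, "row": i // self.p2, "col": i % self.p2}
            for i, name in enumerate(self.feature_names)
        ]
        payload = json.dumps(
            {
                "p1": self.p1,
                "p2": self.p2,
                "fill_order": self.fill_order,
                "pad_value": self.pad_value,
                "features": records,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FeatureIndexMap":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        names = [r["feature"] for r in obj["features"]]
        return cls(tuple(names), obj["p1"], obj["p2"], obj["fill_order"], obj["pad_value"])

    @classmethod
    def from_names(cls, names, p1: int, p2: int) -> "FeatureIndexMap":
        return cls(tuple(names), p1, p2)


def vector_to_image(vec: np.ndarray, index_map: FeatureIndexMap) -> np.ndarray:
    """Arrange a length-p feature vector on the grid (row-major, zero pad)."""
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1:
        raise TensorizationError("feature vector must be 1-D")
    if vec.size != index_map.n_features:
        raise TensorizationError(
            f"vector length {vec.size} != map feature count {index_map.n_features}"
        )
    flat = np.full(index_map.n_cells, index_map.pad_value, dtype=float)
    flat[: vec.size] = vec
    return flat.reshape(index_map.p1, index_map.p2)


def image_to_vector(img: np.ndarray, index_map: FeatureIndexMap) -> np.ndarray:
    """Exact inverse of :func:`vector_to_image` on the occupied cells."""
    img = np.asarray(img, dtype=float)
    if img.shape != (index_map.p1, index_map.p2):
        raise TensorizationError(
            f"image shape {img.shape} != grid ({index_map.p1}, {index_map.p2})"
        )
    return img.ravel()[: index_map.n_features].copy()


def _check_numeric(table: pd.DataFrame) -> None:
    for col in table.columns:
        series = table[col]
        if pd.api.types.is_numeric_dtype(series):
            if series.isna().any():
                patient = series.index[series.isna()][0]
                raise TensorizationError(
                    f"missing value for patient {patient!r}, feature {col!r}"
                )
            continue
        coerced = pd.to_numeric(series, errors="coerce")
        bad = coerced.isna()
        if bad.any():
            patient = series.index[bad][0]
            raise TensorizationError(
                f"non-numeric cell for patient {patient!r}, feature {col!r}: "
                f"{series[patient]!r}"
            )


@dataclass
class FeatureScaler:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""

    mins: pd.Series
    maxs: pd.Series
    clip: bool = True

    @property
    def ranges(self) -> pd.Series:
        return self.maxs - self.mins

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.mins.index if c not in table.columns]
        if missing:
            raise TensorizationError(f"table lacks fitted features: {missing[:3]} ...")
        values = table[self.mins.index].astype(float)
        rng = self.ranges.replace(0.0, np.nan)
        scaled = (values - self.mins) / rng
        scaled = scaled.fillna(0.0)  # constant features -> 0 by definition
        if self.clip:
            scaled = scaled.clip(0.0, 1.0)
        return scaled

    def inverse_transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        values = scaled[self.mins.index].astype(float)
        out = values * self.ranges + self.mins
        # constant features carry no information in scaled space; restore min
        const = self.ranges == 0.0
        if const.any():
            for col in self.ranges.index[const]:
                out[col] = self.mins[col]
        return out


def fit_scaler(table: pd.DataFrame, clip: bool = True) -> FeatureScaler:
    """Fit per-feature (min, max) on a radiomic table (n >= 2 patients)."""
    if len(table) < 2:
        raise TensorizationError("scaler requires at least 2 patients")
    _check_numeric(table)
    values = table.astype(float)
    return FeatureScaler(values.min(axis=0), values.max(axis=0), clip=clip)


@dataclass
class FeatureImageStack:
    """n x p1 x p2 image stack plus the index map that produced it."""

    values: np.ndarray
    index_map: FeatureIndexMap
    patient_ids: tuple
    scaler: FeatureScaler | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (
            self.index_map.p1,
            self.index_map.p2,
        ):
            raise TensorizationError("stack shape inconsistent with index map")
        if self.values.shape[0] != len(self.patient_ids):
            raise TensorizationError("patient id count != stack size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_table(self) -> pd.DataFrame:
        """Regenerate the radiomic table (exact round trip of the stack)."""
        rows = [image_to_vector(img, self.index_map) for img in self.values]
        return pd.DataFrame(
            np.asarray(rows),
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=list(self.index_map.feature_names),
        )


def tensorize_table(
    table: pd.DataFrame,
    p1: int,
    p2: int,
    scaler: FeatureScaler | None = None,
) -> FeatureImageStack:
    """Convert a radiomic table into an image stack.

    If a fitted :class:`FeatureScaler` is given the table is min-max scaled
    first (training-set parameters), otherwise raw values are used.
    """
    if table.shape[1] > p1 * p2:
        raise TensorizationError(
            f"{table.shape[1]} features exceed the {p1}x{p2} grid"
        )
    _check_numeric(table)
    data = scaler.transform(table) if scaler is not None else table.astype(float)
    index_map = FeatureIndexMap(tuple(data.columns), p1, p2)
    imgs = np.stack([vector_to_image(row.to_numpy(), index_map) for _, row in data.iterrows()])
    return FeatureImageStack(imgs, index_map, tuple(table.index), scaler=scaler)
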