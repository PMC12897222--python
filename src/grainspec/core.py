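"""Core containers for single-kernel NIR hyperspectral analysis.

The coordinate system of every spectrum in the package is a
:class:`WavelengthGrid` of band centers in nanometres.  Images live in a
:class:`Hypercube` (rows x cols x bands), segmented kernels in a
:class:`KernelMask`, and extracted per-kernel spectra in a
:class:`SpectraMatrix` (samples x bands, optional binary labels with
0 = healthy, 1 = infested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or header does not conform to the expected format."""


class DimensionError(ValueError):
    """Array shapes or grids are inconsistent."""


class ParameterError(ValueError):
    """An operation received an invalid parameter."""


class DegenerateRowError(ValueError):
    """A spectrum row is degenerate for the requested transform."""


DEFAULT_N_BANDS = 256
DEFAULT_RANGE_NM = (850.0, 1700.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers in nm.

    The default grid mirrors a 256-channel SWIR imager covering
    approximately 850-1700 nm.
    """

    nm: np.ndarray

    def __post_init__(self):
        nm = np.asarray(self.nm, dtype=float)
        if nm.ndim != 1 or nm.size < 2:
            raise ParameterError("wavelength grid needs at least 2 bands")
        if not np.all(np.diff(nm) > 0):
            raise ParameterError("wavelengths must be strictly increasing")
        object.__setattr__(self, "nm", nm)

    @classmethod
    def default(cls, n_bands: int = DEFAULT_N_BANDS,
                lo_nm: float = DEFAULT_RANGE_NM[0],
                hi_nm: float = DEFAULT_RANGE_NM[1]) -> "WavelengthGrid":
        return cls(np.linspace(lo_nm, hi_nm, n_bands))

    def __len__(self) -> int:
        return int(self.nm.size)

    @property
    def step_nm(self) -> float:
        """Mean band spacing in nm."""
        return float(np.mean(np.diff(self.nm)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.nm)
        return bool(np.allclose(d, d[0], rtol=1e-8, atol=1e-9))

    def indices_in_window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """0-based indices of bands with lo_nm <= center <= hi_nm."""
        return np.where((self.nm >= lo_nm) & (self.nm <= hi_nm))[0]

    def __eq__(self, other) -> bool:  # value equality, not identity
        return isinstance(other, WavelengthGrid) and np.array_equal(self.nm, other.nm)

    def __hash__(self):
        return hash(self.nm.tobytes())


@dataclass
class Hypercube:
    """Hyperspectral image stack, rows x cols x bands.

    ``kind`` distinguishes raw sensor counts (non-negative) from
    black/white-corrected reflectance.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"  # {"raw", "reflectance"}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError("hypercube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.grid):
            raise DimensionError(
                f"cube has {self.data.shape[2]} bands but grid has {len(self.grid)}")
        if self.kind not in ("raw", "reflectance"):
            raise ParameterError(f"unknown cube kind {self.kind!r}")
        if self.kind == "raw" and np.any(self.data < 0):
            raise ParameterError("raw cube contains negative counts")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ParameterError("reflectance cube contains non-finite values")

    @property
    def shape(self):
        return self.data.shape

    @property
    def spatial_shape(self):
        return self.data.shape[:2]


@dataclass
class KernelMask:
    """Labelled kernel image: 0 = background, 1..K = kernel ids."""

    labels: np.ndarray
    threshold: Optional[float] = None  # binarization threshold, for the log

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DimensionError("mask must be a 2-D label image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("mask labels must be integers")
        present = np.unique(self.labels)
        k = int(present.max(initial=0))
        expected = np.arange(0, k + 1)
        if not np.array_equal(np.union1d(present, [0]), expected):
            raise ParameterError("labels must be {0} plus contiguous 1..K")

    @property
    def n_kernels(self) -> int:
        return int(self.labels.max(initial=0))

    def pixel_counts(self) -> np.ndarray:
        """Pixels per kernel, index k-1 for label k."""
        return np.bincount(self.labels.ravel(), minlength=self.n_kernels + 1)[1:]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.labels, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "KernelMask":
        return cls(np.loadtxt(path, dtype=int, delimiter=",", ndmin=2))


@dataclass
class SpectraMatrix:
    """N samples x B bands reflectance table with optional binary labels."""

    X: np.ndarray
    grid: WavelengthGrid
    labels: Optional[np.ndarray] = None
    ids: Optional[Sequence] = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("spectra matrix contains non-finite values")
        if self.X.shape[1] != len(self.grid):
            raise DimensionError(
                f"matrix has {self.X.shape[1]} bands but grid has {len(self.grid)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.X.shape[0],):
                raise DimensionError("labels length must equal sample count")
            if not np.isin(self.labels, [0, 1]).all():
                raise ParameterError("labels must be 0 (healthy) or 1 (infested)")
        if self.ids is None:
            self.ids = list(range(1, self.X.shape[0] + 1))
        elif len(self.ids) != self.X.shape[0]:
            raise DimensionError("ids length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def with_X(self, X: np.ndarray) -> "SpectraMatrix":
        """Same metadata, new values (e.g. after preprocessing)."""
        return SpectraMatrix(X=np.asarray(X, dtype=float), grid=self.grid,
                             labels=None if self.labels is None else self.labels.copy(),
                             ids=list(self.ids))

    def subset_rows(self, idx) -> "SpectraMatrix":
        idx = np.asarray(idx)
        return SpectraMatrix(self.X[idx], self.grid,
                             None if self.labels is None else self.labels[idx],
                             [self.ids[i] for i in idx])

    def subset_bands(self, band_idx) -> "SpectraMatrix":
        band_idx = np.asarray(band_idx, dtype=int)
        return SpectraMatrix(self.X[:, band_idx], WavelengthGrid(self.grid.nm[band_idx]),
                             None if self.labels is None else self.labels.copy(),
                             list(self.ids))

    # -- CSV schema: id, [label,] one column per wavelength ("%.1f" nm) --

    def to_csv(self, path) -> None:
        cols = {"id": list(self.ids)}
        if self.labels is not None:
            cols["label"] = self.labels
        for j, w in enumerate(self.grid.nm):
            cols[f"{w:.1f}"] = self.X[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise FormatError("spectra CSV must have an 'id' column")
        ids = df["id"].tolist()
        labels = df["label"].to_numpy() if "label" in df.columns else None
        wave_cols = [c for c in df.columns if c not in ("id", "label")]
        try:
            nm = np.array([float(c) for c in wave_cols])
        except ValueError as e:
            raise FormatError(f"non-numeric wavelength column: {e}") from e
        return cls(df[wave_cols].to_numpy(dtype=float), WavelengthGrid(nm),
                   labels=labels, ids=ids)


def as_array(X) -> np.ndarray:
    """Accept a SpectraMatrix or a 2-D array; return the ndarray view."""
    if isinstance(X, SpectraMatrix):
        return X.X
    return np.atleast_2d(np.asarray(X, dtype=float))
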