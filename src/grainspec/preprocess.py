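"""Row-wise spectral preprocessing transforms.

Seven standard chemometric transforms plus the identity, applied spectrum
by spectrum: Savitzky-Golay smoothing and first/second derivatives,
multiplicative scatter correction (MSC), standard normal variate (SNV),
polynomial detrending, and asymmetric-least-squares baseline correction.

Statistics that depend on the data collection (the MSC reference) are
fitted on a training set and frozen for transforming new spectra; use
:class:`Preprocessor` for that protocol and the plain functions for
one-shot transforms.

Standard deviations use the sample convention (ddof = 1) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .core import (DegenerateRowError, ParameterError, SpectraMatrix, as_array)

log = logging.getLogger(__name__)

METHODS = ("raw", "sg", "sg_fd", "sg_sd", "msc", "snv", "detrend", "baseline")


@dataclass
class PreprocessSpec:
    """Serializable description of one preprocessing transform.

    Defaults follow common NIR practice: SG window 11 / polyorder 2,
    detrend order 2, ALS baseline with smoothness 1e5, asymmetry 0.01
    and 10 reweighting iterations.
    """

    method: str = "raw"
    window: int = 11
    polyorder: int = 2
    detrend_order: int = 2
    baseline_lam: float = 1e5
    baseline_p: float = 0.01
    baseline_iter: int = 10

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(f"unknown preprocessing method {self.method!r}")
        if self.method in ("sg", "sg_fd", "sg_sd"):
            _check_sg(self.window, self.polyorder)
        if self.method == "baseline":
            if not (self.baseline_lam > 0 and 0 < self.baseline_p < 1
                    and self.baseline_iter >= 1):
                raise ParameterError("invalid baseline parameters")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(**d)


def _check_sg(window: int, polyorder: int):
    if window % 2 == 0:
        raise ParameterError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError(
            f"SG window ({window}) must exceed polyorder ({polyorder})")


def _wrap(X, out):
    if isinstance(X, SpectraMatrix):
        return X.with_X(out)
    return out


def sg_smooth(X, window: int = 11, polyorder: int = 2):
    """Savitzky-Golay smoothing: local least-squares polynomial fit."""
    arr = as_array(X)
    _check_sg(window, polyorder)
    if window > arr.shape[1]:
        raise ParameterError("SG window exceeds band count")
    out = savgol_filter(arr, window, polyorder, axis=1, mode="interp")
    return _wrap(X, out)


def sg_derivative(X, window: int = 11, polyorder: int = 2, order: int = 1,
                  grid=None):
    """Savitzky-Golay derivative with respect to wavelength (per nm).

    ``grid`` (a WavelengthGrid) supplies the band spacing; without it the
    derivative is per band index.  Non-uniform grids use the mean step
    with a warning.
    """
    arr = as_array(X)
    _check_sg(window, polyorder)
    if order not in (1, 2):
        raise ParameterError("derivative order must be 1 or 2")
    if polyorder < order:
        raise ParameterError("polyorder must be >= derivative order")
    if window > arr.shape[1]:
        raise ParameterError("SG window exceeds band count")
    if grid is None and isinstance(X, SpectraMatrix):
        grid = X.grid
    if grid is None:
        delta = 1.0
    else:
        if not grid.is_uniform:
            log.warning("sg_derivative: non-uniform grid, using mean step %.4g nm",
                        grid.step_nm)
        delta = grid.step_nm
    out = savgol_filter(arr, window, polyorder, deriv=order, delta=delta,
                        axis=1, mode="interp")
    return _wrap(X, out)


def msc(X, reference: Optional[np.ndarray] = None, return_coef: bool = False):
    """Multiplicative scatter correction.

    Each spectrum is regressed on the reference, x ~ a + b*ref (ordinary
    least squares over bands), and corrected to (x - a)/b.  The reference
    defaults to the column mean of X; pass a frozen training reference
    when transforming held-out spectra.  Rows with |b| < 1e-12 are left
    uncorrected with a warning.
    """
    arr = as_array(X)
    if reference is None:
        if arr.shape[0] < 2:
            raise ParameterError("MSC needs >= 2 rows when no reference is given")
        reference = arr.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (arr.shape[1],):
        raise ParameterError("MSC reference length must equal band count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateRowError("MSC reference has zero variance")
    b = (arr - arr.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = arr.mean(axis=1) - b * ref.mean()
    out = np.empty_like(arr)
    bad = np.abs(b) < 1e-12
    if bad.any():
        log.warning("msc: %d row(s) with |b| < 1e-12 left uncorrected",
                    int(bad.sum()))
    safe_b = np.where(bad, 1.0, b)
    out = (arr - a[:, None]) / safe_b[:, None]
    out[bad] = arr[bad]
    wrapped = _wrap(X, out)
    if return_coef:
        return wrapped, a, b
    return wrapped


def snv(X):
    """Standard normal variate: per-row centering and unit scaling (ddof=1)."""
    arr = as_array(X)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd.ravel() == 0)[0]
    if zero.size:
        raise DegenerateRowError(
            f"SNV: zero-variance row(s) {zero.tolist()}")
    return _wrap(X, (arr - mu) / sd)


def _poly_design(n_bands: int, order: int, grid=None) -> np.ndarray:
    x = grid.nm if grid is not None else np.arange(n_bands, dtype=float)
    # rescale to [-1, 1] for conditioning
    x = 2 * (x - x.min()) / (x.max() - x.min()) - 1
    return np.vander(x, order + 1, increasing=True)


def detrend(X, polyorder: int = 2, grid=None):
    """Subtract the per-row least-squares polynomial of the wavelength."""
    arr = as_array(X)
    if polyorder >= arr.shape[1]:
        raise ParameterError("detrend polyorder must be < band count")
    if grid is None and isinstance(X, SpectraMatrix):
        grid = X.grid
    V = _poly_design(arr.shape[1], polyorder, grid)
    coefs, *_ = np.linalg.lstsq(V, arr.T, rcond=None)
    return _wrap(X, arr - (V @ coefs).T)


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline of a single spectrum.

    Minimises sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2 with asymmetric
    weights w_i = p where y > z (peaks) and 1-p where y <= z, iterated
    ``n_iter`` times (Eilers-style penalized smoother).
    """
    n = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        Wm = sp.diags(w, 0, format="csc")
        z = spsolve(Wm + penalty, w * y)
        w_new = np.where(y > z, p, 1 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def baseline_correct(X, lam: float = 1e5, p: float = 0.01, n_iter: int = 10):
    """Subtract an asymmetric-least-squares baseline from each row."""
    if not (lam > 0 and 0 < p < 1 and n_iter >= 1):
        raise ParameterError("invalid baseline parameters")
    arr = as_array(X)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = arr[i] - als_baseline(arr[i], lam, p, n_iter)
    return _wrap(X, out)


class Preprocessor:
    """Fit-on-train / transform-anywhere wrapper around one PreprocessSpec.

    Only MSC carries state (the training reference spectrum); every other
    method is stateless and ``fit`` just records the spec.
    """

    def __init__(self, spec: PreprocessSpec):
        self.spec = spec
        self.msc_reference_: Optional[np.ndarray] = None

    def fit(self, X) -> "Preprocessor":
        if self.spec.method == "msc":
            self.msc_reference_ = as_array(X).mean(axis=0)
        return self

    def transform(self, X):
        s = self.spec
        if s.method == "raw":
            return _wrap(X, as_array(X).copy())
        if s.method == "sg":
            return sg_smooth(X, s.window, s.polyorder)
        if s.method == "sg_fd":
            return sg_derivative(X, s.window, s.polyorder, order=1)
        if s.method == "sg_sd":
            return sg_derivative(X, s.window, max(s.polyorder, 2), order=2)
        if s.method == "msc":
            if self.msc_reference_ is None:
                raise ParameterError("MSC preprocessor not fitted")
            return msc(X, reference=self.msc_reference_)
        if s.method == "snv":
            return snv(X)
        if s.method == "detrend":
            return detrend(X, s.detrend_order)
        if s.method == "baseline":
            return baseline_correct(X, s.baseline_lam, s.baseline_p,
                                    s.baseline_iter)
        raise ParameterError(f"unknown method {s.method!r}")

    def fit_transform(self, X):
        return self.fit(X).transform(X)


def apply_spec(X, spec: PreprocessSpec):
    """One-shot dispatcher: fit the spec on X and transform X."""
    return Preprocessor(spec).fit_transform(X)
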