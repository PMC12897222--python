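"""Reflectance correction, kernel segmentation and ROI spectrum extraction.

The single-kernel workflow: a raw push-broom cube is corrected against
white/dark reference cubes, R = (I0 - B) / (W - B); kernels are segmented
from the corrected image (Otsu threshold on a grayscale band image, then
4-connected components); and each kernel's mean pixel spectrum becomes one
row of a SpectraMatrix.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .core import (DimensionError, Hypercube, KernelMask, ParameterError,
                   SpectraMatrix)

log = logging.getLogger(__name__)

#: denominator floor, as a fraction of the white-reference dynamic range
EPS_FRACTION = 1e-6


def reflectance_correct(raw: Hypercube, white: Hypercube, dark: Hypercube,
                        clip: bool = False) -> Hypercube:
    """Black-and-white reflectance correction R = (I0 - B) / (W - B).

    All three cubes must be raw, share shape and wavelength grid.  Pixels
    where the white and dark references (nearly) coincide are floored at a
    small fraction of the white dynamic range and counted in the log.
    With ``clip=True`` the result is clipped to [0, 1.2].
    """
    for name, cube in (("raw", raw), ("white", white), ("dark", dark)):
        if cube.kind != "raw":
            raise ParameterError(f"{name} cube must have kind='raw'")
    if not (raw.shape == white.shape == dark.shape):
        raise DimensionError("raw/white/dark cubes must share shape")
    if not (raw.grid == white.grid == dark.grid):
        raise DimensionError("raw/white/dark cubes must share wavelength grid")

    denom = white.data - dark.data
    dyn = float(np.max(np.abs(denom)))
    eps = EPS_FRACTION * (dyn if dyn > 0 else 1.0)
    n_floored = int(np.count_nonzero(denom < eps))
    if n_floored:
        log.warning("reflectance_correct: %d pixel-bands with W-B < eps "
                    "floored at %.3g", n_floored, eps)
    refl = (raw.data - dark.data) / np.maximum(denom, eps)
    if clip:
        refl = np.clip(refl, 0.0, 1.2)
    return Hypercube(data=refl, grid=raw.grid, kind="reflectance")


def segment_kernels(cube: Hypercube,
                    band: Union[int, str] = "mean",
                    min_area_px: int = 10) -> KernelMask:
    """Segment bright kernels from a reflectance cube.

    A grayscale image (one band, or the band mean with ``band="mean"``) is
    binarized by Otsu's threshold; 4-connected components with area >=
    ``min_area_px`` become kernels, labelled 1..K in row-major centroid
    order.  Touching kernels are not split.  An empty foreground yields
    K = 0 with a warning rather than an error.
    """
    if cube.kind != "reflectance":
        raise ParameterError("segmentation expects a reflectance cube")
    if band == "mean":
        gray = cube.data.mean(axis=2)
    else:
        gray = cube.data[:, :, int(band)]
    if np.ptp(gray) == 0:
        log.warning("segment_kernels: flat image, no kernels found")
        return KernelMask(np.zeros(gray.shape, dtype=int), threshold=None)
    thr = float(threshold_otsu(gray))
    binary = gray > thr
    if not binary.any():
        log.warning("segment_kernels: empty foreground at Otsu threshold %.4g", thr)
        return KernelMask(np.zeros(gray.shape, dtype=int), threshold=thr)
    raw_labels = cc_label(binary, connectivity=1)
    props = [p for p in regionprops(raw_labels) if p.area >= min_area_px]
    # deterministic numbering: row-major by centroid
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros(gray.shape, dtype=int)
    for new_id, p in enumerate(props, start=1):
        out[raw_labels == p.label] = new_id
    if not props:
        log.warning("segment_kernels: all components below min_area_px=%d",
                    min_area_px)
    log.info("segment_kernels: threshold=%.6g, K=%d", thr, len(props))
    return KernelMask(out, threshold=thr)


def extract_mean_spectra(cube: Hypercube, mask: KernelMask,
                         ids: Optional[list] = None,
                         labels: Optional[np.ndarray] = None) -> SpectraMatrix:
    """Per-kernel ROI mean spectra.

    Row k of the result is the arithmetic mean, band by band, of the pixel
    spectra with mask label k (the ROI-average spectrum of kernel k).
    """
    if cube.kind != "reflectance":
        raise ParameterError("extraction expects a reflectance cube")
    if mask.labels.shape != cube.spatial_shape:
        raise DimensionError("mask shape does not match cube spatial shape")
    k = mask.n_kernels
    if k == 0:
        raise ParameterError("mask contains no kernels (K = 0)")
    X = np.empty((k, cube.shape[2]))
    for lab in range(1, k + 1):
        region = cube.data[mask.labels == lab]  # (n_pixels, bands)
        X[lab - 1] = region.mean(axis=0)
    return SpectraMatrix(X=X, grid=cube.grid,
                         labels=labels,
                         ids=ids if ids is not None else list(range(1, k + 1)))
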