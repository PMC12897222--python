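"""Synthetic single-kernel NIR spectra and hyperspectral cubes.

The generator emulates the statistical structure of reflectance spectra
from wheat kernels imaged at 850-1700 nm: a smooth base reflectance
profile with water/starch absorption dips, class differences confined to
smooth raised-cosine bumps inside configurable wavelength windows
(defaults: 980-1100, 1200-1300 and 1400-1600 nm, where infested and
healthy kernels separate), per-sample multiplicative/additive scatter,
a slowly varying polynomial baseline drift, and white noise:

    x = gain * (base + label*effect + baseline) + offset + noise

Ground truth (labels, informative band indices, per-sample scatter,
noiseless class means) is returned alongside the data so that every
selector and classifier can be scored against a known answer.

``generate_cube`` additionally paints per-kernel spectra into elliptical
regions of a raw-count hypercube with matching white/dark reference
cubes, exercising the full correction -> segmentation -> extraction
imaging path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (Hypercube, KernelMask, ParameterError, SpectraMatrix,
                   WavelengthGrid)

#: default class-difference windows (lo_nm, hi_nm, amplitude)
DEFAULT_WINDOWS = ((980.0, 1100.0, 0.02),
                   (1200.0, 1300.0, 0.02),
                   (1400.0, 1600.0, 0.02))


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the full-scale acquisition conditions.

    369 infested vs 220 healthy kernels, 256 bands over 850-1700 nm,
    class effect amplitude 0.02 reflectance units inside the three
    windows, lognormal gain scatter (sigma 0.05), additive offset
    scatter (sd 0.01), degree-2 baseline drift and white noise
    (sd 0.005).
    """

    n_healthy: int = 220
    n_infested: int = 369
    n_bands: int = 256
    lo_nm: float = 850.0
    hi_nm: float = 1700.0
    effect_windows: Sequence[Tuple[float, float, float]] = DEFAULT_WINDOWS
    gain_sd: float = 0.05          # sigma of lognormal multiplicative gain
    offset_sd: float = 0.01        # sd of additive offset
    baseline_sd: float = 0.005     # sd of baseline polynomial coefficients
    baseline_degree: int = 2
    noise_sd: float = 0.005        # per-band white noise sd
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy < 1 or self.n_infested < 1:
            raise ParameterError("class counts must be >= 1")
        if self.n_bands < 2:
            raise ParameterError("need at least 2 bands")
        for lo, hi, amp in self.effect_windows:
            if not (self.lo_nm <= lo < hi <= self.hi_nm):
                raise ParameterError(
                    f"effect window ({lo}, {hi}) outside grid range")
        for name in ("gain_sd", "offset_sd", "baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(np.linspace(self.lo_nm, self.hi_nm, self.n_bands))

    @property
    def n_samples(self) -> int:
        return self.n_healthy + self.n_infested

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_windows"] = [list(w) for w in self.effect_windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "effect_windows" in d:
            d["effect_windows"] = [tuple(w) for w in d["effect_windows"]]
        return cls(**d)

    def with_planted_bands(self, band_indices: Sequence[int],
                           amplitude: float = 0.02) -> "SynthConfig":
        """Replace the effect windows with single-band bumps.

        Each window is centered on one band and narrower than the band
        spacing, so the set of informative bands is exactly
        ``band_indices`` — an unambiguous target for selector-recovery
        scoring.
        """
        nm = self.grid.nm
        half = 0.45 * float(np.min(np.diff(nm)))
        windows = tuple((float(nm[j] - half), float(nm[j] + half), amplitude)
                        for j in sorted(band_indices))
        d = self.to_dict()
        d["effect_windows"] = [list(w) for w in windows]
        return SynthConfig.from_dict(d)


@dataclass
class SynthTruth:
    """Everything needed to score a downstream method against the generator."""

    labels: np.ndarray
    informative_band_indices: np.ndarray
    gains: np.ndarray
    offsets: np.ndarray
    healthy_mean: np.ndarray     # noiseless, scatter-free class mean
    infested_mean: np.ndarray
    base: np.ndarray
    effect: np.ndarray

    def to_json(self, path=None) -> str:
        payload = {"labels": self.labels.tolist(),
                   "informative_band_indices":
                       self.informative_band_indices.tolist(),
                   "gains": self.gains.tolist(),
                   "offsets": self.offsets.tolist(),
                   "healthy_mean": self.healthy_mean.tolist(),
                   "infested_mean": self.infested_mean.tolist()}
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def base_profile(nm: np.ndarray) -> np.ndarray:
    """Smooth kernel reflectance: broad hump with absorption dips.

    Gaussian dips near 970, 1200 and 1450 nm stand in for the water and
    C-H/O-H overtone bands of a wheat kernel; values stay in ~0.25-0.65.
    """
    def dip(center, width, depth):
        return depth * np.exp(-0.5 * ((nm - center) / width) ** 2)

    return (0.60
            - dip(970.0, 45.0, 0.08)
            - dip(1200.0, 55.0, 0.05)
            - dip(1450.0, 70.0, 0.18)
            - 1e-4 * (nm - 850.0) * 0.2)


def effect_profile(nm: np.ndarray,
                   windows: Sequence[Tuple[float, float, float]]) -> np.ndarray:
    """Sum of raised-cosine bumps, one per (lo, hi, amplitude) window."""
    effect = np.zeros_like(nm)
    for lo, hi, amp in windows:
        inside = (nm >= lo) & (nm <= hi)
        phase = (nm[inside] - lo) / (hi - lo)
        effect[inside] += amp * 0.5 * (1 - np.cos(2 * np.pi * phase))
    return effect


def generate_spectra(cfg: SynthConfig) -> Tuple[SpectraMatrix, SynthTruth]:
    """Draw a labelled SpectraMatrix and its ground truth.

    Bitwise reproducible from ``cfg.seed``.  Labels are 0 (healthy) for
    the first ``n_healthy`` rows and 1 (infested) for the rest.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    nm = grid.nm
    base = base_profile(nm)
    effect = effect_profile(nm, cfg.effect_windows)
    n = cfg.n_samples
    labels = np.concatenate([np.zeros(cfg.n_healthy, dtype=int),
                             np.ones(cfg.n_infested, dtype=int)])
    gains = np.exp(rng.normal(0.0, cfg.gain_sd, size=n)) if cfg.gain_sd > 0 \
        else np.ones(n)
    offsets = rng.normal(0.0, cfg.offset_sd, size=n) if cfg.offset_sd > 0 \
        else np.zeros(n)
    # baseline drift: low-order polynomial in scaled wavelength
    t = 2 * (nm - nm.min()) / (nm.max() - nm.min()) - 1
    if cfg.baseline_sd > 0:
        coefs = rng.normal(0.0, cfg.baseline_sd,
                           size=(n, cfg.baseline_degree + 1))
        baselines = coefs @ np.vander(t, cfg.baseline_degree + 1,
                                      increasing=True).T
    else:
        baselines = np.zeros((n, nm.size))
    clean = base[None, :] + labels[:, None] * effect[None, :] + baselines
    X = gains[:, None] * clean + offsets[:, None]
    if cfg.noise_sd > 0:
        X = X + rng.normal(0.0, cfg.noise_sd, size=X.shape)
    informative = np.where(np.abs(effect) > 1e-12)[0]
    truth = SynthTruth(labels=labels,
                       informative_band_indices=informative,
                       gains=gains, offsets=offsets,
                       healthy_mean=base.copy(),
                       infested_mean=base + effect,
                       base=base, effect=effect)
    matrix = SpectraMatrix(X=X, grid=grid, labels=labels,
                           ids=[f"s{i+1}" for i in range(n)])
    return matrix, truth


# --------------------------------------------------------------------------
# Synthetic hypercubes
# --------------------------------------------------------------------------

@dataclass
class CubeLayout:
    """Elliptical kernel placement on the imaging plate.

    ``ellipses`` holds (row_center, col_center, row_radius, col_radius)
    per kernel.  ``auto`` lays kernels out on a regular grid, mimicking
    kernels spaced on a plate, so they never touch.
    """

    image_shape: Tuple[int, int]
    ellipses: List[Tuple[float, float, float, float]]

    def __post_init__(self):
        rows, cols = self.image_shape
        for r, c, rr, rc in self.ellipses:
            if not (rr > 0 and rc > 0):
                raise ParameterError("ellipse radii must be positive")
            if r - rr < 0 or r + rr >= rows or c - rc < 0 or c + rc >= cols:
                raise ParameterError("ellipse outside image bounds")
        masks = [self._ellipse_mask(e) for e in self.ellipses]
        total = np.zeros(self.image_shape, dtype=int)
        for m in masks:
            total += m
        if np.any(total > 1):
            raise ParameterError("ellipses overlap")

    def _ellipse_mask(self, ellipse) -> np.ndarray:
        r, c, rr, rc = ellipse
        rows, cols = self.image_shape
        ri, ci = np.ogrid[:rows, :cols]
        return (((ri - r) / rr) ** 2 + ((ci - c) / rc) ** 2 <= 1.0).astype(int)

    @classmethod
    def auto(cls, n_kernels: int, image_shape: Tuple[int, int] = (64, 96),
             radius: Tuple[float, float] = (6.0, 4.0)) -> "CubeLayout":
        rows, cols = image_shape
        rr, rc = radius
        pitch_r, pitch_c = int(4 * rr), int(4 * rc)
        per_row = max(1, (cols - pitch_c) // pitch_c)
        ellipses = []
        for k in range(n_kernels):
            gr, gc = divmod(k, per_row)
            r = pitch_r * (gr + 1)
            c = pitch_c * (gc + 1)
            if r + rr >= rows or c + rc >= cols:
                raise ParameterError(
                    f"cannot place {n_kernels} kernels in image {image_shape}")
            ellipses.append((float(r), float(c), rr, rc))
        return cls(image_shape=image_shape, ellipses=ellipses)

    def truth_mask(self) -> KernelMask:
        """Label image with kernels numbered row-major by centroid."""
        order = sorted(range(len(self.ellipses)),
                       key=lambda i: (self.ellipses[i][0], self.ellipses[i][1]))
        labels = np.zeros(self.image_shape, dtype=int)
        for new_id, i in enumerate(order, start=1):
            labels[self._ellipse_mask(self.ellipses[i]) == 1] = new_id
        return KernelMask(labels)


def generate_cube(cfg: SynthConfig, layout: Optional[CubeLayout] = None,
                  white_level: float = 4000.0, dark_level: float = 100.0,
                  pixel_noise_sd: float = 0.0):
    """Paint per-kernel spectra into a raw cube with reference cubes.

    Per-kernel reflectance spectra come from :func:`generate_spectra`
    (one sample per kernel, K = n_healthy + n_infested).  Raw counts are
    dark + reflectance * (white - dark) + pixel noise; the background
    carries a low reflectance of 0.02 so kernels segment as bright
    objects.  Returns (raw, white, dark, mask_truth, spectra_truth).
    """
    spectra, truth = generate_spectra(cfg)
    k = spectra.n_samples
    if layout is None:
        layout = CubeLayout.auto(k)
    if len(layout.ellipses) != k:
        raise ParameterError(
            f"layout has {len(layout.ellipses)} ellipses for {k} kernels")
    rng = np.random.default_rng(cfg.seed + 1)
    mask = layout.truth_mask()
    rows, cols = layout.image_shape
    bands = spectra.n_bands
    refl = np.full((rows, cols, bands), 0.02)
    for lab in range(1, k + 1):
        refl[mask.labels == lab] = spectra.X[lab - 1]
    span = white_level - dark_level
    raw = dark_level + refl * span
    if pixel_noise_sd > 0:
        raw = raw + rng.normal(0.0, pixel_noise_sd, size=raw.shape)
        raw = np.maximum(raw, 0.0)
    grid = spectra.grid
    white = Hypercube(np.full((rows, cols, bands), white_level), grid, "raw")
    dark = Hypercube(np.full((rows, cols, bands), dark_level), grid, "raw")
    return (Hypercube(raw, grid, "raw"), white, dark, mask, spectra)
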