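"""Vibrational-spectrum handling and comparison.

Covers the spectral half of the ensemble-averaging workflow: Gaussian
broadening of harmonic stick spectra, population-weighted averaging over
conformer clusters, the hierarchical-merge spectrum series, moving-average
smoothing of noisy reference spectra, and the Pendry reliability factor
R_P used to compare two spectra through their logarithmic-derivative
Y-functions.  All wavenumbers are cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StickSpectrum",
    "GridSpectrum",
    "PendryResult",
    "broaden",
    "ensemble_average",
    "hierarchical_series",
    "smooth",
    "pendry_r",
    "region_report",
    "AMIDE_REGION",
    "STRETCH_REGION",
]

#: Amide I/II/III/V fingerprint window (cm^-1).
AMIDE_REGION = (600.0, 1800.0)
#: Amide A/B N-H / C-H stretch window (cm^-1).
STRETCH_REGION = (2700.0, 3600.0)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass
class StickSpectrum:
    """Discrete harmonic lines: (wavenumber cm^-1, intensity) pairs.

    ``scale_factor`` is applied multiplicatively to line positions when the
    spectrum is broadened, the usual correction for the systematic error of
    harmonic frequencies (1.0 for synthetic data).
    """

    lines: np.ndarray  # (n_lines, 2): wavenumber, intensity
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.lines = np.atleast_2d(np.asarray(self.lines, dtype=float))
        if self.lines.size == 0:
            self.lines = self.lines.reshape(0, 2)
        if self.lines.shape[1] != 2:
            raise ValueError("lines must be (wavenumber, intensity) pairs")
        if not np.all(np.isfinite(self.lines)):
            raise ValueError("non-finite line entries")
        if self.lines.shape[0] and np.any(self.lines[:, 0] <= 0):
            raise ValueError("wavenumbers must be strictly positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class GridSpectrum:
    """Continuous spectrum sampled on a strictly increasing wavenumber grid."""

    grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape or self.grid.ndim != 1:
            raise ValueError("grid and intensity must be 1-D and equal length")
        if self.grid.size >= 2 and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def restrict(self, region: tuple[float, float]) -> "GridSpectrum":
        lo, hi = region
        if lo < self.grid[0] - 1e-9 or hi > self.grid[-1] + 1e-9:
            raise ValueError(
                f"region ({lo}, {hi}) outside spectral grid "
                f"({self.grid[0]}, {self.grid[-1]})"
            )
        m = (self.grid >= lo) & (self.grid <= hi)
        return GridSpectrum(self.grid[m], self.intensity[m])

    def write(self, path) -> None:
        np.savetxt(path, np.column_stack([self.grid, self.intensity]),
                   fmt="%.6f %.10g")

    @classmethod
    def read(cls, path) -> "GridSpectrum":
        data = np.loadtxt(path, ndmin=2)
        return cls(data[:, 0], data[:, 1])


@dataclass
class PendryResult:
    """Pendry reliability factor over a wavenumber region.

    ``r_p`` is 0 for identical spectra and 1 for spectra whose Y-functions
    do not overlap at all; it is invariant to independently rescaling
    either spectrum's intensity.
    """

    r_p: float
    region: tuple[float, float]
    v_oi: float


def read_stick_spectrum(path, scale_factor: float = 1.0) -> StickSpectrum:
    data = np.loadtxt(path, ndmin=2)
    return StickSpectrum(data[:, :2], scale_factor=scale_factor)


def write_stick_spectrum(path, s: StickSpectrum) -> None:
    np.savetxt(path, s.lines, fmt="%.6f %.10g")


def broaden(s: StickSpectrum, fwhm: float, grid: np.ndarray) -> GridSpectrum:
    """Convolve stick lines with unit-area Gaussians of the given FWHM.

    Each line contributes a Gaussian of integrated area equal to its
    intensity, centred at ``scale_factor * wavenumber``.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    if s.lines.shape[0] == 0:
        warnings.warn("broadening an empty stick spectrum: zero result")
        return GridSpectrum(grid, np.zeros_like(grid))
    sigma = fwhm / _FWHM_TO_SIGMA
    centers = s.scale_factor * s.lines[:, 0]
    amps = s.lines[:, 1] / (sigma * np.sqrt(2.0 * np.pi))
    dev = (grid[None, :] - centers[:, None]) / sigma
    y = amps @ np.exp(-0.5 * dev**2)
    return GridSpectrum(grid, y)


def _common_grid(spectra) -> np.ndarray:
    g0 = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != g0.shape or not np.array_equal(s.grid, g0):
            raise ValueError("spectra are not on a common grid")
    return g0


def ensemble_average(spectra, weights) -> GridSpectrum:
    """Pointwise convex combination of spectra on a shared grid."""
    spectra = list(spectra)
    weights = np.asarray(weights, dtype=float)
    if len(spectra) != weights.size:
        raise ValueError("one weight per spectrum required")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {weights.sum()}, expected 1")
    g = _common_grid(spectra)
    y = np.zeros_like(g)
    for w, s in zip(weights, spectra):
        y = y + w * s.intensity
    return GridSpectrum(g, y)


def hierarchical_series(tree, leaf_spectra: dict, weights) -> list[GridSpectrum]:
    """Ensemble-averaged spectrum at every level of a cluster merge tree.

    ``leaf_spectra`` maps leaf-cluster ids to the broadened spectrum of that
    cluster's representative conformer.  At each level (from all leaves down
    to the single root) every active node contributes the spectrum of its
    merged representative's leaf, weighted by the node's merged weight.
    Returned in order: level ``n_clusters`` first, level 1 last.
    """
    weights = np.asarray(weights, dtype=float)
    for leaf in range(tree.n_leaves):
        if leaf not in leaf_spectra:
            raise ValueError(f"missing spectrum for leaf cluster {leaf}")
    out = []
    for level in range(tree.n_leaves, 0, -1):
        nodes = tree.nodes_at_level(level)
        specs = [leaf_spectra[tree.representative_leaf(n)] for n in nodes]
        w = np.array([tree.node_weight(n, weights) for n in nodes])
        out.append(ensemble_average(specs, w))
    return out


def smooth(s: GridSpectrum, window: float) -> GridSpectrum:
    """Moving-average smoothing with reflective boundaries.

    ``window`` is in cm^-1 and is rounded to an odd number of grid points.
    Total intensity is conserved (the result is rescaled to the input sum).
    """
    spacing = float(np.min(np.diff(s.grid)))
    if window < spacing:
        warnings.warn("smoothing window below grid spacing: returning input")
        return GridSpectrum(s.grid.copy(), s.intensity.copy())
    half = max(1, int(round(window / spacing)) // 2)
    n = 2 * half + 1
    padded = np.pad(s.intensity, half, mode="reflect")
    kernel = np.full(n, 1.0 / n)
    y = np.convolve(padded, kernel, mode="valid")
    total_in = s.intensity.sum()
    total_out = y.sum()
    if total_out > 0 and total_in > 0:
        y = y * (total_in / total_out)
    return GridSpectrum(s.grid.copy(), y)


def _y_function(intensity: np.ndarray, grid: np.ndarray, v_oi: float) -> np.ndarray:
    """Pendry Y-function: Y = L / (1 + v_oi^2 L^2), L = I'/I.

    The logarithmic derivative uses central differences; where the intensity
    is below eps = 1e-8 * max(I), Y is set to 0 to stabilise L.
    """
    eps = 1e-8 * np.max(np.abs(intensity)) if np.any(intensity) else 0.0
    deriv = np.gradient(intensity, grid)
    y = np.zeros_like(intensity)
    ok = np.abs(intensity) > eps
    L = np.zeros_like(intensity)
    L[ok] = deriv[ok] / intensity[ok]
    y[ok] = L[ok] / (1.0 + v_oi**2 * L[ok] ** 2)
    return y


def _resample(s: GridSpectrum, grid: np.ndarray) -> np.ndarray:
    if grid[0] < s.grid[0] - 1e-9 or grid[-1] > s.grid[-1] + 1e-9:
        raise ValueError("resampling would extrapolate outside the spectrum")
    return np.interp(grid, s.grid, s.intensity)


def pendry_r(
    a: GridSpectrum,
    b: GridSpectrum,
    v_oi: float = 5.0,
    region: tuple[float, float] | None = None,
) -> PendryResult:
    """Pendry reliability factor between two spectra.

    R_P = sum (Y_a - Y_b)^2 / sum (Y_a^2 + Y_b^2) on the common grid of the
    evaluation region; ``b`` is linearly resampled onto ``a``'s grid when the
    grids differ (extrapolation is refused).
    """
    if v_oi <= 0:
        raise ValueError("v_oi must be positive")
    if region is None:
        region = (max(a.grid[0], b.grid[0]), min(a.grid[-1], b.grid[-1]))
    ra = a.restrict(region)
    ib = _resample(b, ra.grid)
    if not np.any(ra.intensity) and not np.any(ib):
        raise ValueError("Pendry R undefined: both spectra are zero on region")
    ya = _y_function(ra.intensity, ra.grid, v_oi)
    yb = _y_function(ib, ra.grid, v_oi)
    denom = np.sum(ya**2 + yb**2)
    if denom == 0.0:
        raise ValueError("Pendry R undefined: Y-functions vanish on region")
    rp = float(np.sum((ya - yb) ** 2) / denom)
    return PendryResult(r_p=rp, region=tuple(region), v_oi=v_oi)


def region_report(
    a: GridSpectrum,
    b: GridSpectrum,
    v_oi: float = 5.0,
    regions=(AMIDE_REGION, STRETCH_REGION),
) -> list[PendryResult]:
    """Pendry R per standard spectral window (amide fingerprint and stretch)."""
    return [pendry_r(a, b, v_oi=v_oi, region=r) for r in regions]
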