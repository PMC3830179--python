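"""Spectral pre-treatments and dual-region feature construction.

The quantification method works on two wavenumber windows treated differently:
the 5311–6811 cm^-1 window is scatter-corrected (SNV) and differentiated
(Savitzky–Golay first derivative, 11-point window, second-order polynomial),
while the 7200–9999 cm^-1 window enters raw.  The two blocks are concatenated
and mean-centered with means learned on the calibration set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .simulate import SpectraSet, WavenumberGrid

__all__ = [
    "snv",
    "savgol_derivative",
    "select_region",
    "Region",
    "PreprocessPlan",
    "paper_plan",
    "DegenerateSpectrumError",
    "NotFittedError",
]

REGION_1 = (5311.0, 6811.0)
REGION_2 = (7200.0, 9999.0)


class DegenerateSpectrumError(ValueError):
    pass


class NotFittedError(RuntimeError):
    pass


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, sample SD (n-1).

    Removes per-spectrum multiplicative gain and constant offset.  Accepts a
    single spectrum or a (samples, points) matrix.
    """
    x = np.asarray(spectra, float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise DegenerateSpectrumError("SNV needs at least 2 points")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSpectrumError("constant spectrum has zero SD")
    out = (x - mu) / sd
    return out[0] if single else out


def savgol_derivative(
    spectra: np.ndarray,
    grid_spacing: float,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 1,
    drop_edges: bool = True,
) -> np.ndarray:
    """Savitzky–Golay derivative in units per cm^-1.

    The local least-squares polynomial convolution is exact for polynomials up
    to ``polyorder``.  With ``drop_edges`` (default) the (window-1)/2 points at
    each end, where the symmetric convolution window does not fit, are
    discarded rather than extrapolated.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    x = np.asarray(spectra, float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < window:
        raise ValueError("spectrum shorter than filter window")
    out = savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=grid_spacing, axis=1,
    )
    if drop_edges:
        h = (window - 1) // 2
        out = out[:, h:-h] if h else out
    return out[0] if single else out


def select_region(grid: WavenumberGrid, lo: float, hi: float) -> np.ndarray:
    """Indices of grid points with lo <= v <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    v = grid.points
    idx = np.nonzero((v >= lo) & (v <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"region [{lo}, {hi}] contains no grid points")
    return idx


@dataclass(frozen=True)
class Region:
    """One spectral window with its ordered treatment chain.

    Chain entries: ``("snv",)`` or ``("sg", window, polyorder, deriv)``.
    """

    lo: float
    hi: float
    chain: tuple[tuple, ...] = ()


def paper_plan() -> "PreprocessPlan":
    """SNV + first SG derivative (11, 2) on 5311–6811 cm^-1; raw 7200–9999
    cm^-1; global mean centering."""
    return PreprocessPlan(
        regions=(
            Region(*REGION_1, chain=(("snv",), ("sg", 11, 2, 1))),
            Region(*REGION_2, chain=()),
        ),
        mean_center=True,
    )


@dataclass
class PreprocessPlan:
    """Ordered region/treatment recipe with fit/apply centering semantics.

    ``fit_transform`` learns the feature column means on the calibration set;
    ``transform`` reuses the stored means, so test spectra never contribute to
    centering.
    """

    regions: tuple[Region, ...]
    mean_center: bool = True
    feature_means_: np.ndarray | None = field(default=None, compare=False)

    def _region_features(self, X: np.ndarray, grid: WavenumberGrid) -> np.ndarray:
        blocks = []
        for region in self.regions:
            idx = select_region(grid, region.lo, region.hi)
            block = X[:, idx]
            for step in region.chain:
                if step[0] == "snv":
                    block = snv(block)
                elif step[0] == "sg":
                    _, window, polyorder, deriv = step
                    block = savgol_derivative(
                        block, grid.spacing, window, polyorder, deriv
                    )
                else:
                    raise ValueError(f"unknown treatment {step[0]!r}")
            blocks.append(block)
        return np.hstack(blocks)

    def fit_transform(self, spectra: SpectraSet) -> np.ndarray:
        F = self._region_features(spectra.absorbance, spectra.grid)
        if self.mean_center:
            self.feature_means_ = F.mean(axis=0)
            F = F - self.feature_means_
        else:
            self.feature_means_ = np.zeros(F.shape[1])
        return F

    def transform(self, spectra: SpectraSet) -> np.ndarray:
        if self.feature_means_ is None:
            raise NotFittedError("plan has no stored means; call fit_transform first")
        F = self._region_features(spectra.absorbance, spectra.grid)
        if F.shape[1] != self.feature_means_.size:
            raise ValueError("feature length does not match fitted plan")
        return F - self.feature_means_

    def n_features(self, grid: WavenumberGrid) -> int:
        total = 0
        for region in self.regions:
            n = select_region(grid, region.lo, region.hi).size
            for step in region.chain:
                if step[0] == "sg":
                    n -= step[1] - 1
            total += n
        return total
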