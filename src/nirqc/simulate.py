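"""Synthetic NIR diffuse-reflectance spectra with the statistical structure the
chemometric pipeline assumes.

A powder-blend absorbance spectrum is modeled as a Beer–Lambert-like additive
mixture of Gaussian-band component spectra weighted by mass fraction, distorted
by the effects scatter correction is designed to remove: a per-spectrum
multiplicative gain (particle-size / packing scatter), a linear baseline, and
iid detector noise.  Each sample spectrum is the average of several independent
"repack" recordings of the same weighed blend, emulating triplicate recording
with vial turnover.

The component band library is an invented stand-in for the pure-compound
spectra of artesunate (AS), azithromycin (AZ), the excipients and the AS
degradant dihydroartemisinin (DHA); it is constructed so that AZ dominates the
capsule-blend spectrum at label composition and DHA differs from AS by a small
configurable band shift, keeping the specificity problem non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BlendDesign, SpecificityMixture, hgc_formulation

__all__ = [
    "WavenumberGrid",
    "Band",
    "ComponentBandSet",
    "NoiseModel",
    "SpectraSet",
    "default_grid",
    "default_library",
    "pure_spectrum",
    "mixture_spectrum",
    "simulate_set",
    "simulate_validation_study",
    "simulate_specificity_set",
]

#: excipient mixture (placebo) internal composition, cellulose : silica by mass
_PLACEBO_PARTS = (("cellulose", 4998.9), ("silica", 122.7))


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1 (ascending)."""

    start: float = 4000.0
    stop: float = 9999.0
    spacing: float = 4.0

    @property
    def points(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.spacing)) + 1
        return self.start + self.spacing * np.arange(n)

    @property
    def n_points(self) -> int:
        return int(np.floor((self.stop - self.start) / self.spacing)) + 1


def default_grid() -> WavenumberGrid:
    """4000–9999 cm^-1 digitized at 4 cm^-1 (1500 points)."""
    return WavenumberGrid()


@dataclass(frozen=True)
class Band:
    center: float  # cm^-1
    width: float  # Gaussian SD, cm^-1
    height: float  # AU

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.height < 0:
            raise ValueError("band height must be >= 0")


@dataclass(frozen=True)
class ComponentBandSet:
    name: str
    bands: tuple[Band, ...]


def pure_spectrum(bands: ComponentBandSet, grid: WavenumberGrid) -> np.ndarray:
    """Sum of Gaussian bands: A(v) = sum_b h_b exp(-(v - c_b)^2 / (2 w_b^2))."""
    v = grid.points
    a = np.zeros_like(v)
    for b in bands.bands:
        a += b.height * np.exp(-0.5 * ((v - b.center) / b.width) ** 2)
    return a


_BASE_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    # (center cm^-1, width cm^-1, height AU); each API has bands in both
    # analysis regions (5311–6811 and 7200–9999 cm^-1)
    "AZ": (
        (4300, 120, 0.50),
        (5600, 90, 0.55),
        (6300, 110, 0.60),
        (7500, 150, 0.35),
        (8600, 180, 0.25),
        (9300, 200, 0.15),
    ),
    "AS": (
        (4500, 110, 0.40),
        (5450, 80, 0.40),
        (6600, 100, 0.45),
        (7800, 160, 0.28),
        (8900, 190, 0.18),
    ),
    "cellulose": (
        (4750, 130, 0.45),
        (5900, 150, 0.35),
        (7000, 160, 0.30),
        (8300, 250, 0.20),
    ),
    "silica": (
        (4450, 150, 0.20),
        (7100, 200, 0.10),
    ),
}

DHA_SHIFT_CM1 = 30.0
DHA_HEIGHT_SCALE = 0.9


def default_library(
    seed: int | None = None,
    dha_shift: float = DHA_SHIFT_CM1,
    dha_height_scale: float = DHA_HEIGHT_SCALE,
) -> dict[str, ComponentBandSet]:
    """Band sets for AS, AZ, cellulose, silica and DHA.

    DHA is the AS band set shifted by ``dha_shift`` cm^-1 with heights scaled
    by ``dha_height_scale``.  With ``seed`` given, centers and heights receive
    a small reproducible jitter (SD 5 cm^-1 and 2% relative); without a seed
    the canonical library is returned.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    lib: dict[str, ComponentBandSet] = {}
    for name, spec_bands in _BASE_BANDS.items():
        bands = []
        for c, w, h in spec_bands:
            if rng is not None:
                c = c + rng.normal(0.0, 5.0)
                h = h * (1.0 + rng.normal(0.0, 0.02))
            bands.append(Band(c, w, max(h, 0.0)))
        lib[name] = ComponentBandSet(name, tuple(bands))
    lib["DHA"] = ComponentBandSet(
        "DHA",
        tuple(
            Band(b.center + dha_shift, b.width, b.height * dha_height_scale)
            for b in lib["AS"].bands
        ),
    )
    return lib


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum distortion magnitudes.

    gain_sd        relative SD of the log-normal multiplicative scatter gain
    offset_sd      SD of the constant baseline offset (AU)
    slope_sd       SD of the baseline slope (AU per normalized wavenumber)
    additive_sd    SD of iid point noise (AU)
    weighing_sd    relative SD of the per-component weighing error
    """

    gain_sd: float = 0.005
    offset_sd: float = 5e-4
    slope_sd: float = 5e-4
    additive_sd: float = 1e-4
    weighing_sd: float = 0.0015

    def __post_init__(self) -> None:
        if any(
            s < 0
            for s in (
                self.gain_sd,
                self.offset_sd,
                self.slope_sd,
                self.additive_sd,
                self.weighing_sd,
            )
        ):
            raise ValueError("noise SDs must be >= 0")


NOISELESS = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SpectraSet:
    """Samples × wavenumber absorbance matrix with per-sample metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray  # (n_samples, n_points), AU
    meta: pd.DataFrame  # one row per sample

    def __post_init__(self) -> None:
        if self.absorbance.ndim != 2 or self.absorbance.shape[1] != self.grid.n_points:
            raise ValueError("absorbance shape does not match grid")
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("metadata rows must match spectra rows")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            self.grid,
            self.absorbance[mask],
            self.meta.loc[mask].reset_index(drop=True),
        )


def _resolve_fractions(fractions: dict[str, float]) -> dict[str, float]:
    """Expand the 'placebo' pseudo-component into cellulose + silica."""
    out: dict[str, float] = {}
    placebo_total = sum(m for _, m in _PLACEBO_PARTS)
    for name, f in fractions.items():
        if f < 0:
            raise ValueError(f"negative fraction for {name!r}")
        if name == "placebo":
            for part, mass in _PLACEBO_PARTS:
                out[part] = out.get(part, 0.0) + f * mass / placebo_total
        else:
            out[name] = out.get(name, 0.0) + f
    return out


def mixture_spectrum(
    fractions: dict[str, float],
    library: dict[str, ComponentBandSet],
    grid: WavenumberGrid,
    noise: NoiseModel = NOISELESS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One recording of a blend: gain × Σ f_i A_i(v) + baseline + noise.

    The gain is log-normal with log-SD ``gain_sd``; the baseline is
    b0 + b1·ṽ with ṽ the wavenumber normalized to [0, 1]; point noise is iid
    Gaussian.
    """
    if rng is None:
        rng = np.random.default_rng()
    resolved = _resolve_fractions(fractions)
    v = grid.points
    signal = np.zeros_like(v)
    for name, f in resolved.items():
        if f == 0.0:
            continue
        signal += f * pure_spectrum(library[name], grid)
    gain = np.exp(rng.normal(0.0, noise.gain_sd)) if noise.gain_sd > 0 else 1.0
    vtilde = (v - v[0]) / (v[-1] - v[0])
    b0 = rng.normal(0.0, noise.offset_sd) if noise.offset_sd > 0 else 0.0
    b1 = rng.normal(0.0, noise.slope_sd) if noise.slope_sd > 0 else 0.0
    eps = rng.normal(0.0, noise.additive_sd, v.shape) if noise.additive_sd > 0 else 0.0
    return gain * signal + b0 + b1 * vtilde + eps


def _weighed_sample(
    design: BlendDesign, level: float, noise: NoiseModel, rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, float]]:
    """Simulate weighing a blend: nominal masses perturbed by relative error.

    Returns (mass fractions, true percent-of-label per API).
    """
    i = design.levels.index(level)
    masses = {
        design.varied_api: design.varied_mass[i],
        design.fixed_api: design.fixed_mass[i],
        "placebo": design.placebo_mass[i],
    }
    if noise.weighing_sd > 0:
        masses = {
            k: m * (1.0 + rng.normal(0.0, noise.weighing_sd))
            for k, m in masses.items()
        }
    total = sum(masses.values())
    fractions = {k: m / total for k, m in masses.items()}
    form = hgc_formulation()
    true_percent = {
        api: 100.0 * fractions[api] / form.mass_fraction(api)
        for api in (design.varied_api, design.fixed_api)
    }
    return fractions, true_percent


def _record_sample(
    fractions: dict[str, float],
    library: dict[str, ComponentBandSet],
    grid: WavenumberGrid,
    noise: NoiseModel,
    repacks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Average of `repacks` independent recordings of one weighed blend."""
    draws = [
        mixture_spectrum(fractions, library, grid, noise, rng) for _ in range(repacks)
    ]
    return np.mean(draws, axis=0)


def simulate_set(
    design: BlendDesign,
    library: dict[str, ComponentBandSet],
    grid: WavenumberGrid,
    noise: NoiseModel = NoiseModel(),
    repacks: int = 3,
    seed: int | np.random.SeedSequence | None = None,
) -> SpectraSet:
    """Simulate one blend-design set: every (level, vial) gives one averaged
    spectrum plus metadata carrying nominal and gravimetric-truth contents."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(design.n_samples)
    rows = []
    spectra = np.empty((design.n_samples, grid.n_points))
    k = 0
    for L in design.levels:
        for r in range(1, design.replicates_per_level + 1):
            rng = np.random.default_rng(children[k])
            fractions, true_percent = _weighed_sample(design, L, noise, rng)
            spectra[k] = _record_sample(fractions, library, grid, noise, repacks, rng)
            rows.append(
                {
                    "sample": f"{design.varied_api}_{design.role}_L{L:g}_r{r}",
                    "varied_api": design.varied_api,
                    "role": design.role,
                    "level_percent": L,
                    "series_id": 1,
                    "replicate_id": r,
                    **{f"percent_{a}": p for a, p in true_percent.items()},
                    **{f"frac_{c}": f for c, f in fractions.items()},
                }
            )
            k += 1
    return SpectraSet(grid, spectra, pd.DataFrame(rows))


def simulate_validation_study(
    design: BlendDesign,
    library: dict[str, ComponentBandSet],
    grid: WavenumberGrid,
    noise: NoiseModel = NoiseModel(),
    n_series: int = 3,
    repacks: int = 3,
    series_gain_sd: float = 0.003,
    seed: int | np.random.SeedSequence | None = None,
) -> SpectraSet:
    """Intermediate-precision design: ``n_series`` independent preparations of
    the validation set (different day/operator), each with its own log-normal
    instrument gain of log-SD ``series_gain_sd`` applied to every spectrum."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_series)
    parts = []
    for s in range(1, n_series + 1):
        child = children[s - 1]
        series_rng = np.random.default_rng(child)
        gain = (
            np.exp(series_rng.normal(0.0, series_gain_sd))
            if series_gain_sd > 0
            else 1.0
        )
        sub = simulate_set(
            design, library, grid, noise, repacks, seed=child.spawn(1)[0]
        )
        sub.absorbance *= gain
        sub.meta["series_id"] = s
        sub.meta["sample"] = sub.meta["sample"] + f"_s{s}"
        parts.append(sub)
    return SpectraSet(
        grid,
        np.vstack([p.absorbance for p in parts]),
        pd.concat([p.meta for p in parts], ignore_index=True),
    )


def simulate_specificity_set(
    mixtures: list[SpecificityMixture],
    library: dict[str, ComponentBandSet],
    grid: WavenumberGrid,
    noise: NoiseModel = NoiseModel(),
    repacks: int = 3,
    replicates: int = 3,
    seed: int | np.random.SeedSequence | None = None,
) -> SpectraSet:
    """Spectra of challenge blends (placebo, degraded, pure APIs)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(mixtures) * replicates)
    spectra = np.empty((len(mixtures) * replicates, grid.n_points))
    rows = []
    k = 0
    for mix in mixtures:
        for r in range(1, replicates + 1):
            rng = np.random.default_rng(children[k])
            fractions = mix.mass_fractions()
            if noise.weighing_sd > 0:
                weighed = {
                    c: f * (1.0 + rng.normal(0.0, noise.weighing_sd))
                    for c, f in fractions.items()
                }
                t = sum(weighed.values())
                fractions = {c: f / t for c, f in weighed.items()}
            spectra[k] = _record_sample(fractions, library, grid, noise, repacks, rng)
            rows.append(
                {
                    "sample": f"{mix.label}_r{r}",
                    "label": mix.label,
                    "replicate_id": r,
                }
            )
            k += 1
    return SpectraSet(grid, spectra, pd.DataFrame(rows))
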