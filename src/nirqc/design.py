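"""Formulation arithmetic and blend designs for calibration, validation and specificity.

The product under study is a hard gelatin capsule (HGC) co-formulating two
active pharmaceutical ingredients (APIs) — artesunate (AS) and azithromycin
dihydrate (AZ) — with microcrystalline cellulose and colloidal silica as
excipients.  Calibration/validation blends vary one API over a percent-of-label
range while the other API stays at 100% of label and the excipient mixture
("placebo") is added *quantum satis* (qsp) to a fixed total blend mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Formulation",
    "BlendDesign",
    "SpecificityMixture",
    "hgc_formulation",
    "formulation_percentages",
    "make_blend_design",
    "set_sizes",
    "dha_fraction",
    "specificity_proof_set",
    "design_table",
    "write_design_csv",
    "read_design_csv",
]

#: fixed total blend masses (mg) used when reconstituting powder blends
CALIBRATION_TOTAL_MG = 2053.64
VALIDATION_TOTAL_MG = 1026.82

#: vials per concentration level in each role
CALIBRATION_REPLICATES = 6
VALIDATION_REPLICATES = 3

#: percent-of-label levels, 80–120% in 5% steps
FULL_LEVELS = tuple(range(80, 125, 5))
VALIDATION_LEVELS = (80, 100, 120)


class InvalidFormulationError(ValueError):
    pass


class InfeasibleDesignError(ValueError):
    pass


@dataclass(frozen=True)
class Formulation:
    """Unit-dose composition: ordered (component, mass per unit in mg) pairs."""

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise InvalidFormulationError("component names must be unique")
        if any(m <= 0 for _, m in self.components):
            raise InvalidFormulationError("all component masses must be > 0")

    @property
    def total_mass(self) -> float:
        return sum(m for _, m in self.components)

    def mass(self, name: str) -> float:
        for n, m in self.components:
            if n == name:
                return m
        raise KeyError(name)

    def mass_fraction(self, name: str) -> float:
        return self.mass(name) / self.total_mass


def hgc_formulation() -> Formulation:
    """The AS+AZ capsule fill: AZ·2H2O 419 mg, AS 300 mg, cellulose 100 mg,
    colloidal silica 1.638 mg per capsule (AZ ≈ 51.06% w/w, AS ≈ 36.56% w/w)."""
    return Formulation(
        components=(
            ("AZ", 419.0),
            ("AS", 300.0),
            ("cellulose", 100.0),
            ("silica", 1.638),
        )
    )


def formulation_percentages(formulation: Formulation) -> list[tuple[str, float]]:
    """Percent w/w of each component: 100 × m_i / Σ m.

    The percents sum to 100 within rounding of the inputs.
    """
    total = formulation.total_mass
    if total <= 0:
        raise InvalidFormulationError("total mass must be > 0")
    return [(n, 100.0 * m / total) for n, m in formulation.components]


@dataclass(frozen=True)
class BlendDesign:
    """Per-level component masses for a varied-API blend series.

    For level L (% of label) the varied API mass is (L/100)·w_varied·total,
    the fixed API mass is w_fixed·total, and the excipient placebo brings the
    blend to ``total_mass`` exactly (qsp).
    """

    varied_api: str
    fixed_api: str
    levels: tuple[float, ...]
    total_mass: float
    varied_mass: tuple[float, ...]
    fixed_mass: tuple[float, ...]
    placebo_mass: tuple[float, ...]
    replicates_per_level: int
    role: str = "calibration"

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, float)
        if not np.all(np.diff(lv) > 0):
            raise InfeasibleDesignError("levels must be strictly increasing")
        for v, f, p in zip(self.varied_mass, self.fixed_mass, self.placebo_mass):
            if p < 0:
                raise InfeasibleDesignError("placebo mass negative")
            if abs(v + f + p - self.total_mass) > 0.01:
                raise InfeasibleDesignError("masses do not sum to total")

    @property
    def n_samples(self) -> int:
        return len(self.levels) * self.replicates_per_level

    def mass_fractions(self, level: float) -> dict[str, float]:
        """Nominal mass fractions (varied API, fixed API, placebo) at a level."""
        i = self.levels.index(level)
        t = self.total_mass
        return {
            self.varied_api: self.varied_mass[i] / t,
            self.fixed_api: self.fixed_mass[i] / t,
            "placebo": self.placebo_mass[i] / t,
        }


def make_blend_design(
    formulation: Formulation,
    varied_api: str,
    levels: tuple[float, ...] = FULL_LEVELS,
    total_mass: float = CALIBRATION_TOTAL_MG,
    replicates: int = CALIBRATION_REPLICATES,
    role: str = "calibration",
    fixed_api: str | None = None,
) -> BlendDesign:
    """Build the per-level blend masses for one varied API.

    Parameters
    ----------
    varied_api:
        API whose content spans ``levels`` (% of its label); the other API is
        held at 100% of label.
    total_mass:
        Fixed blend mass in mg; placebo is added qsp.
    """
    if total_mass <= 0:
        raise InfeasibleDesignError("total_mass must be > 0")
    lv = tuple(float(x) for x in levels)
    if any(not (0 < x <= 200) for x in lv):
        raise InfeasibleDesignError("levels must lie in (0, 200]")
    if fixed_api is None:
        apis = [n for n, _ in formulation.components[:2]]
        fixed_api = next(n for n in apis if n != varied_api)
    w_var = formulation.mass_fraction(varied_api)
    w_fix = formulation.mass_fraction(fixed_api)
    varied = tuple(L / 100.0 * w_var * total_mass for L in lv)
    fixed = tuple(w_fix * total_mass for _ in lv)
    placebo = tuple(total_mass - v - f for v, f in zip(varied, fixed))
    if any(p < 0 for p in placebo):
        raise InfeasibleDesignError(
            f"placebo mass negative for varied API {varied_api!r} at the "
            "highest level; reduce levels or total mass"
        )
    return BlendDesign(
        varied_api=varied_api,
        fixed_api=fixed_api,
        levels=lv,
        total_mass=total_mass,
        varied_mass=varied,
        fixed_mass=fixed,
        placebo_mass=placebo,
        replicates_per_level=replicates,
        role=role,
    )


def set_sizes(
    levels: int = len(FULL_LEVELS),
    calibration_replicates: int = CALIBRATION_REPLICATES,
    validation_replicates: int = VALIDATION_REPLICATES,
) -> tuple[int, int]:
    """(n_calibration, n_validation) = levels × vials per level for each role."""
    return levels * calibration_replicates, levels * validation_replicates


@dataclass(frozen=True)
class SpecificityMixture:
    """A challenge blend for the identification library (masses in mg)."""

    label: str
    masses: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if any(m < 0 for _, m in self.masses):
            raise InvalidFormulationError("masses must be >= 0")
        if not any(m > 0 for _, m in self.masses):
            raise InvalidFormulationError("at least one component must be > 0")

    def mass(self, name: str) -> float:
        for n, m in self.masses:
            if n == name:
                return m
        return 0.0

    @property
    def total(self) -> float:
        return sum(m for _, m in self.masses)

    def mass_fractions(self) -> dict[str, float]:
        t = self.total
        return {n: m / t for n, m in self.masses}


class UndefinedFractionError(ZeroDivisionError):
    pass


def dha_fraction(mix: SpecificityMixture) -> float:
    """Degradant load: 100 × DHA / (AS + DHA), the convention behind the
    '10% DHA' challenge label."""
    denom = mix.mass("AS") + mix.mass("DHA")
    if denom <= 0:
        raise UndefinedFractionError("AS + DHA mass is zero")
    return 100.0 * mix.mass("DHA") / denom


def specificity_proof_set() -> list[SpecificityMixture]:
    """Challenges presented to the identification library: excipient placebo,
    a 10%-DHA degraded blend, and each pure API."""
    return [
        SpecificityMixture("placebo", (("cellulose", 4998.9), ("silica", 122.7))),
        SpecificityMixture(
            "10% DHA",
            (("AZ", 261.88), ("AS", 168.75), ("DHA", 18.75), ("placebo", 64.04)),
        ),
        SpecificityMixture("pure AS", (("AS", 200.0),)),
        SpecificityMixture("pure AZ", (("AZ", 200.0),)),
    ]


def design_table(design: BlendDesign) -> pd.DataFrame:
    """Long-format design table, one row per (level, replicate vial)."""
    rows = []
    for i, L in enumerate(design.levels):
        for r in range(1, design.replicates_per_level + 1):
            rows.append(
                {
                    "level_percent": L,
                    f"mass_{design.varied_api}_mg": round(design.varied_mass[i], 2),
                    f"mass_{design.fixed_api}_mg": round(design.fixed_mass[i], 2),
                    "mass_placebo_mg": round(design.placebo_mass[i], 2),
                    "total_mg": design.total_mass,
                    "role": design.role,
                    "replicate_id": r,
                }
            )
    return pd.DataFrame(rows)


def write_design_csv(design: BlendDesign, path) -> None:
    design_table(design).to_csv(path, index=False)


def read_design_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"level_percent", "total_mg", "role", "replicate_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design CSV missing columns: {sorted(missing)}")
    return df
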