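"""Run configuration: one serializable object from which a full study is
bit-reproducible."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import (
    CALIBRATION_REPLICATES,
    CALIBRATION_TOTAL_MG,
    FULL_LEVELS,
    VALIDATION_LEVELS,
    VALIDATION_REPLICATES,
    VALIDATION_TOTAL_MG,
)
from .simulate import DHA_HEIGHT_SCALE, DHA_SHIFT_CM1, NoiseModel, WavenumberGrid

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 17
    # wavenumber axis
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    # measurement noise
    noise: NoiseModel = field(default_factory=NoiseModel)
    repacks: int = 3
    # blend designs
    apis: tuple[str, ...] = ("AZ", "AS")
    calibration_levels: tuple[float, ...] = FULL_LEVELS
    validation_levels: tuple[float, ...] = FULL_LEVELS
    profile_levels: tuple[float, ...] = VALIDATION_LEVELS
    calibration_total_mg: float = CALIBRATION_TOTAL_MG
    validation_total_mg: float = VALIDATION_TOTAL_MG
    calibration_replicates: int = CALIBRATION_REPLICATES
    validation_replicates: int = VALIDATION_REPLICATES
    # band library
    library_seed: int | None = None
    dha_shift_cm1: float = DHA_SHIFT_CM1
    dha_height_scale: float = DHA_HEIGHT_SCALE
    # PLS
    max_factors: int = 8
    cv_splits: int = 6
    # specificity
    pca_components: int = 5
    score_quantile: float = 0.999
    residual_sds: float = 5.0
    # validation study / accuracy profile
    n_series: int = 3
    series_replicates: int = 3
    series_gain_sd: float = 0.003
    beta: float = 0.95
    acceptance_limit: float = 5.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = asdict(self.grid)
        d["noise"] = asdict(self.noise)
        return d


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    grid = WavenumberGrid(**raw.pop("grid", {}))
    noise = NoiseModel(**raw.pop("noise", {}))
    for key in ("apis", "calibration_levels", "validation_levels", "profile_levels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(grid=grid, noise=noise, **raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
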