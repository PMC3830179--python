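#!/usr/bin/env python
"""Simulate the NIR spectra for every blend set of the study.

Uses the default band library and noise model (scatter gain SD 0.5%, baseline
offset/slope SD 5e-4 AU, point noise SD 1e-4 AU, weighing SD 0.15%), three
repack recordings averaged per sample, seed 17.  Spectra and metadata CSVs go
to results/spectra/ (regenerable; ~1.5 MB each).
"""

from pathlib import Path

from nirqc.config import RunConfig
from nirqc.design import hgc_formulation, make_blend_design
from nirqc.io import write_spectra_csv
from nirqc.pipeline import stage_seeds
from nirqc.simulate import default_library, simulate_set

OUT = Path(__file__).resolve().parents[1] / "results" / "spectra"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=17)
    seeds = stage_seeds(cfg.seed)
    form = hgc_formulation()
    library = default_library(cfg.library_seed)
    for api in cfg.apis:
        for role, total, reps, seed_key in (
            ("calibration", cfg.calibration_total_mg, cfg.calibration_replicates,
             f"cal_{api}"),
            ("validation", cfg.validation_total_mg, cfg.validation_replicates,
             f"val_{api}"),
        ):
            d = make_blend_design(form, api, total_mass=total, replicates=reps,
                                  role=role)
            s = simulate_set(d, library, cfg.grid, cfg.noise, cfg.repacks,
                             seeds[seed_key])
            write_spectra_csv(s, OUT / f"{api}_{role}.csv",
                              OUT / f"{api}_{role}_meta.csv")
            print(f"{api} {role}: {s.n_samples} spectra x "
                  f"{s.grid.n_points} points -> {OUT / f'{api}_{role}.csv'}")


if __name__ == "__main__":
    main()
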