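#!/usr/bin/env python
"""Build the formulation table and the calibration/validation blend designs.

For each API the design spans 80–120% of label in 5% steps while the other
API stays at 100%; excipient placebo tops each blend up to the fixed total
mass (2053.64 mg calibration, 1026.82 mg validation).  Writes the per-level
component masses under results/designs/ and prints the capsule composition.
"""

from pathlib import Path

import pandas as pd

from nirqc.design import (
    CALIBRATION_TOTAL_MG,
    VALIDATION_TOTAL_MG,
    design_table,
    formulation_percentages,
    hgc_formulation,
    make_blend_design,
    set_sizes,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "designs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    form = hgc_formulation()
    comp = pd.DataFrame(
        [(n, form.mass(n), p) for n, p in formulation_percentages(form)],
        columns=["component", "mg_per_capsule", "percent_ww"],
    )
    comp.to_csv(OUT / "formulation.csv", index=False)
    print("Capsule composition (%w/w):")
    print(comp.round(2).to_string(index=False))

    for api in ("AZ", "AS"):
        for role, total, reps in (
            ("calibration", CALIBRATION_TOTAL_MG, 6),
            ("validation", VALIDATION_TOTAL_MG, 3),
        ):
            d = make_blend_design(form, api, total_mass=total, replicates=reps,
                                  role=role)
            design_table(d).to_csv(OUT / f"{api}_{role}.csv", index=False)
    n_cal, n_val = set_sizes()
    print(f"\nPer API: {n_cal} calibration and {n_val} validation samples "
          f"(9 levels x 6/3 vials). Tables in {OUT}")


if __name__ == "__main__":
    main()
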