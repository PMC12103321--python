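#!/usr/bin/env python
"""Reconstruct the rotor geometry of the two reference spins and compute
their nominal and effective size cutoffs.

The bench settings quote RCF at the rotor's outer limit, but the liquid
column sits further in and spans a g-force gradient.  From the gradient
endpoints (1042-1976 g and 1668-3161 g over a 60 mm column) the radii
and angular speed follow, and with them the effective cutoff — the
diameter whose exponential Stokes trajectory just traverses the column
in the spin time.  Writes results/cutoffs.csv.
"""

from pathlib import Path

import pandas as pd

from fractoc.reproduce import build_runs, study_inputs
from fractoc.sedimentation import effective_cutoff_diameter, nominal_cutoff_diameter

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    inputs = study_inputs()
    density = inputs["ps_density"]
    rows = []
    for spec, run in zip(inputs["runs"], build_runs(inputs)):
        effective = effective_cutoff_diameter(run, density)
        nominal = nominal_cutoff_diameter(
            spec["rcf_set"], spec["column_height_mm"], spec["duration_min"] * 60.0,
            density, run.fluid,
        )
        rows.append(
            {
                "run": spec["name"],
                "rcf_set": spec["rcf_set"],
                "rpm_set": spec["rpm_set"],
                "rpm_implied": round(run.rpm, 0),
                "r_top_mm": round(run.r_top, 1),
                "r_bottom_mm": round(run.r_bottom, 1),
                "duration_min": spec["duration_min"],
                "nominal_cutoff_nm": round(nominal, 0),
                "effective_cutoff_nm": round(effective, 0),
            }
        )
        print(
            f"{spec['name']}: column {run.r_top:.1f}-{run.r_bottom:.1f} mm, "
            f"{run.rpm:.0f} rpm (set {spec['rpm_set']:.0f}); nominal cutoff "
            f"{nominal:.0f} nm, effective cutoff {effective:.0f} nm"
        )
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "cutoffs.csv", index=False)
    print(f"wrote {OUT / 'cutoffs.csv'}")


if __name__ == "__main__":
    main()
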