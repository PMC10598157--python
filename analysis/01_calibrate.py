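"""Fit the bilinear HU→density calibration from the synthetic rod table.

Writes the fitted coefficients to results/calibration.json and prints the
per-rod residuals.  The breakpoint sits at the muscle rod's mean HU; soft
tissues fall on the lower segment, bone on the upper one.
"""

from pathlib import Path

from ctbsp.calibration import (
    fit_bilinear_calibration,
    hu_to_density,
    read_rod_table,
    write_calibration,
)
from ctbsp.tables import rod_table_path

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rods = read_rod_table(rod_table_path())
    cal = fit_bilinear_calibration(rods)
    OUT.mkdir(exist_ok=True)
    write_calibration(cal, OUT / "calibration.json")
    print(
        f"breakpoint {cal.breakpoint_hu:.1f} HU | "
        f"lower: rho = {cal.lower_slope:.4f} HU + {cal.lower_intercept:.1f} | "
        f"upper: rho = {cal.upper_slope:.4f} HU + {cal.upper_intercept:.1f} (kg/m^3)"
    )
    for rod in rods:
        pred = hu_to_density(cal, rod.mean_hu)
        print(
            f"  {rod.name:<11s} {rod.mean_hu:8.1f} HU  nominal {rod.nominal_density:7.1f}"
            f"  fitted {pred:7.1f}  residual {pred - rod.nominal_density:+7.1f} kg/m^3"
        )
    print(f"wrote {OUT / 'calibration.json'}")


if __name__ == "__main__":
    main()
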