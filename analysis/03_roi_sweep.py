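#!/usr/bin/env python
"""The fat-infiltration robustness experiment.

Seven pure-muscle seed ROIs on the fat border are expanded voxel-by-voxel
into pure fat up to FF = 70%. For every ROI the pipeline measures apparent
T1, MTR, and the two-pool MMF under all four calculation variants
(constant 750 ms vs measured T1, with/without B1 correction), normalises
each metric to its FF = 0 value, and reports the robustness range (largest
FF with deviation within 5%).

Findings on the noise-free default phantom: apparent T1, MTR, and the
constant-T1 MMF all lose more than 5% of their baseline by FF = 10-20%,
with constant-T1 MMF diluting fastest (super-linear, since muscle
saturation is deep and fat adds an unsaturable signal floor). Feeding the
measured (lower) mixed-ROI T1 into the model inflates the fitted bound
pool and cancels a large part of that dilution at every FF, making the
measured-T1 MMF by far the most fat-robust metric — though on pure-voxel
equal-density mixtures the compensation is partial rather than complete.
"""

from pathlib import Path

import json

from utemt import PhantomSpec, simulate_study
from utemt.roi_analysis import (
    build_roi_series,
    curves_to_tidy,
    robustness_curves,
    robustness_summary,
    run_variants,
)

OUT = Path("results")


def main() -> None:
    study = simulate_study(PhantomSpec())
    series = build_roi_series(study.phantom.labels)
    table = run_variants(series, study)
    curves = robustness_curves(table)

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "roi_table.csv", index=False)
    curves_to_tidy(curves).to_csv(OUT / "robustness_curves.csv", index=False)
    summary = robustness_summary(curves)
    (OUT / "robustness_summary.json").write_text(json.dumps(summary, indent=2))

    print("normalized value (% of FF=0 baseline) vs FF target:")
    header = "metric    " + "".join(f"{f:>7.0f}" for f in curves[0].ff)
    print(header)
    for c in curves:
        vals = "".join(f"{v:7.1f}" for v in c.normalized_mean)
        print(f"{c.metric:<10}{vals}   robust to FF={c.robustness_ff:.0f}%")


if __name__ == "__main__":
    main()
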