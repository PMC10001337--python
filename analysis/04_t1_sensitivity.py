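#!/usr/bin/env python
"""Sensitivity of the fitted MMF to the assumed observed T1.

A pure-muscle 15-point MT grid is generated with observed T1 = 1000 ms and
MMF calibrated to 9%, then refitted with the assumed T1 pinned to values
from 1000 down to 300 ms. Lowering the assumed T1 raises the derived
free-pool R1 and the fit compensates by inflating the bound-pool fraction
— the mechanism by which the measured (fat-depressed) T1 stabilises MMF in
mixed muscle/fat ROIs.
"""

from pathlib import Path

from utemt import MTProtocol
from utemt.mt_model import mt_signal_grid, t1_sensitivity_sweep
from utemt.synthetic_data import TissueParams

OUT = Path("results")


def main() -> None:
    protocol = MTProtocol()
    tissue = TissueParams(t1_ms=1000.0, mmf_percent=9.0, t2_free_ms=30.0)
    grid = mt_signal_grid(tissue.two_pool(), protocol)
    df = t1_sensitivity_sweep(
        grid, [300, 400, 500, 600, 750, 800, 900, 1000], protocol=protocol
    )
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "t1_sensitivity.csv", index=False)
    print(df.to_string(index=False))
    lo = df.mmf_percent.iloc[0]
    hi = df.mmf_percent.iloc[-1]
    print(f"\nMMF rises from {hi:.1f}% (assumed T1 = 1000 ms) to "
          f"{lo:.1f}% (300 ms); monotone: "
          f"{df.attrs['monotone_nonincreasing_in_t1']}")


if __name__ == "__main__":
    main()
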