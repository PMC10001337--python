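# utemt — two-pool UTE-MT modeling of muscle under fat infiltration

Fat infiltration is a hallmark of muscle injury and degeneration, but it
also corrupts the quantitative MRI measures used to grade the muscle
itself. This package implements a quantitative magnetization-transfer
(qMT) pipeline for ultrashort-echo-time (UTE) acquisitions and uses a
digital muscle/fat phantom to ask: how far can fat infiltration rise
before the estimated **macromolecular fraction (MMF)** — a proxy for
myofibrillar protein and collagen content — stops being trustworthy, and
how much does measuring T1 (instead of assuming a constant) buy you?

It is aimed at quantitative-MRI researchers who want a tested, pure-Python
reference implementation of the CW-power-equivalent two-pool model with an
observed-T1 constraint, VFA/AFI relaxometry, and the expanding-ROI
robustness experiment.

## The model

Free water pool *a* (M₀ₐ = 1) exchanges longitudinal magnetization with a
semi-solid bound pool *b* (M₀ᵦ). Under off-resonance irradiation of
CW-equivalent amplitude ω₁ at offset Δ, the steady-state signal is

    S = M₀ · (RᵦRM₀ᵦ/Rₐ + R_RFB + Rᵦ + RM₀ᵦ) /
        [ (RM₀ᵦ/Rₐ)(Rᵦ + R_RFB) + (1 + (ω₁/2πΔ)²/(Rₐ·T₂ₐ)) (R_RFB + Rᵦ + RM₀ᵦ) ]

with R_RFB = π ω₁² g(Δ, T₂ᵦ) the bound-pool saturation rate through the
super-Lorentzian lineshape g, RM₀ᵦ = R·M₀ᵦ the exchange flux, and
Rₐ derived — never fitted — from the measured R₁,obs by requiring that
the slow eigenvalue of the 2×2 exchange matrix equal R₁,obs. The pulsed
Fermi saturation (powers 500°/1000°/1500°, offsets 2–50 kHz) is mapped to
ω₁ by RMS averaging over one MT preparation period. MMF is
100·M₀ᵦ/(1 + M₀ᵦ).

T1 comes from a B1-corrected variable-flip-angle (VFA) SPGR fit; B1 from
the actual-flip-angle (AFI) dual-TR ratio. The four calculation variants
cross {constant 750 ms, measured T1} × {no B1 correction, AFI B1}.

## Worked example

The analysis scripts run the study end to end on the default 96×96
phantom (muscle: observed T1 972 ms, MMF 9%; fat: T1 233 ms, MT-inert;
linear 0.9–1.1 B1 field; noise-free):

```sh
python analysis/01_simulate_phantom.py   # 21 volumes + ground truth
python analysis/02_relaxometry.py        # B1 exact; T1 = 971.3 / 232.9 ms
python analysis/03_roi_sweep.py          # the robustness experiment
python analysis/04_t1_sensitivity.py     # MMF vs assumed T1
```

`03_roi_sweep.py` prints each metric normalized to its fat-free baseline
(percent) across the fat-fraction grid:

```
metric          0      1      5     10     20     30     35     50     70
t1          100.0   96.2   89.7   79.3   64.4   54.1   49.8   39.9   31.5   robust to FF=1%
mtr         100.0   98.5   95.6   90.3   80.3   70.7   65.7   50.6   30.9   robust to FF=5%
mmf_v1      100.0   90.3   75.7   57.2   36.5   25.2   21.1   12.4    5.7   robust to FF=0%
mmf_v2      100.0   90.0   75.1   56.5   35.9   24.8   20.7   12.1    5.6   robust to FF=0%
mmf_v3      100.0   97.7   93.5   86.5   73.7   63.0   57.8   42.9   24.2   robust to FF=1%
mmf_v4      100.0   97.5   93.0   85.3   72.3   61.6   56.5   41.8   23.5   robust to FF=1%
```

Reading: apparent T1, MTR, and especially the constant-T1 MMF (variants
1–2) collapse as fat enters the ROI — the fit sees a diluted MT effect.
The measured-T1 variants (3–4) stay far closer to baseline at every fat
fraction because the apparent T1 of the mixed ROI drops (972 → ~630 ms at
FF = 20%), and a lower T1 fed into the constraint inflates the fitted
bound pool, compensating most of the dilution. `04_t1_sensitivity.py`
isolates that mechanism on pure-muscle data: the fitted MMF rises
monotonically from 9.0% at an assumed T1 of 1000 ms to 30.2% at 300 ms.

A `utemt` CLI wraps the same library (`utemt simulate`, `fit-b1`,
`fit-t1`, `fit-mt`, `roi-sweep`, `reproduce`, `fixtures`); `utemt
reproduce` is the one-command version of the whole experiment.

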