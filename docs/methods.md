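# Methods

## Signal model

The MT stage uses the continuous-wave power-equivalent (CWPE) form of the
binary spin-bath model. A free water pool *a* (M₀ₐ ≡ 1, relaxation rates
R₁ₐ, 1/T₂ₐ) exchanges with a semi-solid bound pool *b* (size M₀ᵦ, rate
R₁ᵦ, transverse time T₂ᵦ); the fundamental exchange rate constant R sets
the forward flux kf = R·M₀ᵦ and reverse rate kr = R. Off-resonance
irradiation saturates the bound pool at rate R_RFB = π ω₁² g(Δ, T₂ᵦ) and
the free pool directly through the Lorentzian term (ω₁/2πΔ)²/(R₁ₐT₂ₐ).
The steady-state signal is the standard CWPE rational expression (see the
README); its zero-power limit is exactly M₀, which the test suite asserts
to machine precision.

**Lineshape.** The bound pool uses the super-Lorentzian absorption
lineshape, the orientation integral of a Gaussian over sin θ with the
characteristic |3cos²θ − 1| scaling. The integrand has an integrable
singularity at the magic angle; quadrature is split there
(`scipy.integrate.quad` with a breakpoint, relative tolerance 1e-11).
Because g(Δ, T₂ᵦ) = T₂ᵦ·h(Δ·T₂ᵦ) exactly, the fitting path evaluates a
log-log cubic spline of h built once on 1200 points over
Δ·T₂ᵦ ∈ [10⁻³, 6] — covering offsets 2–50 kHz against any T₂ᵦ up to the
50 µs fit bound — and reproduces the quadrature to ~1e-9 relative (the
tests require 1e-6 against an independently formulated oracle). The
lineshape is not evaluated below 2 kHz offset, the protocol's lowest
sample; closer to resonance the steady-state description itself degrades.

**CW power equivalent.** The Fermi saturation pulse (duration 8 ms, flat
top with transition width duration/70, repeated every 125 ms around an
11-spoke readout block) is scaled so its flip angle γ∫B₁dt equals the
nominal power (500°–1500°) times the local B1 scale, then ω₁ is RMS-
averaged over the full preparation period. The pulse timing is a
configurable package default — plausible for an MT-prepared UTE sequence —
and recovery results are invariant to it because simulation and fitting
share the same pulse objects; the *absolute* saturation depth (hence MTR
and the dilution curves) does scale with it.

**Observed-T1 constraint.** R₁ₐ is never a free parameter. Given the
measured R₁,obs, it is the closed-form root of
det(A − R₁,obs·I) = 0 for the 2×2 longitudinal exchange matrix,
R₁ₐ = R₁,obs − kf(R₁ᵦ − R₁,obs)/(R₁ᵦ + kr − R₁,obs), which makes R₁,obs
the slow recovery eigenvalue; a bracketed root solve backs it up in
degenerate corners and every evaluation verifies self-consistency to
1e-10 relative. R₁ᵦ is fixed at 1 s⁻¹, the qMT convention (the data carry
almost no information about it).

## Fitting

`fit_two_pool` inverts the 15-point grid (3 powers × 5 offsets) by
bounded trust-region least squares with free parameters
(M₀, M₀ᵦ, T₂ₐ, T₂ᵦ): bounds M₀ᵦ ∈ [0, 1], T₂ₐ ∈ [5, 200] ms,
T₂ᵦ ∈ [2, 50] µs; inits 0.10 / 30 ms / 10 µs, M₀ from the weakest
saturation point (50 kHz, 500°). Three multi-starts with seeded jitter
guard against local minima; the best-residual solution is kept.
Non-convergence, a pinned bound-pool fraction, or a relative residual
above 0.15 flags the result; flagged fits are carried through tables,
never silently dropped.

The exchange rate constant R is **fixed at 50 s⁻¹ by default**
(`float_k_exch=True` restores a fully floating fit). This is a deliberate
conditioning choice: when R₁ᵦ ≈ R₁,obs — exactly the muscle regime,
1.0 vs 1.03 s⁻¹ — the signal depends on (M₀ᵦ, R) essentially only through
the product kf = R·M₀ᵦ; the split enters only via a ≲10⁻³ relative term
of the T1 constraint, so floating both turns MMF into a flat-valley
artifact of the optimizer. Fixing R makes kf (and hence MMF) well
conditioned: noise-free round trips recover MMF to <0.01 points and at
SNR 50 the median |ΔMMF| over 100 replicates is ~0.4 points.

The four calculation variants cross the T1 source (constant 750 ms vs the
ROI's measured VFA T1) with the B1 source (unity vs the ROI's AFI value).
Measured T1 inputs are always B1-corrected.

## Relaxometry

VFA T1 uses the SPGR steady state at B1-corrected flip angles
(TR 20 ms; 5/10/20/30°), initialised by the Ernst-linearised regression
S/sin α vs S/tan α and refined by bounded least squares
(T1 ∈ [50, 5000] ms). T2* decay is neglected at TE = 32 µs. AFI inverts
r = S2/S1 through cos α = (rn − 1)/(n − r), n = TR2/TR1 = 5; ratios
outside (1/n, n) are flagged invalid, not clamped. Both the forward
simulation and the inversion use the short-TR ideal-spoiling dual-TR
steady state, so the pair round-trips exactly; this is the standard AFI
operating assumption (TR1, TR2 ≪ T1).

T1 and MT fitting operate on ROI-mean signals, matching the ROI-based
analysis design; voxel-wise maps exist as a visualization mode
(`utemt fit-t1`).

## The synthetic phantom

A 96×96 single slice: muscle (left) and fat (right) abut along a straight
vertical border inside a signal-free frame. Muscle is a two-pool tissue
with observed T1 972 ms, MMF 9%, T₂ₐ 30 ms, T₂ᵦ 10 µs, R 50 s⁻¹; fat is a
single free pool (T1 233 ms, T₂ 60 ms) experiencing only direct
saturation — lipid protons are effectively isolated from the water and
macromolecular spin system, so fat is nearly MT-transparent (simulated
pure-fat MTR < 1%). Proton densities are equal (1:1) by default and
configurable, since MT dilution depends on signal fraction rather than
voxel fraction. B1 defaults to a linear 0.9–1.1 gradient (uniform and
Gaussian-bump fields available). Rician noise (magnitude of complex
Gaussian, σ = mean tissue signal/SNR) is applied per volume with seeds
derived from the phantom seed; SNR = ∞ is the noise-free path.

Simulation uses the *same* steady-state forward models the fits invert —
a deliberate inverse crime. The phantom exists to test mechanism
reproduction and parameter recovery, not acquisition realism: it omits
k-space/trajectory effects, partial-volume voxels at the border (every
voxel is pure), chemical-shift displacement and blurring of fat,
spatial heterogeneity of muscle T1/MMF, and temperature effects. Passing
tests therefore demonstrate the estimator's behaviour under ideal mixing,
not performance on scanner data.

An optional `fat_offset_shift_khz` adds the fat spectral offset to the
saturation frequency seen by fat (second order at ≥2 kHz offsets; off by
default).

## The expanding-ROI experiment

Seven 8×8 pure-muscle seed ROIs sit on the border, evenly spaced. Fat
voxels are ranked by distance to the nearest seed voxel (row-major
tie-break, fully deterministic) and appended until each fat-fraction
target in {0, 1, 5, 10, 20, 30, 35, 50, 70}% is met to within half a
voxel's worth of FF; seed muscle voxels are never removed, and masks are
nested. FF is the fat-voxel count over the total count (a signal-fraction
variant is a one-line change given equal densities). MTR uses the
2 kHz/1000° point against the saturation-off reference (configurable,
recorded in output).

Each metric is normalised per series to its FF = 0 value, averaged across
the seven series at matched targets (per-series curves are retained), and
the robustness range is the largest grid FF such that the mean normalised
value stays within 5% of 100 at every grid point up to it (contiguous
from zero, so a chance re-entry into the band at high FF does not count).

## Known limitations

* The measured-T1 compensation on this phantom is partial: at FF = 20%
  the measured-T1+B1 MMF retains ~72% of baseline rather than the
  near-100% seen in the ex vivo experiment the phantom is modelled on.
  The gap is structural for pure-voxel, equal-density mixtures: deep
  bound-pool saturation (kf ≈ 5 s⁻¹ ≫ R₁) makes MMF dilution super-linear
  in the fat signal fraction, while the apparent-T1 drop supplies an
  inflation factor of only ~1.6–2.2 where ~2.8 would be needed. Border
  partial-volume voxels, tissue heterogeneity, and fat signal losses in
  a long-spoke UTE readout — all absent here by design — soften the
  dilution in real data. The mechanism (measured-T1 MMF strictly more
  robust than constant-T1 MMF at every FF; monotone dilution of MTR and
  constant-T1 MMF; MMF inflation under lowered assumed T1) reproduces
  robustly and is what the test suite asserts.
* The T1-sensitivity sweep rises 9% → ~30% for assumed T1 1000 → 300 ms;
  the magnitude at the low-T1 end depends on the unprinted saturation
  duty cycle and on fit bounds (T₂ₐ can pin at its lower bound there).
* AFI/VFA assume ideal spoiling; no inversion-recovery gold standard, no
  multi-component T2*, no Dixon fat-water separation, and only the
  super-Lorentzian lineshape (no Gaussian/Lorentzian variants).

## Problem sizes

Default runs use the 96×96 slice (3872 voxels per compartment), seven ROI
series over nine FF targets, and four variants — 252 MT fits, a few
seconds on one CPU thanks to the spline lineshape. The 32×32 fixture
phantom exercises the identical code paths in under a minute including
simulation and I/O.
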