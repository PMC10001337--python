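"""B1 mapping (AFI) and single-exponential T1 fitting (VFA).

The VFA T1 fit uses the spoiled gradient-echo steady state at B1-corrected
flip angles; initialisation is the Ernst-linearised regression
(S/sin(a) vs S/tan(a)), refined by bounded nonlinear least squares.

The AFI B1 map inverts the dual-TR signal ratio r = S2/S1 through
cos(alpha) = (r*n - 1)/(n - r) with n = TR2/TR1.  Both the inversion and
the matching forward model assume ideal spoiling and TR1, TR2 << T1 (the
first-order dual-TR steady state), the standard operating regime of the
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .protocols import AFIProtocol, VFAProtocol


def spgr_signal(
    m0, t1_ms, tr_ms: float, fa_deg, b1_scale=1.0
):
    """Spoiled gradient-echo steady-state signal.

    S = m0 * sin(b1*a) * (1 - E1) / (1 - E1*cos(b1*a)), E1 = exp(-TR/T1).
    T2* decay is neglected (TE = 0.032 ms << any tissue T2*).  Inputs
    broadcast as numpy arrays.
    """
    m0 = np.asarray(m0, dtype=float)
    t1_ms = np.asarray(t1_ms, dtype=float)
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    a = np.radians(np.asarray(fa_deg, dtype=float)) * np.asarray(b1_scale, dtype=float)
    e1 = np.exp(-tr_ms / t1_ms)
    out = m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    return out if out.ndim else float(out)


def afi_signal_pair(m0, t1_ms, proto: AFIProtocol, b1_scale=1.0):
    """Forward dual-TR (AFI) signal pair in the short-TR regime.

    First order in TR/T1 with the shared exact-spoiling denominator:

        S1 = m0*sin(a)*(TR2 + TR1*cos(a)) / (T1*(1 - E1*E2*cos^2(a)))
        S2 = m0*sin(a)*(TR1 + TR2*cos(a)) / (T1*(1 - E1*E2*cos^2(a)))

    so the ratio S2/S1 = (1 + n*cos(a))/(n + cos(a)) holds exactly and the
    standard AFI inversion round-trips without model error.
    """
    m0 = np.asarray(m0, dtype=float)
    t1_ms = np.asarray(t1_ms, dtype=float)
    a = np.radians(proto.nominal_fa_deg) * np.asarray(b1_scale, dtype=float)
    e12 = np.exp(-(proto.tr1_ms + proto.tr2_ms) / t1_ms)
    den = t1_ms * (1.0 - e12 * np.cos(a) ** 2)
    s1 = m0 * np.sin(a) * (proto.tr2_ms + proto.tr1_ms * np.cos(a)) / den
    s2 = m0 * np.sin(a) * (proto.tr1_ms + proto.tr2_ms * np.cos(a)) / den
    return s1, s2


def afi_b1_map(s1, s2, proto: AFIProtocol):
    """Per-voxel B1 scale from an AFI pair.

    Returns ``(b1, valid)``: voxels whose ratio r = s2/s1 falls outside
    (1/n, n) — impossible under the model, i.e. noise-corrupted — are
    flagged invalid (b1 = nan there), never clamped silently.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"AFI volumes have mismatched grids: {s1.shape} vs {s2.shape}")
    n = proto.n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s2 / s1
        valid = np.isfinite(r) & (s1 > 0) & (r > 1.0 / n) & (r < n)
        cosa = (r * n - 1.0) / (n - r)
        valid &= (cosa > -1.0) & (cosa <= 1.0)
        b1 = np.where(valid, np.arccos(np.clip(cosa, -1.0, 1.0)), np.nan)
    b1 = b1 / math.radians(proto.nominal_fa_deg)
    if b1.ndim == 0:
        return float(b1), bool(valid)
    return b1, valid


@dataclass
class T1FitResult:
    t1_ms: float
    m0: float
    residual_norm: float
    converged: bool

    def __iter__(self):  # convenient unpacking
        yield self.t1_ms
        yield self.m0


def _ernst_linearized(signals: np.ndarray, fas_rad: np.ndarray, tr_ms: float):
    """Linear-regression initialiser: S/sin = E1*(S/tan) + m0*(1-E1)."""
    y = signals / np.sin(fas_rad)
    x = signals / np.tan(fas_rad)
    slope, intercept = np.polyfit(x, y, 1)
    if not 0.0 < slope < 1.0:
        return None
    t1 = -tr_ms / math.log(slope)
    m0 = intercept / (1.0 - slope)
    if t1 <= 0 or m0 <= 0:
        return None
    return m0, t1


def fit_vfa_t1(
    signals,
    proto: VFAProtocol,
    b1_scale: float = 1.0,
    t1_bounds_ms: tuple[float, float] = (50.0, 5000.0),
) -> T1FitResult:
    """Single-exponential (mono-T1) fit of a VFA series at B1-corrected
    flip angles.

    Flagged (``converged=False``) when the signals carry no flip-angle
    dependence or the optimizer fails; t1 is then nan.
    """
    signals = np.asarray(signals, dtype=float)
    fas = np.asarray(proto.flip_angles_deg, dtype=float)
    if signals.shape != fas.shape:
        raise ValueError("one signal per protocol flip angle required")
    if signals.size < 2:
        raise ValueError("need at least 2 flip angles")
    if np.any(signals <= 0):
        raise ValueError("VFA signals must be positive")
    if np.ptp(signals) == 0.0:
        return T1FitResult(float("nan"), float("nan"), float("nan"), False)

    fas_rad = np.radians(fas) * b1_scale
    init = _ernst_linearized(signals, fas_rad, proto.tr_ms)
    if init is None:
        init = (float(signals.max()) * 5.0, 800.0)
    m0_0, t1_0 = init
    t1_0 = min(max(t1_0, t1_bounds_ms[0]), t1_bounds_ms[1])

    def resid(x):
        return spgr_signal(x[0], x[1], proto.tr_ms, fas, b1_scale) - signals

    sol = least_squares(
        resid,
        [m0_0, t1_0],
        bounds=([1e-12, t1_bounds_ms[0]], [np.inf, t1_bounds_ms[1]]),
        x_scale=[max(m0_0, 1e-6), max(t1_0, 1.0)],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return T1FitResult(
        t1_ms=float(sol.x[1]),
        m0=float(sol.x[0]),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
    )


__all__ = [
    "spgr_signal",
    "afi_signal_pair",
    "afi_b1_map",
    "fit_vfa_t1",
    "T1FitResult",
]
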