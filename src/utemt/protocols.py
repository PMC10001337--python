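"""Acquisition protocol definitions.

Three acquisitions make up one study of the muscle/fat phantom:

* a variable-flip-angle (VFA) spoiled gradient-echo series for T1 mapping,
* an actual-flip-angle (AFI) dual-TR pair for B1 transmit-field mapping,
* an MT-prepared series over a grid of Fermi saturation powers and
  frequency offsets for MT-ratio and two-pool modeling.

All defaults are the acquisition parameters of the ex vivo muscle/fat
experiment this package emulates (3T, ultrashort-TE readout): VFA TR 20 ms
with flip angles 5/10/20/30 deg; AFI TRs 20/100 ms at 45 deg; MT saturation
powers 500/1000/1500 deg at offsets 2/5/10/20/50 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class VFAProtocol:
    """Variable-flip-angle SPGR protocol for T1 mapping."""

    tr_ms: float = 20.0
    flip_angles_deg: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0)
    te_ms: float = 0.032  # nominal tag; T2* decay neglected at this TE

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if len(set(self.flip_angles_deg)) < 2:
            raise ValueError("VFA needs at least 2 distinct flip angles")


@dataclass(frozen=True)
class AFIProtocol:
    """Actual-flip-angle dual-TR protocol for B1 mapping."""

    tr1_ms: float = 20.0
    tr2_ms: float = 100.0
    nominal_fa_deg: float = 45.0
    te_ms: float = 0.032

    def __post_init__(self) -> None:
        if not self.tr2_ms > self.tr1_ms:
            raise ValueError("AFI requires tr2 > tr1")
        if not 0.0 < self.nominal_fa_deg <= 90.0:
            raise ValueError("nominal flip angle must be in (0, 90] degrees")

    @property
    def n(self) -> float:
        """TR ratio n = TR2/TR1 (5 for the default 20/100 ms pair)."""
        return self.tr2_ms / self.tr1_ms


@dataclass(frozen=True)
class FermiShape:
    """Fermi RF envelope f(t) = 1 / (1 + exp((|t - t0| - a)/b)).

    ``a_ms`` is the half-width of the flat top and ``b_ms`` the transition
    width; both in milliseconds relative to the pulse centre t0.
    """

    a_ms: float
    b_ms: float

    def __post_init__(self) -> None:
        if self.a_ms <= 0 or self.b_ms <= 0:
            raise ValueError("Fermi shape parameters must be positive")


def default_fermi_shape(duration_ms: float) -> FermiShape:
    """Flat-topped Fermi envelope filling a pulse of the given duration.

    Transition width b = duration/70 and half-width a = duration/2 - 7b,
    which brings the envelope to ~1e-3 of its peak at the pulse edges.
    """
    b = duration_ms / 70.0
    return FermiShape(a_ms=duration_ms / 2.0 - 7.0 * b, b_ms=b)


@dataclass(frozen=True)
class SaturationPulse:
    """One off-resonance Fermi saturation condition of the MT series.

    ``power_deg`` is the equivalent flip angle of the saturation pulse and
    ``prep_period_ms`` the repetition period of one MT preparation (pulse
    plus the multi-spoke readout block) over which the continuous-wave
    power equivalent is averaged.
    """

    power_deg: float
    offset_khz: float
    duration_ms: float = 8.0
    prep_period_ms: float = 125.0
    shape: FermiShape | None = None

    def __post_init__(self) -> None:
        if self.power_deg <= 0:
            raise ValueError("saturation power must be positive")
        if self.offset_khz <= 0:
            raise ValueError("offset must be positive (never on-resonance)")
        if not self.duration_ms < self.prep_period_ms:
            raise ValueError("pulse duration must be shorter than the prep period")
        if self.shape is None:
            object.__setattr__(self, "shape", default_fermi_shape(self.duration_ms))


@dataclass(frozen=True)
class MTProtocol:
    """The 3 powers x 5 offsets MT measurement grid."""

    powers_deg: tuple[float, ...] = (500.0, 1000.0, 1500.0)
    offsets_khz: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0, 50.0)
    readout_fa_deg: float = 7.0
    pulse_duration_ms: float = 8.0
    prep_period_ms: float = 125.0

    @property
    def n_points(self) -> int:
        return len(self.powers_deg) * len(self.offsets_khz)

    def pulses(self) -> list[SaturationPulse]:
        """All saturation conditions, power-major then offset (row-major)."""
        return [
            SaturationPulse(
                power_deg=p,
                offset_khz=off,
                duration_ms=self.pulse_duration_ms,
                prep_period_ms=self.prep_period_ms,
            )
            for p in self.powers_deg
            for off in self.offsets_khz
        ]

    def pulse(self, power_deg: float, offset_khz: float) -> SaturationPulse:
        return SaturationPulse(
            power_deg=power_deg,
            offset_khz=offset_khz,
            duration_ms=self.pulse_duration_ms,
            prep_period_ms=self.prep_period_ms,
        )


@dataclass(frozen=True)
class ProtocolSet:
    """The three acquisitions of one study."""

    vfa: VFAProtocol = field(default_factory=VFAProtocol)
    afi: AFIProtocol = field(default_factory=AFIProtocol)
    mt: MTProtocol = field(default_factory=MTProtocol)


def default_protocols() -> ProtocolSet:
    return ProtocolSet()


__all__ = [
    "VFAProtocol",
    "AFIProtocol",
    "FermiShape",
    "SaturationPulse",
    "MTProtocol",
    "ProtocolSet",
    "default_fermi_shape",
    "default_protocols",
    "replace",
]
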