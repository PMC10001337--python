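"""Digital muscle/fat phantom and forward simulation of the full study.

The phantom emulates a single coronal slice through a lean muscle block
embedded in pure fat: a rectangular muscle compartment abutting a fat
compartment along a straight vertical border (so region-of-interest
expansion from muscle into fat is well defined), surrounded by a
signal-free background frame.

Tissue calibration (defaults):

* muscle — a two-pool MT compartment with observed T1 = 972 ms,
  macromolecular fraction 9%, free-pool T2 = 30 ms, bound-pool T2 = 10 us,
  exchange rate 50 1/s;
* fat — MT-inert (the lipid proton spin group is effectively isolated from
  both water and macromolecular protons): a single free pool with
  T1 = 233 ms and T2 = 60 ms, experiencing only direct saturation.

Simulated signals per voxel are the proton-density-weighted compartment
signals through the same steady-state forward models the fitting modules
invert (SPGR for VFA, first-order dual-TR for AFI, CWPE two-pool for MT).
This inverse-crime construction is deliberate: the phantom exists to test
mechanism reproduction and parameter recovery, not reconstruction realism.
Magnitude (Rician) noise is added at a configurable SNR with a fixed seed;
SNR = inf gives the noise-free path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mt_model import TwoPoolParams, ramani_signal
from .protocols import ProtocolSet, default_protocols
from .relaxometry import afi_signal_pair, spgr_signal


@dataclass(frozen=True)
class TissueParams:
    """Per-compartment tissue parameters of the phantom."""

    t1_ms: float
    mmf_percent: float
    t2_free_ms: float
    t2_bound_us: float = 10.0
    k_exch: float = 50.0
    r1_bound: float = 1.0
    proton_density: float = 1.0

    def two_pool(self) -> TwoPoolParams:
        return TwoPoolParams(
            m0=self.proton_density,
            bound_ratio=TwoPoolParams.bound_ratio_from_mmf(self.mmf_percent),
            k_exch=self.k_exch,
            t2_free_ms=self.t2_free_ms,
            t2_bound_us=self.t2_bound_us,
            r1_obs=1.0 / (self.t1_ms * 1e-3),
            r1_bound=self.r1_bound,
        )


MUSCLE = TissueParams(t1_ms=972.0, mmf_percent=9.0, t2_free_ms=30.0)
FAT = TissueParams(t1_ms=233.0, mmf_percent=0.0, t2_free_ms=60.0)

#: Compartment labels of the phantom grid.
BACKGROUND, LABEL_MUSCLE, LABEL_FAT = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue, field, and noise specification of one phantom."""

    shape: tuple[int, int] = (96, 96)
    spacing_mm: tuple[float, float] = (1.25, 1.25)
    background_width: int = 4
    muscle_fraction: float = 0.5  # fraction of interior width that is muscle
    muscle: TissueParams = field(default_factory=lambda: MUSCLE)
    fat: TissueParams = field(default_factory=lambda: FAT)
    b1_field: str = "linear"  # uniform | linear | gaussian
    b1_range: tuple[float, float] = (0.9, 1.1)
    b1_uniform_value: float = 1.0
    snr: float = math.inf
    seed: int = 0
    # optional fat spectral shift added to the saturation offset seen by the
    # fat pool (kHz); second-order at protocol offsets >= 2 kHz, off by default
    fat_offset_shift_khz: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.muscle_fraction < 1.0):
            raise ValueError(
                "muscle_fraction must be in (0, 1): both compartments required"
            )
        if self.snr <= 0:
            raise ValueError("snr must be positive (use inf for noise-free)")


@dataclass
class Phantom:
    """Label map plus per-voxel ground-truth parameter maps."""

    spec: PhantomSpec
    labels: np.ndarray  # int: 0 background, 1 muscle, 2 fat
    t1_map_ms: np.ndarray
    m0_map: np.ndarray
    mmf_map: np.ndarray
    b1_map: np.ndarray

    @property
    def muscle_mask(self) -> np.ndarray:
        return self.labels == LABEL_MUSCLE

    @property
    def fat_mask(self) -> np.ndarray:
        return self.labels == LABEL_FAT


def _b1_field(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    lo, hi = spec.b1_range
    if spec.b1_field == "uniform":
        return np.full(spec.shape, spec.b1_uniform_value)
    if spec.b1_field == "linear":
        return np.tile(np.linspace(lo, hi, w), (h, 1))
    if spec.b1_field == "gaussian":
        yy, xx = np.mgrid[0:h, 0:w]
        bump = np.exp(-(((yy - h / 2) / (h / 3)) ** 2 + ((xx - w / 2) / (w / 3)) ** 2))
        return lo + (hi - lo) * bump
    raise ValueError(f"unknown b1_field {spec.b1_field!r}")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministic phantom geometry: muscle left, fat right, straight
    vertical border, background frame."""
    h, w = spec.shape
    bg = spec.background_width
    interior_w = w - 2 * bg
    interior_h = h - 2 * bg
    if interior_w < 2 or interior_h < 1:
        raise ValueError("grid too small for the background frame")
    border_col = bg + int(round(interior_w * spec.muscle_fraction))
    labels = np.full(spec.shape, BACKGROUND, dtype=np.int8)
    labels[bg : h - bg, bg:border_col] = LABEL_MUSCLE
    labels[bg : h - bg, border_col : w - bg] = LABEL_FAT
    if not np.any(labels == LABEL_MUSCLE) or not np.any(labels == LABEL_FAT):
        raise ValueError("phantom must contain both muscle and fat voxels")

    t1 = np.zeros(spec.shape)
    m0 = np.zeros(spec.shape)
    mmf = np.zeros(spec.shape)
    for lab, tis in ((LABEL_MUSCLE, spec.muscle), (LABEL_FAT, spec.fat)):
        mask = labels == lab
        t1[mask] = tis.t1_ms
        m0[mask] = tis.proton_density
        mmf[mask] = tis.mmf_percent
    return Phantom(
        spec=spec,
        labels=labels,
        t1_map_ms=t1,
        m0_map=m0,
        mmf_map=mmf,
        b1_map=_b1_field(spec),
    )


def add_noise(volume: np.ndarray, snr: float, seed: int) -> np.ndarray:
    """Rician (magnitude) noise: |S + n1 + i*n2| with n1, n2 ~ N(0, sigma),
    sigma = mean tissue signal / snr.  Identity at snr = inf."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    if math.isinf(snr):
        return volume.copy()
    tissue = volume[volume > 0]
    sigma = (float(tissue.mean()) if tissue.size else float(np.abs(volume).mean())) / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.hypot(volume + n1, n2)


@dataclass
class SimulatedStudy:
    """One complete simulated acquisition with its ground truth.

    ``mt`` has shape (n_powers, n_offsets, H, W); ``mt_ref`` is the
    saturation-off reference used for the MT-ratio.
    """

    phantom: Phantom
    protocols: ProtocolSet
    vfa: np.ndarray  # (n_fa, H, W)
    afi: np.ndarray  # (2, H, W)
    mt: np.ndarray  # (n_pow, n_off, H, W)
    mt_ref: np.ndarray  # (H, W)
    manifest: dict = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return self.vfa.shape[0] + self.afi.shape[0] + self.mt.shape[0] * self.mt.shape[1]


def _mt_compartment_signals(
    tissue: TissueParams, protocols: ProtocolSet, b1: np.ndarray, shift_khz: float = 0.0
) -> np.ndarray:
    """(n_pow, n_off, ...) MT signals of one compartment over a B1 array."""
    params = tissue.two_pool()
    mtp = protocols.mt
    out = np.empty((len(mtp.powers_deg), len(mtp.offsets_khz)) + b1.shape)
    for i, p in enumerate(mtp.powers_deg):
        for j, off in enumerate(mtp.offsets_khz):
            pulse = mtp.pulse(p, off + shift_khz)
            out[i, j] = ramani_signal(params, pulse, b1)
    return out


def simulate_study(
    spec: PhantomSpec, protocols: ProtocolSet | None = None
) -> SimulatedStudy:
    """Forward-simulate the full VFA + AFI + MT study on a phantom.

    Per voxel, signals follow the compartment of the voxel's label through
    the shared steady-state forward models at the voxel's B1; Rician noise
    is then applied per volume with seeds derived from ``spec.seed``.
    """
    protocols = protocols or default_protocols()
    ph = make_phantom(spec)
    h, w = spec.shape
    mus, fat = ph.muscle_mask, ph.fat_mask
    b1 = ph.b1_map

    # VFA series
    vfa = np.zeros((len(protocols.vfa.flip_angles_deg), h, w))
    for k, fa in enumerate(protocols.vfa.flip_angles_deg):
        vol = np.zeros((h, w))
        for mask, tis in ((mus, spec.muscle), (fat, spec.fat)):
            vol[mask] = spgr_signal(
                tis.proton_density, tis.t1_ms, protocols.vfa.tr_ms, fa, b1[mask]
            )
        vfa[k] = vol

    # AFI pair
    afi = np.zeros((2, h, w))
    for mask, tis in ((mus, spec.muscle), (fat, spec.fat)):
        s1, s2 = afi_signal_pair(tis.proton_density, tis.t1_ms, protocols.afi, b1[mask])
        afi[0][mask], afi[1][mask] = s1, s2

    # MT series + saturation-off reference
    mtp = protocols.mt
    mt = np.zeros((len(mtp.powers_deg), len(mtp.offsets_khz), h, w))
    for mask, tis, shift in (
        (mus, spec.muscle, 0.0),
        (fat, spec.fat, spec.fat_offset_shift_khz),
    ):
        sig = _mt_compartment_signals(tis, protocols, b1[mask], shift)
        mt[:, :, mask] = sig
    mt_ref = ph.m0_map.copy()  # zero-saturation limit of the MT model

    # Noise: one child seed per volume, derived from the spec seed
    if not math.isinf(spec.snr):
        ss = np.random.SeedSequence(spec.seed)
        seeds = iter(ss.generate_state(vfa.shape[0] + 2 + mtp.n_points + 1))
        for k in range(vfa.shape[0]):
            vfa[k] = add_noise(vfa[k], spec.snr, int(next(seeds)))
        for k in range(2):
            afi[k] = add_noise(afi[k], spec.snr, int(next(seeds)))
        for i in range(mt.shape[0]):
            for j in range(mt.shape[1]):
                mt[i, j] = add_noise(mt[i, j], spec.snr, int(next(seeds)))
        mt_ref = add_noise(mt_ref, spec.snr, int(next(seeds)))

    manifest = {
        "seed": spec.seed,
        "snr": None if math.isinf(spec.snr) else spec.snr,
        "shape": list(spec.shape),
        "n_volumes": {"vfa": vfa.shape[0], "afi": 2, "mt": mtp.n_points},
        "muscle": {"t1_ms": spec.muscle.t1_ms, "mmf_percent": spec.muscle.mmf_percent},
        "fat": {"t1_ms": spec.fat.t1_ms, "mmf_percent": spec.fat.mmf_percent},
        "b1_field": spec.b1_field,
    }
    return SimulatedStudy(
        phantom=ph, protocols=protocols, vfa=vfa, afi=afi, mt=mt, mt_ref=mt_ref,
        manifest=manifest,
    )


def fixture_spec(seed: int = 0, snr: float = math.inf) -> PhantomSpec:
    """Small 32x32 phantom for fast tests and CI fixtures."""
    return PhantomSpec(shape=(32, 32), background_width=2, seed=seed, snr=snr)


__all__ = [
    "TissueParams",
    "MUSCLE",
    "FAT",
    "BACKGROUND",
    "LABEL_MUSCLE",
    "LABEL_FAT",
    "PhantomSpec",
    "Phantom",
    "SimulatedStudy",
    "make_phantom",
    "simulate_study",
    "add_noise",
    "fixture_spec",
    "replace",
]
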