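"""NIfTI volume and JSON manifest I/O for simulated studies.

A study on disk is a directory of NIfTI volumes plus ``manifest.json``
recording protocol parameters, the generator seed, the phantom spec echo,
ground-truth paths, and per-volume sha256 checksums, so every artifact is
regenerable and verifiable bit-identically from its resolved config.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocols import ProtocolSet, default_protocols
from .synthetic_data import Phantom, PhantomSpec, SimulatedStudy, make_phantom


def _affine(spacing_mm: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = spacing_mm
    return aff


def save_volume(path: Path, data: np.ndarray, spacing_mm=(1.25, 1.25)) -> str:
    """Write a 2-D (or stacked) array as NIfTI; returns its sha256."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing_mm))
    nib.save(img, str(path))
    return hashlib.sha256(np.ascontiguousarray(data).tobytes()).hexdigest()


def load_volume(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "shape": list(spec.shape),
        "spacing_mm": list(spec.spacing_mm),
        "background_width": spec.background_width,
        "muscle_fraction": spec.muscle_fraction,
        "muscle": vars(spec.muscle).copy(),
        "fat": vars(spec.fat).copy(),
        "b1_field": spec.b1_field,
        "b1_range": list(spec.b1_range),
        "b1_uniform_value": spec.b1_uniform_value,
        "snr": None if math.isinf(spec.snr) else spec.snr,
        "seed": spec.seed,
        "fat_offset_shift_khz": spec.fat_offset_shift_khz,
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    from .synthetic_data import TissueParams

    return PhantomSpec(
        shape=tuple(d["shape"]),
        spacing_mm=tuple(d["spacing_mm"]),
        background_width=d["background_width"],
        muscle_fraction=d["muscle_fraction"],
        muscle=TissueParams(**d["muscle"]),
        fat=TissueParams(**d["fat"]),
        b1_field=d["b1_field"],
        b1_range=tuple(d["b1_range"]),
        b1_uniform_value=d["b1_uniform_value"],
        snr=math.inf if d["snr"] is None else d["snr"],
        seed=d["seed"],
        fat_offset_shift_khz=d.get("fat_offset_shift_khz", 0.0),
    )


def save_study(study: SimulatedStudy, outdir: Path) -> Path:
    """Write all volumes, ground truth, and the manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = study.phantom.spec
    sp = spec.spacing_mm
    checksums: dict[str, str] = {}

    def put(name: str, data: np.ndarray) -> str:
        checksums[name] = save_volume(outdir / name, data, sp)
        return name

    volumes = {
        "vfa": [
            put(f"vfa_fa{int(fa):02d}.nii.gz", study.vfa[k])
            for k, fa in enumerate(study.protocols.vfa.flip_angles_deg)
        ],
        "afi": [put(f"afi_tr{k + 1}.nii.gz", study.afi[k]) for k in range(2)],
        "mt": [
            put(
                f"mt_p{int(p):04d}_o{int(o * 1000):05d}hz.nii.gz",
                study.mt[i, j],
            )
            for i, p in enumerate(study.protocols.mt.powers_deg)
            for j, o in enumerate(study.protocols.mt.offsets_khz)
        ],
        "mt_ref": put("mt_ref.nii.gz", study.mt_ref),
    }
    truth = {
        "labels": put("truth_labels.nii.gz", study.phantom.labels.astype(float)),
        "t1_ms": put("truth_t1_ms.nii.gz", study.phantom.t1_map_ms),
        "b1": put("truth_b1.nii.gz", study.phantom.b1_map),
        "mmf_percent": put("truth_mmf.nii.gz", study.phantom.mmf_map),
        "m0": put("truth_m0.nii.gz", study.phantom.m0_map),
    }
    manifest = {
        "spec": _spec_to_dict(spec),
        "protocols": {
            "vfa": {
                "tr_ms": study.protocols.vfa.tr_ms,
                "flip_angles_deg": list(study.protocols.vfa.flip_angles_deg),
            },
            "afi": {
                "tr1_ms": study.protocols.afi.tr1_ms,
                "tr2_ms": study.protocols.afi.tr2_ms,
                "nominal_fa_deg": study.protocols.afi.nominal_fa_deg,
            },
            "mt": {
                "powers_deg": list(study.protocols.mt.powers_deg),
                "offsets_khz": list(study.protocols.mt.offsets_khz),
                "pulse_duration_ms": study.protocols.mt.pulse_duration_ms,
                "prep_period_ms": study.protocols.mt.prep_period_ms,
            },
        },
        "volumes": volumes,
        "ground_truth": truth,
        "checksums": checksums,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_study(studydir: Path) -> SimulatedStudy:
    """Reassemble a SimulatedStudy from a study directory's manifest."""
    studydir = Path(studydir)
    manifest = json.loads((studydir / "manifest.json").read_text())
    spec = spec_from_dict(manifest["spec"])
    protocols = default_protocols()
    vols = manifest["volumes"]
    vfa = np.stack([load_volume(studydir / n) for n in vols["vfa"]])
    afi = np.stack([load_volume(studydir / n) for n in vols["afi"]])
    mtp = protocols.mt
    flat = np.stack([load_volume(studydir / n) for n in vols["mt"]])
    mt = flat.reshape(len(mtp.powers_deg), len(mtp.offsets_khz), *flat.shape[1:])
    mt_ref = load_volume(studydir / vols["mt_ref"])
    phantom = make_phantom(spec)
    return SimulatedStudy(
        phantom=phantom,
        protocols=protocols,
        vfa=vfa,
        afi=afi,
        mt=mt,
        mt_ref=mt_ref,
        manifest=manifest,
    )


__all__ = [
    "save_volume",
    "load_volume",
    "save_study",
    "load_study",
    "spec_from_dict",
]
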