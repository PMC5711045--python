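"""Reading and writing: NIfTI volumes, projection stacks, YAML configs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .acquisition import ProjectionSet, ScanProtocol
from .motion import MotionPattern
from .phantom import PhantomConfig, TargetSpec, VoxelVolume, default_config

__all__ = [
    "save_volume",
    "load_volume",
    "save_projections",
    "load_config",
    "dump_config",
]


def save_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing/origin in the affine."""
    affine = np.diag([volume.spacing] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = float(affine[0, 0])
    if not np.allclose(np.diag(affine)[:3], spacing):
        raise ValueError("only isotropic axis-aligned volumes are supported")
    return VoxelVolume(
        values=np.asarray(img.dataobj, dtype=np.float64),
        spacing=spacing,
        origin=tuple(float(v) for v in affine[:3, 3]),
    )


def save_projections(projections: ProjectionSet, stem: str | Path) -> None:
    """Write projections as ``<stem>.nii.gz`` plus a ``<stem>.csv`` sidecar.

    The sidecar has one row per projection: index, gantry angle (deg) and
    acquisition time (s).
    """
    stem = Path(stem)
    nib.save(
        nib.Nifti1Image(np.asarray(projections.data, dtype=np.float32), np.eye(4)),
        str(stem.with_suffix(".nii.gz")),
    )
    pd.DataFrame(
        {
            "index": np.arange(projections.n),
            "angle_deg": np.rad2deg(projections.angles_rad),
            "time_s": projections.times_s,
        }
    ).to_csv(stem.with_suffix(".csv"), index=False)


def _target_from_dict(d: dict) -> TargetSpec:
    return TargetSpec(
        name=d["name"],
        extents=tuple(float(v) for v in d["extents_mm"]),
        center=tuple(float(v) for v in d["center_mm"]),
        mu=float(d.get("mu_per_mm", 0.020)),
    )


def _box(d) -> tuple:
    return tuple((float(lo), float(hi)) for lo, hi in d)


def load_config(path: str | Path):
    """Load phantom / motion / protocol sections from one YAML file.

    Returns ``(PhantomConfig, MotionPattern, ScanProtocol | None)``; every
    section is optional and falls back to the package defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    ph = doc.get("phantom")
    if ph is None:
        config = default_config()
    else:
        base = default_config()
        config = PhantomConfig(
            shape=tuple(ph.get("shape", base.shape)),
            spacing=float(ph.get("spacing_mm", base.spacing)),
            mu_foam=float(ph.get("mu_foam", base.mu_foam)),
            mu_water=float(ph.get("mu_water", base.mu_water)),
            mu_air=float(ph.get("mu_air", base.mu_air)),
            slab_region=_box(ph["slab_region_mm"]) if "slab_region_mm" in ph else base.slab_region,
            foam_region=_box(ph["foam_region_mm"]) if "foam_region_mm" in ph else base.foam_region,
            targets=tuple(_target_from_dict(t) for t in ph["targets"])
            if "targets" in ph
            else base.targets,
            supersample=int(ph.get("supersample", 1)),
        )

    mo = doc.get("motion", {})
    pattern = MotionPattern(
        kind=mo.get("kind", "static"),
        A=float(mo.get("amplitude_mm", 0.0)),
        f=float(mo.get("frequency_hz", 0.25)),
        phi=float(mo.get("phase_rad", 0.0)),
        Vp=float(mo.get("speed_mm_s", 0.0)),
        Zo=float(mo.get("offset_mm", 0.0)),
    )

    pr = doc.get("protocol")
    protocol = None
    if pr is not None:
        mode = pr.get("mode", "full_fan")
        base_p = ScanProtocol.full_fan() if mode == "full_fan" else ScanProtocol.half_fan()
        protocol = ScanProtocol(
            mode=mode,
            arc_deg=float(pr.get("arc_deg", base_p.arc_deg)),
            duration_s=float(pr.get("duration_s", base_p.duration_s)),
            n_projections=int(pr.get("n_projections", base_p.n_projections)),
            sad=float(pr.get("sad_mm", base_p.sad)),
            sdd=float(pr.get("sdd_mm", base_p.sdd)),
            nu=int(pr.get("nu", base_p.nu)),
            nv=int(pr.get("nv", base_p.nv)),
            pitch=float(pr.get("pitch_mm", base_p.pitch)),
            lateral_offset_mm=float(pr.get("lateral_offset_mm", base_p.lateral_offset_mm)),
            kvp=float(pr.get("kvp", base_p.kvp)),
            mas=float(pr.get("mas", base_p.mas)),
        )
    return config, pattern, protocol


def dump_config(
    config: PhantomConfig,
    pattern: MotionPattern | None = None,
    protocol: ScanProtocol | None = None,
    path: str | Path | None = None,
) -> str:
    """Serialize a configuration back to YAML (round-trips load_config)."""
    doc: dict = {
        "phantom": {
            "shape": list(config.shape),
            "spacing_mm": config.spacing,
            "mu_foam": config.mu_foam,
            "mu_water": config.mu_water,
            "mu_air": config.mu_air,
            "slab_region_mm": [list(b) for b in config.slab_region],
            "foam_region_mm": [list(b) for b in config.foam_region],
            "supersample": config.supersample,
            "targets": [
                {
                    "name": t.name,
                    "extents_mm": list(t.extents),
                    "center_mm": list(t.center),
                    "mu_per_mm": t.mu,
                }
                for t in config.targets
            ],
        }
    }
    if pattern is not None:
        doc["motion"] = {
            "kind": pattern.kind,
            "amplitude_mm": pattern.A,
            "frequency_hz": pattern.f,
            "phase_rad": pattern.phi,
            "speed_mm_s": pattern.Vp,
            "offset_mm": pattern.Zo,
        }
    if protocol is not None:
        doc["protocol"] = {
            "mode": protocol.mode,
            "arc_deg": protocol.arc_deg,
            "duration_s": protocol.duration_s,
            "n_projections": protocol.n_projections,
            "sad_mm": protocol.sad,
            "sdd_mm": protocol.sdd,
            "nu": protocol.nu,
            "nv": protocol.nv,
            "pitch_mm": protocol.pitch,
            "lateral_offset_mm": protocol.lateral_offset_mm,
            "kvp": protocol.kvp,
            "mas": protocol.mas,
        }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
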