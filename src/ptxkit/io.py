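"""Readers and writers for every pipeline artifact.

Complex volumes are stored as paired magnitude/phase NIfTI files (phase in
radians wrapped to (-pi, pi]) with a JSON sidecar carrying the channel table
and grid metadata — robust to viewers that mishandle complex dtypes.  VOP
sets go to HDF5; shims and pulses to JSON; L-curves to CSV; configs to YAML.
Channel order always comes from the sidecar, never from filename sorting.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .ktpoints import KTPulse, LCurve
from .mapping import RelativeB1MapSet
from .shim import ShimWeights
from .synth import B1MapSet, CalibrationStack, Phantom, VOPSet

__all__ = [
    "save_b1_dataset",
    "load_b1_dataset",
    "save_mask",
    "load_mask",
    "save_calibration_stack",
    "load_calibration_stack",
    "save_vops",
    "load_vops",
    "save_shim",
    "load_shim",
    "save_pulse",
    "load_pulse",
    "save_lcurve",
    "load_lcurve",
    "load_config",
    "save_config",
    "config_hash",
]

SIDECAR_NAME = "b1_dataset.json"


def _affine(phantom: Phantom) -> np.ndarray:
    aff = np.diag(list(phantom.voxel_size_mm) + [1.0])
    for i, (n, vs) in enumerate(zip(phantom.grid_shape, phantom.voxel_size_mm)):
        aff[i, 3] = -(n - 1) / 2.0 * vs  # isocenter at the grid center
    return aff


def _write_nifti(path: Path, data: np.ndarray, phantom: Phantom) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(phantom))
    nib.save(img, str(path))


def _phantom_meta(phantom: Phantom) -> dict:
    return {
        "grid_shape": list(phantom.grid_shape),
        "voxel_size_mm": list(phantom.voxel_size_mm),
    }


def save_mask(path, mask: np.ndarray, phantom: Phantom) -> None:
    _write_nifti(Path(path), mask.astype(np.uint8), phantom)


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)


def save_b1_dataset(b1: B1MapSet, out_dir) -> Path:
    """Write per-channel magnitude/phase NIfTI volumes plus a JSON sidecar
    (channel table, active mask, units, grid metadata) and the masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = []
    for c in range(b1.n_channels):
        mag_name = f"b1_ch{c + 1:02d}_mag.nii.gz"
        ph_name = f"b1_ch{c + 1:02d}_phase.nii.gz"
        _write_nifti(out / mag_name, np.abs(b1.maps[c]), b1.phantom)
        phase = np.angle(b1.maps[c])  # wrapped to (-pi, pi]
        _write_nifti(out / ph_name, phase, b1.phantom)
        channels.append({"channel": c + 1, "magnitude": mag_name, "phase": ph_name})
    sidecar = {
        "units": "relative",
        "phase_units": "radians",
        "active_mask": [bool(a) for a in b1.active_mask],
        "power_budget": [float(p) for p in np.asarray(b1.power_budget)],
        "channels": channels,
        **_phantom_meta(b1.phantom),
    }
    extra = {}
    if isinstance(b1, RelativeB1MapSet):
        extra["reference_label"] = b1.reference_label
        if b1.ratio_noise_level is not None:
            extra["ratio_noise_level"] = float(b1.ratio_noise_level)
        save_mask(out / "validity_mask.nii.gz", b1.validity_mask, b1.phantom)
        sidecar["validity_mask"] = "validity_mask.nii.gz"
    sidecar.update(extra)
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    save_mask(out / "body_mask.nii.gz", b1.phantom.body_mask, b1.phantom)
    save_mask(out / "roi_mask.nii.gz", b1.phantom.roi_mask, b1.phantom)
    return out


def load_b1_dataset(path) -> B1MapSet:
    """Load a B1 map set written by :func:`save_b1_dataset`.

    The round trip is lossless to float32 NIfTI precision; the channel order
    is taken from the sidecar, so on-disk file order is irrelevant.
    """
    d = Path(path)
    sidecar_path = d / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    grid_shape = tuple(sidecar["grid_shape"])
    voxel = tuple(sidecar["voxel_size_mm"])
    body = load_mask(d / "body_mask.nii.gz")
    roi = load_mask(d / "roi_mask.nii.gz")
    phantom = Phantom(grid_shape, voxel, body, roi)

    n_listed = len(sidecar["channels"])
    if len(sidecar["active_mask"]) != n_listed:
        raise ValueError("sidecar active_mask length disagrees with channel table")
    maps = np.empty((n_listed,) + grid_shape, dtype=np.complex128)
    for i, entry in enumerate(sidecar["channels"]):
        for key in ("magnitude", "phase"):
            if not (d / entry[key]).exists():
                raise FileNotFoundError(
                    f"channel {entry['channel']}: missing volume {entry[key]}"
                )
        mag = np.asarray(nib.load(str(d / entry["magnitude"])).dataobj)
        ph = np.asarray(nib.load(str(d / entry["phase"])).dataobj)
        if mag.shape != grid_shape or ph.shape != grid_shape:
            raise ValueError(f"channel {entry['channel']}: grid mismatch")
        maps[i] = mag * np.exp(1j * ph)

    active = np.asarray(sidecar["active_mask"], dtype=bool)
    budget = np.asarray(sidecar.get("power_budget", np.ones(n_listed)))
    if "validity_mask" in sidecar:
        return RelativeB1MapSet(
            maps=maps,
            phantom=phantom,
            active_mask=active,
            power_budget=budget,
            reference_label=sidecar.get("reference_label", "channel_sum"),
            validity_mask=load_mask(d / sidecar["validity_mask"]),
            ratio_noise_level=sidecar.get("ratio_noise_level"),
        )
    return B1MapSet(maps, phantom, active, budget)


def save_calibration_stack(stack: CalibrationStack, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for m, label in enumerate(stack.scheme):
        mag_name = f"meas_{m:03d}_{label}_mag.nii.gz"
        ph_name = f"meas_{m:03d}_{label}_phase.nii.gz"
        _write_nifti(out / mag_name, np.abs(stack.images[m]), stack.phantom)
        _write_nifti(out / ph_name, np.angle(stack.images[m]), stack.phantom)
        entries.append({"label": label, "magnitude": mag_name, "phase": ph_name})
    meta = {
        "scheme": list(stack.scheme),
        "noise_sigma": stack.noise_sigma,
        "measurements": entries,
        **_phantom_meta(stack.phantom),
    }
    _write_nifti(out / "receive_profile.nii.gz", stack.receive_profile, stack.phantom)
    save_mask(out / "body_mask.nii.gz", stack.phantom.body_mask, stack.phantom)
    save_mask(out / "roi_mask.nii.gz", stack.phantom.roi_mask, stack.phantom)
    (out / "stack.json").write_text(json.dumps(meta, indent=2))
    return out


def load_calibration_stack(path) -> CalibrationStack:
    d = Path(path)
    meta = json.loads((d / "stack.json").read_text())
    grid_shape = tuple(meta["grid_shape"])
    phantom = Phantom(
        grid_shape,
        tuple(meta["voxel_size_mm"]),
        load_mask(d / "body_mask.nii.gz"),
        load_mask(d / "roi_mask.nii.gz"),
    )
    images = np.empty((len(meta["measurements"]),) + grid_shape, dtype=np.complex128)
    for m, entry in enumerate(meta["measurements"]):
        mag = np.asarray(nib.load(str(d / entry["magnitude"])).dataobj)
        ph = np.asarray(nib.load(str(d / entry["phase"])).dataobj)
        images[m] = mag * np.exp(1j * ph)
    receive = np.asarray(nib.load(str(d / "receive_profile.nii.gz")).dataobj)
    return CalibrationStack(
        images, tuple(meta["scheme"]), float(meta["noise_sigma"]), receive, phantom
    )


def save_vops(vops: VOPSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=vops.matrices)
        f.attrs["scaling"] = "median unit-norm quadratic form = 1"


def load_vops(path) -> VOPSet:
    with h5py.File(path, "r") as f:
        return VOPSet(f["matrices"][...])


def save_shim(shim: ShimWeights, path, provenance: dict | None = None) -> None:
    payload = {
        "mode": shim.mode,
        "power_norm": shim.power_norm,
        "magnitude": [float(a) for a in np.abs(shim.weights)],
        "phase_rad": [float(p) for p in np.angle(shim.weights)],
    }
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2))


def load_shim(path) -> ShimWeights:
    payload = json.loads(Path(path).read_text())
    w = np.asarray(payload["magnitude"]) * np.exp(1j * np.asarray(payload["phase_rad"]))
    return ShimWeights(w, payload["mode"], payload["power_norm"])


def save_pulse(pulse: KTPulse, path, provenance: dict | None = None) -> None:
    payload = {
        "n_kt": pulse.n_kt,
        "blip_us": pulse.blip_us,
        "subpulse_us": pulse.subpulse_us,
        "nominal_fa_deg": pulse.nominal_fa_deg,
        "scale_deg": pulse.scale_deg,
        "k_locations_rad_per_m": pulse.k_locations.tolist(),
        "weights": [
            [[float(w.real), float(w.imag)] for w in row] for row in pulse.weights
        ],
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_pulse(path) -> KTPulse:
    payload = json.loads(Path(path).read_text())
    w = np.asarray(
        [[complex(re, im) for re, im in row] for row in payload["weights"]]
    )
    return KTPulse(
        k_locations=np.asarray(payload["k_locations_rad_per_m"]),
        weights=w,
        subpulse_us=payload["subpulse_us"],
        blip_us=payload["blip_us"],
        nominal_fa_deg=payload["nominal_fa_deg"],
        scale_deg=payload.get("scale_deg", 10.0),
    )


def save_lcurve(lcurve: LCurve, path) -> None:
    df = lcurve.to_dataframe()
    df.to_csv(path, index=False)


def load_lcurve(path, fingerprint: dict | None = None) -> LCurve:
    import pandas as pd

    df = pd.read_csv(path)
    return LCurve(
        betas=df["beta"].to_numpy(),
        power=df["power"].to_numpy(),
        cv=df["cv"].to_numpy(),
        fingerprint=fingerprint or {},
    )


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration for provenance blocks."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
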