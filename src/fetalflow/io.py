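"""File formats: the raw HDF5 container, NIfTI volumes, and report files.

HDF5 layout (version attribute ``fetalflow-raw-1``)::

    /samples            complex (readout, kx, coil)
    /meta/time          s
    /meta/ky, /meta/kz  phase-encode indices
    /meta/segment       Hadamard encoding segment 0..3
    /meta/resp          respiratory belt value (optional)
    /coil_sens          complex (coil, x, y, z)
    /triggers           cardiac trigger times, s
    /header             attrs: matrix_size, voxel_size, venc, n_frames
    /truth/*            optional simulator ground truth (per-readout shift,
                        cardiac frame, vessel masks, velocity field)

A bespoke layout is used rather than a full scanner-raw standard because the
pipeline needs only these few metadata fields plus ground-truth attachments.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import h5py
import nibabel as nib
import numpy as np

from .recon import ReconResult
from .sampling import KSpaceData

RAW_VERSION = "fetalflow-raw-1"


class SchemaError(RuntimeError):
    """The container is missing a required dataset or attribute."""


def write_container(kspace: KSpaceData, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = RAW_VERSION
        f.create_dataset("samples", data=kspace.samples)
        meta = f.create_group("meta")
        meta.create_dataset("time", data=kspace.time)
        meta.create_dataset("ky", data=kspace.ky)
        meta.create_dataset("kz", data=kspace.kz)
        meta.create_dataset("segment", data=kspace.segment)
        if kspace.resp is not None:
            meta.create_dataset("resp", data=kspace.resp)
        f.create_dataset("coil_sens", data=kspace.coil_sens)
        f.create_dataset("triggers", data=kspace.trigger_times)
        hdr = f.create_group("header")
        hdr.attrs["matrix_size"] = kspace.matrix_size
        hdr.attrs["voxel_size"] = kspace.voxel_size
        hdr.attrs["venc"] = kspace.venc
        hdr.attrs["n_frames"] = kspace.n_frames
        truth = kspace.truth or {}
        if truth:
            tg = f.create_group("truth")
            if "shift_mm" in truth:
                tg.create_dataset("shift_mm", data=np.asarray(truth["shift_mm"]))
            if "frame" in truth:
                tg.create_dataset("frame", data=np.asarray(truth["frame"]))
            scene = truth.get("scene")
            if scene is not None:
                mg = tg.create_group("vessel_masks")
                for name, m in scene.vessel_masks.items():
                    mg.create_dataset(name, data=m.astype(np.uint8))
                tg.create_dataset("velocity_field", data=scene.velocity_field)
                tg.create_dataset("magnitude_map", data=scene.magnitude_map)
                tg.attrs["phi0"] = scene.phi0


def read_container(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != RAW_VERSION:
            raise SchemaError(f"unknown or missing container version in {path}")
        for ds in ("samples", "meta/time", "meta/ky", "meta/kz", "meta/segment",
                   "coil_sens", "triggers"):
            if ds not in f:
                raise SchemaError(f"missing required dataset /{ds}")
        hdr = f["header"]
        for attr in ("matrix_size", "voxel_size", "venc", "n_frames"):
            if attr not in hdr.attrs:
                raise SchemaError(f"missing required header attribute '{attr}'")
        resp = f["meta/resp"][()] if "resp" in f["meta"] else None
        truth: Dict = {}
        if "truth" in f:
            tg = f["truth"]
            if "shift_mm" in tg:
                truth["shift_mm"] = tg["shift_mm"][()]
            if "frame" in tg:
                truth["frame"] = tg["frame"][()]
            if "vessel_masks" in tg:
                truth["vessel_masks"] = {
                    k: tg["vessel_masks"][k][()].astype(bool)
                    for k in tg["vessel_masks"]
                }
            if "velocity_field" in tg:
                truth["velocity_field"] = tg["velocity_field"][()]
            if "phi0" in tg.attrs:
                truth["phi0"] = float(tg.attrs["phi0"])
        return KSpaceData(
            samples=f["samples"][()],
            time=f["meta/time"][()],
            ky=f["meta/ky"][()],
            kz=f["meta/kz"][()],
            segment=f["meta/segment"][()],
            resp=resp,
            matrix_size=tuple(int(v) for v in hdr.attrs["matrix_size"]),
            voxel_size=tuple(float(v) for v in hdr.attrs["voxel_size"]),
            venc=float(hdr.attrs["venc"]),
            n_frames=int(hdr.attrs["n_frames"]),
            trigger_times=f["triggers"][()],
            coil_sens=f["coil_sens"][()],
            truth=truth,
        )


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_mask_nifti(mask: np.ndarray, voxel_size, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size)), str(path))


def read_mask_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_recon_result(result: ReconResult, out_dir, prefix: str = "") -> None:
    """ReconResult as NIfTI: magnitude and vx/vy/vz as 4D, PC-MRA as 3D."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(result.voxel_size)
    desc = f"venc={result.venc}cm/s;{result.provenance}".encode()[:79]

    def save4d(data_t_xyz, name):
        img = nib.Nifti1Image(
            np.moveaxis(data_t_xyz, 0, -1).astype(np.float32), aff
        )
        img.header["descrip"] = desc
        nib.save(img, str(out / f"{prefix}{name}.nii"))

    save4d(result.magnitude, "magnitude")
    for i, comp in enumerate("xyz"):
        save4d(result.velocity[:, i], f"v{comp}")
    img = nib.Nifti1Image(result.pcmra.astype(np.float32), aff)
    img.header["descrip"] = desc
    nib.save(img, str(out / f"{prefix}pcmra.nii"))
    sidecar = {
        "venc_cm_s": result.venc,
        "voxel_size_mm": list(result.voxel_size),
        "provenance": result.provenance,
        "n_frames": int(result.magnitude.shape[0]),
    }
    (out / f"{prefix}recon.json").write_text(json.dumps(sidecar, indent=2))


def read_recon_result(out_dir, prefix: str = "") -> ReconResult:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{prefix}recon.json").read_text())

    def load4d(name):
        arr = np.asarray(nib.load(str(out / f"{prefix}{name}.nii")).dataobj)
        return np.moveaxis(arr, -1, 0)

    mag = load4d("magnitude")
    vel = np.stack([load4d(f"v{c}") for c in "xyz"], axis=1)
    pcmra = np.asarray(nib.load(str(out / f"{prefix}pcmra.nii")).dataobj)
    return ReconResult(
        magnitude=mag, velocity=vel, pcmra=pcmra,
        venc=float(sidecar["venc_cm_s"]),
        voxel_size=tuple(sidecar["voxel_size_mm"]),
        provenance=sidecar["provenance"],
    )
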