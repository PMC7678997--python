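"""Thin NIfTI helpers around nibabel for phantom volumes and scalar maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "save_phantom", "affine_for"]


def affine_for(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def save_volume(data: np.ndarray, path: str | Path, voxel_size: float = 2.0) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine_for(voxel_size))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return np.asarray(img.get_fdata()), voxel_size


def save_phantom(phantom, out_dir: str | Path, stem: str) -> dict:
    """Write a phantom as 4D signal + 3D masks + gradient tables + a
    ground-truth sidecar CSV; returns the path map."""
    from .gradients import write_bval_bvec

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vol4d = np.zeros(phantom.grid_shape + (phantom.scheme.n_volumes,), dtype=np.float32)
    idx = phantom.in_brain_index()
    flat = vol4d.reshape(-1, phantom.scheme.n_volumes)
    flat[idx] = phantom.signal
    paths["dwi"] = out / f"{stem}_dwi.nii.gz"
    save_volume(vol4d, paths["dwi"], phantom.voxel_size)

    for name in ("left_mask", "right_mask", "wm_mask", "wmh_mask", "icv_mask"):
        paths[name] = out / f"{stem}_{name}.nii.gz"
        save_volume(getattr(phantom, name).astype(np.float32), paths[name], phantom.voxel_size)

    paths["bval"] = out / f"{stem}.bval"
    paths["bvec"] = out / f"{stem}.bvec"
    write_bval_bvec(phantom.scheme, paths["bval"], paths["bvec"])

    import pandas as pd

    from .tensor import tensor_scalars

    vals = np.linalg.eigvalsh(phantom.true_tensors)[..., ::-1]
    sc = tensor_scalars(np.clip(vals, 0, None))
    truth = pd.DataFrame(
        {
            "voxel_flat_index": idx,
            "true_fw": phantom.true_fractions,
            "true_fa": sc["fa"],
            "true_md": sc["md"],
            "true_s0": phantom.true_s0,
        }
    )
    paths["truth"] = out / f"{stem}_truth.csv"
    truth.to_csv(paths["truth"], index=False)
    return paths
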