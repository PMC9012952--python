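"""I/O: NIfTI ingestion, dense tensor storage (NPZ/HDF5), TSV tables.

Voxel flattening order: masked voxels are taken in Fortran (column-major)
scan order over the 3-D grid, so row v of the tensor corresponds to the
v-th True voxel of ``mask.ravel(order='F')``.  The mapping is kept in
``DataTensor.voxel_index`` so spatial maps can be written back to volume
space with the mask's grid and affine.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .tensor_ops import DataTensor

try:  # optional at import time; required only for NIfTI paths
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None


def _require_nibabel():
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required for NIfTI input/output")
    return nib


def load_fmri_tensor(nifti_paths: list[str | Path], mask_path: str | Path) -> DataTensor:
    """Flatten K per-subject 4-D volumes into a masked V x T x K tensor.

    All volumes must share the mask's 3-D grid and a common number of time
    points; the mask must be binary with at least one in-brain voxel.
    """
    nib_mod = _require_nibabel()
    mask_img = nib_mod.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask is not binary: values {uniq[:10]}")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask selects zero voxels")
    flat_mask = mask.ravel(order="F")
    voxel_rows = np.flatnonzero(flat_mask)
    coords = np.stack(np.unravel_index(voxel_rows, mask.shape, order="F"), axis=1)

    slabs = []
    T_ref: int | None = None
    for path in nifti_paths:
        img = nib_mod.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4-D volume, got shape {data.shape}")
        if data.shape[:3] != mask.shape:
            raise ValueError(
                f"{path}: grid {data.shape[:3]} does not match mask grid {mask.shape}"
            )
        if T_ref is None:
            T_ref = data.shape[3]
        elif data.shape[3] != T_ref:
            raise ValueError(
                f"{path}: {data.shape[3]} time points, expected {T_ref}"
            )
        flat = data.reshape(-1, data.shape[3], order="F")
        slabs.append(flat[voxel_rows, :])
    X = np.stack(slabs, axis=2)
    return DataTensor(values=X, voxel_index=coords)


def map_to_volume(
    values: np.ndarray, voxel_index: np.ndarray, grid: tuple[int, ...]
) -> np.ndarray:
    """Scatter a per-voxel vector back into a dense volume (zeros elsewhere)."""
    vol = np.zeros(grid, dtype=float)
    vol[tuple(np.asarray(voxel_index).T)] = np.asarray(values, dtype=float).ravel()
    return vol


def save_map_nifti(
    values: np.ndarray,
    voxel_index: np.ndarray,
    mask_path: str | Path,
    out_path: str | Path,
) -> None:
    """Write a spatial map as a NIfTI volume on the mask's grid and affine."""
    nib_mod = _require_nibabel()
    mask_img = nib_mod.load(str(mask_path))
    vol = map_to_volume(values, voxel_index, mask_img.shape[:3])
    nib_mod.save(nib_mod.Nifti1Image(vol, mask_img.affine, mask_img.header), str(out_path))


def save_tensor_npz(path: str | Path, X: DataTensor) -> None:
    """Store the dense tensor as NPZ with named arrays ``X`` and ``mask_index``."""
    arrays = {"X": X.values}
    if X.voxel_index is not None:
        arrays["mask_index"] = X.voxel_index
    np.savez(str(path), **arrays)


def load_tensor(path: str | Path) -> DataTensor:
    """Load a tensor from NPZ or HDF5 (named arrays ``X``, ``mask_index``)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            values = f["X"][()]
            idx = f["mask_index"][()] if "mask_index" in f else None
    else:
        with np.load(path) as f:
            values = f["X"]
            idx = f["mask_index"] if "mask_index" in f.files else None
    return DataTensor(values=values, voxel_index=idx)


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "slctkd": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "python": sys.version.split()[0],
    }


def save_results(path: str | Path, fit, config: dict | None = None) -> None:
    """Persist a fit (S, B, G, E, eps trace) plus provenance to HDF5.

    The config echo and library versions are stored as JSON attributes so a
    run can be reproduced from its output file alone.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("S", "B", "G", "E", "eps_trace"):
            f.create_dataset(name, data=np.asarray(getattr(fit, name)))
        f.attrs["converged_reason"] = fit.converged_reason
        f.attrs["config"] = json.dumps(config or {}, sort_keys=True)
        f.attrs["versions"] = json.dumps(_versions())


def load_results(path: str | Path):
    """Reload a saved fit; returns (FitResult, config dict)."""
    from .solver import FitResult

    with h5py.File(path, "r") as f:
        fit = FitResult(
            S=f["S"][()],
            B=f["B"][()],
            G=f["G"][()],
            E=f["E"][()],
            eps_trace=f["eps_trace"][()],
            converged_reason=str(f.attrs["converged_reason"]),
        )
        config = json.loads(f.attrs["config"])
    return fit, config


def save_table_tsv(path: str | Path, table: np.ndarray, columns: list[str], index_name: str = "subject") -> None:
    """Write a subjects-as-rows table as TSV."""
    df = pd.DataFrame(np.asarray(table), columns=columns)
    df.index = np.arange(1, len(df) + 1)
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Read a JSON or YAML configuration file mirroring the hyper-parameters."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
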