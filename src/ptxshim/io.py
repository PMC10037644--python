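"""File formats: HDF5 field/Q containers, NIfTI maps, JSON vectors, YAML configs.

The HDF5 field container is the substitution point for external full-wave
solvers: any per-channel complex B1+/E dataset written in this layout can
be fed to the SAR and shimming stages in place of the built-in synthetic
model.  Layout: ``/B1plus[channel, z, y, x]``, ``/E[channel, axis, z, y, x]``
with attributes ``spacing_mm``, ``origin_mm``, ``frequency``, ``kind`` and
``normalization`` (must be ``"per_sqrtW"``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .em import ChannelFieldSet
from .sar import QMatrixSet, VOPSet
from .scene import VoxelGrid
from .shim import ExcitationVector, ParetoFront


class SchemaError(ValueError):
    """Container is missing or disagrees on a required key/attribute."""


REQUIRED_FIELD_ATTRS = ("spacing_mm", "origin_mm", "frequency", "kind", "normalization")


def save_fields(path, fields: ChannelFieldSet) -> None:
    g = fields.grid
    with h5py.File(path, "w") as f:
        # container axis order is [channel, z, y, x] per the interchange contract
        f.create_dataset("B1plus", data=np.transpose(fields.B1plus, (0, 3, 2, 1)))
        f.create_dataset("E", data=np.transpose(fields.E, (0, 1, 4, 3, 2)))
        f.attrs["spacing_mm"] = g.spacing * 1e3
        f.attrs["origin_mm"] = np.asarray(g.origin) * 1e3
        f.attrs["frequency"] = fields.frequency
        f.attrs["kind"] = fields.kind
        f.attrs["normalization"] = "per_sqrtW"


def load_fields(path) -> ChannelFieldSet:
    with h5py.File(path, "r") as f:
        for key in REQUIRED_FIELD_ATTRS:
            if key not in f.attrs:
                raise SchemaError(f"field container missing attribute {key!r}")
        if f.attrs["normalization"] != "per_sqrtW":
            raise SchemaError("field container normalization must be 'per_sqrtW'")
        B1 = np.transpose(f["B1plus"][...], (0, 3, 2, 1))
        E = np.transpose(f["E"][...], (0, 1, 4, 3, 2))
        spacing = float(f.attrs["spacing_mm"]) * 1e-3
        origin = tuple(np.asarray(f.attrs["origin_mm"]) * 1e-3)
        grid = VoxelGrid(shape=B1.shape[1:], spacing=spacing, origin=origin)
        return ChannelFieldSet(grid=grid, B1plus=B1, E=E,
                               kind=str(f.attrs["kind"]),
                               frequency=float(f.attrs["frequency"]))


def save_q_matrices(path, q: QMatrixSet, vops: VOPSet | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Q", data=q.Q)
        f.create_dataset("voxel_index", data=q.voxel_index)
        f.attrs["level"] = q.level
        f.attrs["shape"] = q.grid.shape
        f.attrs["spacing_mm"] = q.grid.spacing * 1e3
        f.attrs["origin_mm"] = np.asarray(q.grid.origin) * 1e3
        f.attrs["normalization"] = "per_sqrtW"
        if vops is not None:
            f.create_dataset("VOP", data=vops.vops)
            f.attrs["epsilon"] = vops.epsilon
            f.attrs["vop_max_norm"] = vops.max_norm


def load_q_matrices(path) -> tuple[QMatrixSet, VOPSet | None]:
    with h5py.File(path, "r") as f:
        if "normalization" not in f.attrs:
            raise SchemaError("Q container missing attribute 'normalization'")
        grid = VoxelGrid(shape=tuple(int(s) for s in f.attrs["shape"]),
                         spacing=float(f.attrs["spacing_mm"]) * 1e-3,
                         origin=tuple(np.asarray(f.attrs["origin_mm"]) * 1e-3))
        q = QMatrixSet(grid=grid, voxel_index=f["voxel_index"][...],
                       Q=f["Q"][...], level=str(f.attrs["level"]))
        vops = None
        if "VOP" in f:
            vops = VOPSet(vops=f["VOP"][...], epsilon=float(f.attrs["epsilon"]),
                          max_norm=float(f.attrs["vop_max_norm"]))
        return q, vops


# ---------------------------------------------------------------------------

def grid_affine(grid: VoxelGrid) -> np.ndarray:
    """NIfTI affine encoding the grid spacing and origin, in millimetres."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = grid.spacing * 1e3
    aff[:3, 3] = np.asarray(grid.origin) * 1e3
    return aff


def save_map_nifti(path, data: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid_affine(grid))
    nib.save(img, str(path))


def load_map_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float32), img.affine


# ---------------------------------------------------------------------------

def _complex_list(u: np.ndarray) -> list[dict]:
    return [{"re": float(c.real), "im": float(c.imag)} for c in u]


def _complex_array(lst) -> np.ndarray:
    return np.array([complex(d["re"], d["im"]) for d in lst])


def vector_to_dict(vec: ExcitationVector, objectives: dict | None = None) -> dict:
    d = {"method": vec.method, "K": vec.K, "normalization": vec.normalization,
         "u": _complex_list(vec.u), "seed": vec.seed}
    if objectives:
        d["objectives"] = objectives
    return d


def save_vector(path, vec: ExcitationVector, objectives: dict | None = None) -> None:
    Path(path).write_text(json.dumps(vector_to_dict(vec, objectives), indent=2))


def load_vector(path) -> ExcitationVector:
    d = json.loads(Path(path).read_text())
    for key in ("method", "K", "u", "normalization"):
        if key not in d:
            raise SchemaError(f"excitation vector file missing key {key!r}")
    return ExcitationVector(u=_complex_array(d["u"]), K=float(d["K"]),
                            normalization=d["normalization"], method=d["method"],
                            seed=d.get("seed"))


def save_front(path, front: ParetoFront) -> None:
    members = [{"vector": vector_to_dict(vec),
                "objectives": obj.__dict__} for vec, obj in front.members]
    blob = {"members": members,
            "ga": {"pop_size": front.config.pop_size,
                   "generations": front.config.generations,
                   "seed": front.config.seed, "tol": front.config.tol},
            "n_generations": front.n_generations}
    Path(path).write_text(json.dumps(blob, indent=2))


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)
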