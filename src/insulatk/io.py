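"""File formats: NIfTI masks, Wavefront OBJ meshes, CSV/JSON tables.

CSV output uses 6 significant digits; JSON keeps full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, NetworkTrajectory
from .dynamics import TrajectoryEI
from .geometry import MaskVolume, SurfaceMesh
from .somatotopy import RegionSamples, RegionSet

__all__ = [
    "save_mask",
    "load_mask",
    "save_obj",
    "load_obj",
    "save_regions_csv",
    "load_regions_csv",
    "save_samples_csv",
    "load_samples_csv",
    "save_matrix_csv",
    "load_matrix_csv",
    "save_edge_list_json",
    "save_trajectory_csv",
    "save_network_trajectory_csv",
    "save_json",
]

CSV_FLOAT_FORMAT = "%.6g"

#: NIfTI xform code for MNI 152 space.
_NIFTI_MNI_CODE = 4


# -- NIfTI ---------------------------------------------------------------

def save_mask(mask: MaskVolume, path) -> None:
    """Write a binary mask as NIfTI-1 (uint8, 1 = inside, MNI sform/qform)."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_xyzt_units("mm")
    img.set_sform(mask.affine, code=_NIFTI_MNI_CODE)
    img.set_qform(mask.affine, code=_NIFTI_MNI_CODE)
    nib.save(img, str(path))


def load_mask(path) -> MaskVolume:
    """Read a NIfTI binary mask back into a :class:`MaskVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.uint8)
    affine = img.affine
    voxel = float(np.abs(np.linalg.det(affine[:3, :3])) ** (1.0 / 3.0))
    return MaskVolume(data=data, affine=affine, voxel_size=voxel)


# -- Wavefront OBJ -------------------------------------------------------

def save_obj(mesh: SurfaceMesh, path) -> None:
    """Write a triangle mesh as Wavefront OBJ (v/f records, 1-based indices)."""
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
    lines += [f"f {i + 1} {j + 1} {k + 1}" for i, j, k in mesh.faces]
    Path(path).write_text("\n".join(lines) + "\n")


def load_obj(path) -> SurfaceMesh:
    """Read v/f records of a Wavefront OBJ triangle mesh."""
    vertices, faces = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            vertices.append([float(p) for p in parts[1:4]])
        elif parts[0] == "f":
            faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return SurfaceMesh(
        vertices=np.array(vertices, dtype=float),
        faces=np.array(faces, dtype=int) if faces else np.empty((0, 3), dtype=int),
        grid_shape=(0, 0),
    )


# -- coordinate tables ---------------------------------------------------

def save_regions_csv(regions: RegionSet, path) -> None:
    regions.to_frame().to_csv(path, float_format=CSV_FLOAT_FORMAT)


def load_regions_csv(path) -> RegionSet:
    return RegionSet.from_frame(pd.read_csv(path))


def save_samples_csv(samples: RegionSamples, path) -> None:
    samples.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def load_samples_csv(path) -> RegionSamples:
    return RegionSamples.from_frame(pd.read_csv(path))


# -- connectivity --------------------------------------------------------

def save_matrix_csv(conn: ConnectivityMatrix, path) -> None:
    """5x5 matrix with a header row and an index column of labels."""
    conn.to_frame().to_csv(path, float_format=CSV_FLOAT_FORMAT)


def load_matrix_csv(path) -> ConnectivityMatrix:
    return ConnectivityMatrix.from_frame(pd.read_csv(path, index_col=0))


def save_edge_list_json(conn: ConnectivityMatrix, path) -> None:
    Path(path).write_text(json.dumps(conn.edge_list(), indent=2, sort_keys=True) + "\n")


# -- trajectories --------------------------------------------------------

def save_trajectory_csv(traj: TrajectoryEI, path) -> None:
    pd.DataFrame({"t": traj.times, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT
    )


def save_network_trajectory_csv(traj: NetworkTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


# -- generic JSON --------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")
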