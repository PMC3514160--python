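"""Reading and writing of velocity datasets.

Two on-disk dialects are supported:

* **hdf5** (native): a single self-describing file with datasets
  ``/velocity/x|y|z``, ``/mask/myo``, ``/mask/static``,
  ``/contours/endo|epi`` and the acquisition metadata as attributes of
  ``/meta``.
* **nifti_bundle** (interchange): a directory with one 4D NIfTI per
  velocity component (``velocity_x.nii`` ...), mask NIfTIs, and a JSON
  sidecar (``meta.json``) holding the acquisition metadata and the
  contour point lists.

Contour point lists are stored with a uniform point count per
(phase, slice) so all containers stay rectangular.  Files may be written
in either slice order; on read everything is normalised to the internal
convention (slice index 0 = most apical), and a normalisation flag is
recorded on the returned dataset (``source_slice_order``).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np

from .datamodel import AcquisitionMeta, VelocityDataset

__all__ = ["read_dataset", "write_dataset", "LoadError", "DimensionError"]

_COMPONENTS = ("x", "y", "z")
_FORMAT_VERSION = 1


class LoadError(IOError):
    """A declared array or metadata field is missing from the container."""


class DimensionError(LoadError):
    """Array shapes in the container are mutually inconsistent."""


def _flip_slices(ds: VelocityDataset) -> VelocityDataset:
    out = ds.copy()
    out.velocities = ds.velocities[:, :, ::-1].copy()
    out.myo_mask = ds.myo_mask[:, ::-1].copy()
    out.static_mask = ds.static_mask[::-1].copy()
    out.endo_contours = ds.endo_contours[:, ::-1].copy()
    out.epi_contours = ds.epi_contours[:, ::-1].copy()
    return out


# -- HDF5 --------------------------------------------------------------------

def _write_hdf5(ds: VelocityDataset, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        g = f.create_group("velocity")
        for i, c in enumerate(_COMPONENTS):
            d = g.create_dataset(c, data=ds.velocities[i])
            d.attrs["units"] = "cm/s"
        m = f.create_group("mask")
        m.create_dataset("myo", data=ds.myo_mask.astype(np.uint8))
        m.create_dataset("static", data=ds.static_mask.astype(np.uint8))
        c = f.create_group("contours")
        c.create_dataset("endo", data=ds.endo_contours)
        c.create_dataset("epi", data=ds.epi_contours)
        meta = f.create_group("meta")
        for k, v in ds.meta.to_dict().items():
            meta.attrs[k] = v


def _require(f, name, what):
    if name not in f:
        raise LoadError(f"missing {what}")
    return f[name]


def _read_hdf5(path: Path) -> VelocityDataset:
    with h5py.File(path, "r") as f:
        comps = []
        for c in _COMPONENTS:
            comps.append(
                np.asarray(_require(f, f"velocity/{c}", f"velocity component {c}"))
            )
        vel = np.stack(comps, axis=0)
        myo = np.asarray(_require(f, "mask/myo", "mask 'myo'")).astype(bool)
        static = np.asarray(_require(f, "mask/static", "mask 'static'")).astype(bool)
        endo = np.asarray(_require(f, "contours/endo", "contours 'endo'"))
        epi = np.asarray(_require(f, "contours/epi", "contours 'epi'"))
        if "meta" not in f:
            raise LoadError("missing metadata group 'meta'")
        meta = AcquisitionMeta.from_dict(
            {k: v for k, v in f["meta"].attrs.items()}
        )
    return _assemble(vel, myo, static, endo, epi, meta)


# -- NIfTI bundle ------------------------------------------------------------

def _write_nifti_bundle(ds: VelocityDataset, path: Path) -> None:
    import nibabel as nib

    path.mkdir(parents=True, exist_ok=True)
    dx, dy, dz = ds.meta.voxel_size_mm
    affine = np.diag([dx, dy, dz, 1.0])

    def to_xyzt(a):  # (phase, slice, row, col) -> (col, row, slice, phase)
        return np.transpose(a, (3, 2, 1, 0))

    for i, c in enumerate(_COMPONENTS):
        nib.save(
            nib.Nifti1Image(to_xyzt(ds.velocities[i]).astype(np.float64), affine),
            path / f"velocity_{c}.nii",
        )
    nib.save(
        nib.Nifti1Image(to_xyzt(ds.myo_mask.astype(np.uint8)), affine),
        path / "mask_myo.nii",
    )
    nib.save(
        nib.Nifti1Image(
            np.transpose(ds.static_mask.astype(np.uint8), (2, 1, 0)), affine
        ),
        path / "mask_static.nii",
    )
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "meta": ds.meta.to_dict(),
        "contours": {
            "endo": ds.endo_contours.tolist(),
            "epi": ds.epi_contours.tolist(),
        },
    }
    (path / "meta.json").write_text(json.dumps(sidecar))


def _read_nifti_bundle(path: Path) -> VelocityDataset:
    import nibabel as nib

    side = path / "meta.json"
    if not side.exists():
        raise LoadError("missing sidecar 'meta.json'")
    sidecar = json.loads(side.read_text())
    meta = AcquisitionMeta.from_dict(sidecar["meta"])
    try:
        contours = sidecar["contours"]
        endo = np.asarray(contours["endo"], dtype=float)
        epi = np.asarray(contours["epi"], dtype=float)
    except KeyError as e:
        raise LoadError(f"missing contours {e} in sidecar") from None

    def from_xyzt(a):
        return np.transpose(a, (3, 2, 1, 0))

    comps = []
    for c in _COMPONENTS:
        f = path / f"velocity_{c}.nii"
        if not f.exists():
            raise LoadError(f"missing velocity component {c}")
        comps.append(from_xyzt(np.asarray(nib.load(f).dataobj, dtype=float)))
    vel = np.stack(comps, axis=0)
    f = path / "mask_myo.nii"
    if not f.exists():
        raise LoadError("missing mask 'myo'")
    myo = from_xyzt(np.asarray(nib.load(f).dataobj)).astype(bool)
    f = path / "mask_static.nii"
    if not f.exists():
        raise LoadError("missing mask 'static'")
    static = np.transpose(np.asarray(nib.load(f).dataobj), (2, 1, 0)).astype(bool)
    return _assemble(vel, myo, static, endo, epi, meta)


# -- shared assembly ---------------------------------------------------------

def _assemble(vel, myo, static, endo, epi, meta) -> VelocityDataset:
    if myo.shape != vel.shape[1:]:
        raise DimensionError(
            f"myo_mask shape {myo.shape} does not match velocity shape {vel.shape[1:]}"
        )
    if static.shape != vel.shape[2:]:
        raise DimensionError(
            f"static_mask shape {static.shape} does not match {vel.shape[2:]}"
        )
    source_order = meta.slice_order
    ds = VelocityDataset(
        velocities=vel,
        myo_mask=myo,
        static_mask=static,
        endo_contours=endo,
        epi_contours=epi,
        meta=meta,
    )
    if source_order == "base_to_apex":
        ds = _flip_slices(ds)
        ds.meta.slice_order = "apex_to_base"
    ds.validate()
    ds.source_slice_order = source_order
    return ds


# -- public API --------------------------------------------------------------

def write_dataset(ds: VelocityDataset, path, format: str = "hdf5") -> None:
    """Write a dataset losslessly in the requested dialect.

    A dataset whose metadata declares ``base_to_apex`` slice order is
    written with its slice axis reversed (the file then matches its
    declared order); in-memory datasets are always apex-first.
    """
    path = Path(path)
    if ds.meta.slice_order == "base_to_apex":
        ds = _flip_slices(ds)   # file stores base-first, metadata says so
    if format == "hdf5":
        _write_hdf5(ds, path)
    elif format == "nifti_bundle":
        _write_nifti_bundle(ds, path)
    else:
        raise ValueError(f"unknown format {format!r} (hdf5 | nifti_bundle)")


def read_dataset(path, format: str = None) -> VelocityDataset:
    """Read and validate a dataset; slices normalised apex-first.

    The original on-file slice order is recorded on the returned object as
    ``source_slice_order``.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such path: {path}")
    if format is None:
        if path.is_dir():
            format = "nifti_bundle"
        elif h5py.is_hdf5(os.fspath(path)):
            format = "hdf5"
        else:
            raise LoadError(f"cannot identify the container format of {path}")
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "nifti_bundle":
        return _read_nifti_bundle(path)
    raise ValueError(f"unknown format {format!r} (hdf5 | nifti_bundle)")
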