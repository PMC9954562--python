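"""Reading and writing masks, volumes and tables.

Masks travel as single-page uint8 TIFF (0/255) with the physical pixel size
in a JSON sidecar (``<name>.json`` next to the image); volumes as NIfTI with
the voxel size (mm) in the affine, or as multi-page TIFF with a sidecar.
Tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .growth import CountSeries
from .morphometry import Mask2D, Volume3D


def write_mask(mask: Mask2D, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.pixels.astype(np.uint8) * 255)
    sidecar = {
        "pixel_size_um": mask.pixel_size,
        "object_id": mask.object_id,
        "time_d": mask.time,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_mask(path: str | Path) -> Mask2D:
    path = Path(path)
    pixels = tifffile.imread(path) > 0
    meta = json.loads(path.with_suffix(".json").read_text())
    return Mask2D(
        pixels, meta["pixel_size_um"],
        object_id=meta.get("object_id", path.stem),
        time=meta.get("time_d"),
    )


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".tif" or path.suffix == ".tiff":
        tifffile.imwrite(path, volume.voxels.astype(np.uint8) * 255)
        path.with_suffix(".json").write_text(json.dumps(
            {"voxel_size_mm": volume.voxel_size,
             "tumor_id": volume.tumor_id}, indent=1))
    else:
        affine = np.diag([volume.voxel_size] * 3 + [1.0])
        nib.save(
            nib.Nifti1Image(volume.voxels.astype(np.uint8), affine), path
        )
    return path


def read_volume(path: str | Path, tumor_id: str | None = None) -> Volume3D:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        voxels = tifffile.imread(path) > 0
        meta = json.loads(path.with_suffix(".json").read_text())
        return Volume3D(voxels, meta["voxel_size_mm"],
                        tumor_id=tumor_id or meta.get("tumor_id", path.stem))
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("anisotropic voxels are not supported")
    return Volume3D(np.asarray(img.dataobj) > 0, float(zooms[0]),
                    tumor_id=tumor_id or path.stem.replace(".nii", ""))


def write_counts(series_list, path: str | Path) -> Path:
    rows = []
    for s in series_list:
        for t, n in zip(s.times, s.counts):
            rows.append({"culture_id": s.culture_id,
                         "replicate_id": s.replicate_id,
                         "time_d": t, "cells": int(n)})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_counts(path: str | Path) -> list[CountSeries]:
    df = pd.read_csv(path)
    out = []
    for (cid, rid), sub in df.groupby(["culture_id", "replicate_id"],
                                      dropna=False, sort=True):
        sub = sub.sort_values("time_d")
        out.append(CountSeries(sub["time_d"].to_numpy(),
                               sub["cells"].to_numpy(),
                               culture_id=str(cid), replicate_id=str(rid)))
    return out
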