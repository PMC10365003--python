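"""On-disk formats.

Primary format is NIfTI plus a JSON sidecar carrying the echo times in
ms (the field's portable, PHI-free choice); DICOM series with per-image
EchoTime tags are read but never written.  Decay curves and cohorts
travel as plain CSV; CSV files written by this package carry ``#``
provenance header lines and readers skip them.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import EchoSeries, EchoTrain, ImageStack
from .exceptions import FormatError, InvalidInputError
from .mapping import T2StarMap

__all__ = [
    "write_stack", "read_stack", "write_mask", "read_mask",
    "write_series_csv", "read_series_csv",
    "write_cohort_csv", "read_cohort_csv", "write_map",
]

SIDECAR_KEY = "EchoTimes_ms"


def _sidecar_path(nii_path: Path) -> Path:
    name = nii_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nii_path.with_name(name[: -len(suffix)] + ".json")
    raise FormatError(f"not a NIfTI path: {nii_path}")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a multi-echo stack as 4-D NIfTI (x, y, 1, echo) + JSON sidecar."""
    path = Path(path)
    data = np.transpose(stack.data, (1, 0, 2))[:, :, None, :]
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({SIDECAR_KEY: list(map(float, stack.echo_train.tes))},
                  fh, indent=2)
    return path


def _order_echoes(tes) -> np.ndarray:
    tes = np.asarray(tes, float)
    if np.any(~np.isfinite(tes)):
        bad = int(np.nonzero(~np.isfinite(tes))[0][0])
        raise FormatError(f"echo {bad}: missing/non-finite echo time")
    uniq, counts = np.unique(tes, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise FormatError(f"duplicate echo time {dup} ms in metadata")
    return np.argsort(tes)


def read_stack(path) -> ImageStack:
    """Read a stack from NIfTI + JSON sidecar, or from a DICOM directory.

    Echoes are sorted ascending by TE regardless of file order; missing or
    duplicate TE metadata raises :class:`FormatError` naming the offender.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise FormatError(f"expected a single slice, got shape {data.shape}")
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise FormatError(f"expected 3-D/4-D stack, got shape {data.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing echo-time sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    tes = meta.get(SIDECAR_KEY)
    if tes is None:
        raise FormatError(f"sidecar {sidecar} lacks {SIDECAR_KEY!r}")
    tes = np.asarray(tes, float)
    if tes.size != data.shape[2]:
        raise FormatError(
            f"sidecar lists {tes.size} echo times but stack has "
            f"{data.shape[2]} frames"
        )
    order = _order_echoes(tes)
    return ImageStack(np.transpose(data, (1, 0, 2))[:, :, order],
                      EchoTrain(tes[order]))


def _read_dicom_dir(path: Path) -> ImageStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FormatError(f"no .dcm files in {path}")
    frames, tes = [], []
    for f in files:
        ds = pydicom.dcmread(str(f))
        te = ds.get("EchoTime")
        if te is None:
            raise FormatError(f"{f.name}: missing EchoTime tag")
        tes.append(float(te))
        frames.append(ds.pixel_array.astype(float))
    tes = np.asarray(tes)
    try:
        order = _order_echoes(tes)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    data = np.stack([frames[i] for i in order], axis=-1)
    return ImageStack(data, EchoTrain(tes[order]))


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8).T,
                             affine=np.eye(4)), str(path))
    return path


def read_mask(path) -> np.ndarray:
    """Read an ROI mask (NIfTI or PNG); nonzero pixels are in-mask."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return arr > 0
    arr = np.asarray(nib.load(str(path)).dataobj)
    return np.squeeze(arr).T > 0


def write_map(t2map: T2StarMap, path) -> Path:
    """Write a T2* map as NIfTI (ms); invalid pixels stored as NaN."""
    path = Path(path)
    nib.save(nib.Nifti1Image(t2map.values.T, affine=np.eye(4)), str(path))
    return path


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_with_header(df: pd.DataFrame, path, header: dict | None,
                       index: bool = False) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index)
    return path


def write_series_csv(series: EchoSeries, path, header: dict | None = None) -> Path:
    df = pd.DataFrame({"te_ms": series.tes, "signal": series.signals})
    return _write_with_header(df, path, header)


def read_series_csv(path) -> EchoSeries:
    df = pd.read_csv(path, comment="#")
    for col in ("te_ms", "signal"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return EchoSeries(EchoTrain(df["te_ms"].to_numpy()),
                      df["signal"].to_numpy())


def write_cohort_csv(cohort: pd.DataFrame, path,
                     header: dict | None = None) -> Path:
    return _write_with_header(cohort, path, header)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "patient_id" not in df.columns:
        raise FormatError(f"{path}: not a cohort table (no patient_id column)")
    return df
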