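"""Reading and writing volumes in standard medical and generic stack formats.

Supported formats: NIfTI-1 (``.nii`` / ``.nii.gz``), a DICOM series
directory, a multipage TIFF stack, and raw binary with a plain-text
sidecar (dims, dtype, order, spacing).  Volumes are returned in the
package's canonical ``(x, y, z)`` order with ``z`` the axial slice axis;
DICOM series are sorted by slice position so the result is invariant under
shuffling of the input file list.

Intensities are mapped to [0, 1] on read according to the source's
normalisation policy and the affine is recorded in ``intensity_map`` so
writing restores the original scale: ``original = scale * value + offset``.
Policies: ``minmax`` (default; a constant-intensity input maps to zero and
sets a degenerate-range flag), ``fixed-window(lo, hi)`` (e.g. a CT
Hounsfield window), or ``none``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
import tifffile

from .core_model import Volume

_RAW_SUFFIXES = {".raw", ".bin"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


class DegenerateRangeWarning(UserWarning):
    """Min-max normalisation hit a constant-intensity input."""


@dataclass
class VolumeSource:
    """A volume location plus its format and normalisation policy.

    ``format`` is auto-detected from the path (directory = DICOM series,
    else by extension) unless given explicitly.  ``window`` carries the
    (lo, hi) bounds for ``fixed-window`` normalisation.
    """

    path: str | Path
    format: str | None = None
    normalisation: str = "minmax"
    window: tuple[float, float] | None = None
    degenerate_range: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.format is None:
            self.format = detect_format(self.path)
        if self.format not in ("nifti", "dicom-series", "tiff-stack",
                               "raw+sidecar"):
            raise ValueError(f"unknown format {self.format!r}")
        if self.normalisation not in ("minmax", "fixed-window", "none"):
            raise ValueError(f"unknown normalisation {self.normalisation!r}")
        if self.normalisation == "fixed-window":
            if self.window is None or not self.window[0] < self.window[1]:
                raise ValueError("fixed-window requires window=(lo, hi), lo < hi")


def detect_format(path: str | Path) -> str:
    path = Path(path)
    if path.is_dir():
        return "dicom-series"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return "tiff-stack"
    if path.suffix.lower() in _RAW_SUFFIXES:
        return "raw+sidecar"
    raise ValueError(f"cannot detect volume format of {path}")


def _normalise(data: np.ndarray, src: VolumeSource) -> tuple[np.ndarray,
                                                             tuple[float, float]]:
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{src.path}: non-finite intensities")
    if src.normalisation == "none":
        return data, (1.0, 0.0)
    if src.normalisation == "fixed-window":
        lo, hi = src.window  # type: ignore[misc]
        return np.clip((data - lo) / (hi - lo), 0.0, 1.0), (hi - lo, lo)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        src.degenerate_range = True
        warnings.warn(
            f"{src.path}: constant intensity {lo}; min-max normalisation "
            "yields an all-zero volume", DegenerateRangeWarning,
            stacklevel=3)
        return np.zeros_like(data), (1.0, lo)
    return (data - lo) / (hi - lo), (hi - lo, lo)


# -- per-format readers ---------------------------------------------------


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple | None]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple | None]:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # non-DICOM files in the directory are ignored
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"{path}: no DICOM images found")

    def position(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=position)
    shapes = {ds.pixel_array.shape for ds in slices}
    if len(shapes) != 1:
        raise ValueError(f"{path}: inconsistent slice dimensions {shapes}")
    spacings = {tuple(getattr(ds, "PixelSpacing", (1.0, 1.0)))
                for ds in slices}
    if len(spacings) != 1:
        raise ValueError(f"{path}: inconsistent pixel spacing {spacings}")
    positions = [position(ds) for ds in slices]
    dz = np.diff(positions)
    if len(dz) and (np.any(dz <= 0) or not np.allclose(dz, dz[0], atol=1e-3)):
        raise ValueError(f"{path}: non-monotone or uneven slice positions")

    def hu(ds) -> np.ndarray:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    # pixel_array is (rows, cols) = (y, x); canonical order is (x, y, z)
    data = np.stack([hu(ds).T for ds in slices], axis=-1)
    sy, sx = (float(v) for v in next(iter(spacings)))
    sz = float(dz[0]) if len(dz) else 1.0
    return data, (sx, sy, sz)


def _read_tiff_stack(path: Path) -> tuple[np.ndarray, tuple | None]:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D TIFF, got shape {data.shape}")
    # pages are axial slices (z, y, x) -> (x, y, z)
    return np.ascontiguousarray(data.transpose(2, 1, 0)).astype(np.float64), None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def _read_raw(path: Path) -> tuple[np.ndarray, tuple | None]:
    meta: dict[str, str] = {}
    for line in _sidecar_path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    dims = tuple(int(t) for t in meta["dims"].split())
    dtype = np.dtype(meta.get("dtype", "float64"))
    order = meta.get("order", "xyz")
    if order != "xyz":
        raise ValueError(f"{path}: unsupported raw order {order!r}")
    spacing = None
    if "spacing" in meta:
        spacing = tuple(float(t) for t in meta["spacing"].split())
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(dims)):
        raise ValueError(f"{path}: raw size {data.size} != dims {dims}")
    return data.reshape(dims).astype(np.float64), spacing


def read_volume(src: VolumeSource | str | Path) -> Volume:
    """Read a volume, normalise intensities and record the affine map."""
    if not isinstance(src, VolumeSource):
        src = VolumeSource(src)
    reader = {
        "nifti": _read_nifti,
        "dicom-series": _read_dicom_series,
        "tiff-stack": _read_tiff_stack,
        "raw+sidecar": _read_raw,
    }[src.format]
    data, spacing = reader(Path(src.path))
    norm, intensity_map = _normalise(data, src)
    return Volume(data=norm, spacing=spacing, intensity_map=intensity_map)


def write_volume(vol: Volume, dst: VolumeSource | str | Path) -> None:
    """Write a volume with the inverse intensity map applied, so the file
    holds values on the original source scale (lossless for float NIfTI,
    TIFF and raw)."""
    if not isinstance(dst, VolumeSource):
        dst = VolumeSource(dst, normalisation="none")
    data = vol.denormalised()
    path = Path(dst.path)
    if dst.format == "nifti":
        affine = np.eye(4)
        if vol.spacing is not None:
            affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
        nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))
    elif dst.format == "tiff-stack":
        tifffile.imwrite(str(path),
                         data.transpose(2, 1, 0).astype(np.float32))
    elif dst.format == "raw+sidecar":
        data.astype(np.float64).tofile(path)
        lines = [f"dims = {data.shape[0]} {data.shape[1]} {data.shape[2]}",
                 "dtype = float64", "order = xyz"]
        if vol.spacing is not None:
            lines.append("spacing = " + " ".join(str(s) for s in vol.spacing))
        _sidecar_path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"writing format {dst.format!r} is not supported")
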