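"""Image-series, mask and ROI containers plus readers/writers.

Conventions used throughout the package:

* arrays are indexed ``(row, col)`` with 0-based indices; row 0 is the most
  cranial line of the stored array and row indices increase caudally,
* positions are reported in mm via ``pixel_spacing``,
* frame times are ``n * frame_interval`` — absolute acquisition timestamps
  are only used for ordering/uniformity checks, never as the time axis.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "ImageSeries",
    "LungMask",
    "RoiSpec",
    "read_series",
    "write_series",
    "write_dicom_series",
    "read_mask",
    "write_mask",
    "write_map",
    "read_config",
    "write_config",
]


@dataclass
class ImageSeries:
    """A free-breathing 2D+t acquisition.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of nonnegative intensities (arbitrary units).
    frame_interval
        Temporal resolution in seconds (e.g. 0.310 s/frame).
    pixel_spacing
        In-plane spacing ``(row_mm, col_mm)``.
    slice_label
        Free-text slice identifier (e.g. ``"aorta"`` or ``"lung"``).
    meta
        Free-form acquisition metadata.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_spacing: tuple[float, float] = (3.91, 3.91)
    slice_label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("an image series needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < 0:
            raise ValueError("frame intensities must be nonnegative")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class LungMask:
    """Binary lung segmentation on the series grid.

    ``excludes_heart_vessels`` records whether large vessels and the heart
    were removed (the convention for ventilation maps); a perfusion mask
    typically keeps the vessels.
    """

    mask: np.ndarray
    excludes_heart_vessels: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0.5
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("empty mask")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def check_grid(self, shape: tuple[int, int]) -> None:
        if self.mask.shape != tuple(shape):
            raise ValueError(f"mask grid {self.mask.shape} does not match series grid {tuple(shape)}")


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest: ``origin`` is the (row, col) of the
    top-left corner (0-based, row increases caudally), ``size`` the edge
    length in px — an int for the square ROIs used by map normalization
    (8 or 12) or ``(height, width)`` for e.g. a diaphragm box."""

    origin: tuple[int, int]
    size: int | tuple[int, int]
    label: Any = None

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI size must be >= 1")

    @property
    def height(self) -> int:
        return self.size if isinstance(self.size, int) else int(self.size[0])

    @property
    def width(self) -> int:
        return self.size if isinstance(self.size, int) else int(self.size[1])

    @property
    def rows(self) -> slice:
        return slice(self.origin[0], self.origin[0] + self.height)

    @property
    def cols(self) -> slice:
        return slice(self.origin[1], self.origin[1] + self.width)

    def check_inside(self, shape: tuple[int, int]) -> None:
        r0, c0 = self.origin
        if r0 < 0 or c0 < 0 or r0 + self.height > shape[0] or c0 + self.width > shape[1]:
            raise ValueError(f"ROI {self.origin}+{self.size} lies outside grid {shape}")

    def check_inside_mask(self, mask: np.ndarray) -> None:
        self.check_inside(mask.shape)
        if not mask[self.rows, self.cols].all():
            raise ValueError(f"ROI {self.origin}+{self.size} overlaps non-mask pixels")


# ---------------------------------------------------------------------------
# series I/O


def _nifti_mod():
    import nibabel as nib

    return nib


def read_series(
    path: str | os.PathLike,
    frame_interval: float | None = None,
    pixel_spacing: tuple[float, float] | None = None,
    slice_label: str = "",
) -> ImageSeries:
    """Read a 2D+t series from a NIfTI file (time as 3rd axis) or a directory
    of single-frame DICOM files.

    ``frame_interval``/``pixel_spacing`` override metadata when given (for
    NIfTI files with unset temporal zoom they are required).
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path, frame_interval, pixel_spacing, slice_label)
    nib = _nifti_mod()
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D NIfTI (row, col, t), got {data.ndim}-D")
    zooms = img.header.get_zooms()
    dt = frame_interval if frame_interval is not None else float(zooms[2]) if len(zooms) > 2 else 0.0
    if not dt > 0:
        raise ValueError("frame_interval missing from NIfTI header; pass it explicitly")
    ps = pixel_spacing if pixel_spacing is not None else (float(zooms[0]), float(zooms[1]))
    frames = np.moveaxis(data, -1, 0)
    return ImageSeries(frames, dt, ps, slice_label, meta={"source": str(path)})


def write_series(series: ImageSeries, path: str | os.PathLike) -> Path:
    """Write an :class:`ImageSeries` as a NIfTI-1 file with time as 3rd axis."""
    nib = _nifti_mod()
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((series.pixel_spacing[0], series.pixel_spacing[1], series.frame_interval))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def _read_dicom_dir(
    path: Path,
    frame_interval: float | None,
    pixel_spacing: tuple[float, float] | None,
    slice_label: str,
) -> ImageSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"} or p.suffix == "")
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"no DICOM image series found in {path}")
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    numbers = [int(d.InstanceNumber) for d in datasets]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        missing = sorted(set(range(numbers[0], numbers[-1] + 1)) - set(numbers))
        raise ValueError(f"DICOM series has gaps: missing instance number(s) {missing}")
    shape0 = (int(datasets[0].Rows), int(datasets[0].Columns))
    for d in datasets:
        if (int(d.Rows), int(d.Columns)) != shape0:
            raise ValueError(
                f"mixed geometries: instance {int(d.InstanceNumber)} has shape "
                f"({int(d.Rows)}, {int(d.Columns)}), expected {shape0}"
            )
    frames = np.stack([d.pixel_array.astype(float) for d in datasets])
    if pixel_spacing is None:
        ps_attr = getattr(datasets[0], "PixelSpacing", None)
        pixel_spacing = (float(ps_attr[0]), float(ps_attr[1])) if ps_attr else (1.0, 1.0)
    if frame_interval is None:
        times = _acquisition_seconds(datasets)
        if times is None:
            raise ValueError("frame_interval missing: no usable DICOM timing tags; pass it explicitly")
        diffs = np.diff(times)
        dt = float(np.median(diffs))
        bad = np.nonzero(np.abs(diffs - dt) > 1e-3)[0]
        if bad.size:
            raise ValueError(
                f"non-uniform frame timing at instance {numbers[int(bad[0]) + 1]}: "
                f"interval {diffs[int(bad[0])]:.6f} s deviates from {dt:.6f} s by more than 1 ms"
            )
        frame_interval = dt
    return ImageSeries(frames, frame_interval, pixel_spacing, slice_label, meta={"source": str(path)})


def _acquisition_seconds(datasets) -> np.ndarray | None:
    times = []
    for d in datasets:
        t = getattr(d, "AcquisitionTime", None) or getattr(d, "ContentTime", None)
        if t is None:
            return None
        t = str(t)
        try:
            sec = int(t[0:2]) * 3600 + int(t[2:4]) * 60 + float(t[4:])
        except (ValueError, IndexError):
            return None
        times.append(sec)
    return np.asarray(times)


def write_dicom_series(series: ImageSeries, directory: str | os.PathLike) -> Path:
    """Write the series as a directory of single-frame secondary-capture DICOM
    files (intensities rounded to uint16 — lossy for non-integer data)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = 1.0
    vmax = float(series.frames.max())
    if vmax > 65535:
        scale = 65535.0 / vmax
    series_uid = generate_uid()
    dt_ms = series.frame_interval * 1000.0
    for i, frame in enumerate(series.frames):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.SeriesDescription = series.slice_label or "series"
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = frame.shape
        ds.PixelSpacing = [str(series.pixel_spacing[0]), str(series.pixel_spacing[1])]
        ds.FrameTime = str(dt_ms)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.round(frame * scale).astype(np.uint16).tobytes()
        ds.save_as(str(directory / f"frame_{i + 1:04d}.dcm"), enforce_file_format=True)
    return directory


# ---------------------------------------------------------------------------
# mask / map I/O


def read_mask(path: str | os.PathLike, excludes_heart_vessels: bool = True) -> LungMask:
    """Read a binary mask from NIfTI (float masks thresholded at > 0.5)."""
    nib = _nifti_mod()
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"mask must be 2-D, got {data.ndim}-D")
    return LungMask(data > 0.5, excludes_heart_vessels=excludes_heart_vessels)


def write_mask(mask: LungMask, path: str | os.PathLike) -> Path:
    nib = _nifti_mod()
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4))
    nib.save(img, str(path))
    return Path(path)


def write_map(fmap, path: str | os.PathLike) -> Path:
    """Write a functional map as NIfTI float, plus a sibling ``.csv`` holding
    the masked mean, masked median and pixel count."""
    nib = _nifti_mod()
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(fmap.values, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))
    inside = np.asarray(fmap.values)[np.asarray(fmap.mask)]
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    csv_path = path.with_name(stem + "_summary.csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "normalized_by", "masked_mean", "masked_median", "n_pixels"])
        w.writerow(
            [
                fmap.kind,
                json.dumps(fmap.normalized_by),
                repr(float(inside.mean())),
                repr(float(np.median(inside))),
                inside.size,
            ]
        )
    return path


def read_map(path: str | os.PathLike, mask: LungMask, kind: str = "Vw"):
    """Read a functional map written by :func:`write_map` back onto ``mask``."""
    from .core import FunctionalMap

    nib = _nifti_mod()
    values = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    return FunctionalMap(values=values, mask=mask.mask, kind=kind)


# ---------------------------------------------------------------------------
# config I/O


def read_config(path: str | os.PathLike) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def write_config(cfg: dict, path: str | os.PathLike) -> Path:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return Path(path)
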