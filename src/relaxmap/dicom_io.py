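"""Reading and writing single-slice DICOM relaxometry series.

A relaxometry study is a directory of single-frame magnitude images, one
per acquisition, in which either TR varies at fixed TE (T1 mapping) or TE
varies at fixed TR (T2 mapping). This module loads such a directory into a
:class:`RelaxationSeries` — a ``rows x cols x K`` stack sorted by the
varied time — and writes series and derived maps back to disk.

Conventions: 0-based ``[row, col]`` indexing with row 0 at the image top
(DICOM pixel-data order); square ROIs are half-open ``[row0, row0+side)``.
Fixture series are stored as 16-bit unsigned integers with
RescaleSlope/RescaleIntercept, the typical clinical magnitude layout.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

__all__ = [
    "SeriesMode",
    "RelaxationSeries",
    "RoiSquare",
    "SeriesFormatError",
    "SeriesShapeError",
    "SeriesProtocolError",
    "read_series",
    "write_series",
    "export_map",
]


class SeriesFormatError(ValueError):
    """A file is not a usable single-frame magnitude DICOM."""


class SeriesShapeError(ValueError):
    """Array dimensions are inconsistent across the series."""


class SeriesProtocolError(ValueError):
    """The held-constant time parameter is not constant."""


class SeriesMode(enum.Enum):
    T1_SERIES = "t1"  # varied TR, fixed TE
    T2_SERIES = "t2"  # varied TE, fixed TR

    @property
    def varied_tag(self) -> str:
        return "RepetitionTime" if self is SeriesMode.T1_SERIES else "EchoTime"

    @property
    def fixed_tag(self) -> str:
        return "EchoTime" if self is SeriesMode.T1_SERIES else "RepetitionTime"


@dataclass
class RelaxationSeries:
    """Stack of co-registered magnitude images over a varied time parameter.

    pixels
        ``rows x cols x K`` float array of non-negative intensities.
    times
        The K varied times in ms, strictly increasing.
    mode
        T1_SERIES (varied TR) or T2_SERIES (varied TE).
    fixed_time
        The held-constant TE (T1 mode) or TR (T2 mode), ms.
    """

    pixels: np.ndarray
    times: np.ndarray
    mode: SeriesMode
    fixed_time: float
    pixel_spacing: tuple[float, float] | None = None
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.pixels.ndim != 3:
            raise SeriesShapeError(
                f"pixels must be rows x cols x K, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[2] != self.times.size:
            raise SeriesShapeError(
                f"{self.pixels.shape[2]} frames but {self.times.size} times"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pixels < 0):
            raise ValueError("magnitude intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[2]

    def pixel_vectors(self) -> np.ndarray:
        """All per-pixel intensity-vs-time vectors, row-major, (N, K)."""
        return self.pixels.reshape(-1, self.n_frames)


@dataclass(frozen=True)
class RoiSquare:
    """Axis-aligned square region of interest, half-open in both axes."""

    row0: int
    col0: int
    side: int

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError(f"ROI side must be >= 1, got {self.side}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.side > shape[0] or self.col0 + self.side > shape[1]:
            raise ValueError(f"ROI {self} exceeds image of shape {shape}")

    def overlaps(self, other: "RoiSquare") -> bool:
        return not (
            self.row0 + self.side <= other.row0
            or other.row0 + other.side <= self.row0
            or self.col0 + self.side <= other.col0
            or other.col0 + other.side <= self.col0
        )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.side),
            slice(self.col0, self.col0 + self.side),
        )


def _read_one(path: Path) -> Dataset:
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with filename context
        raise SeriesFormatError(f"{path}: not a readable DICOM file ({exc})") from exc
    for tag in ("RepetitionTime", "EchoTime"):
        if getattr(ds, tag, None) is None:
            raise SeriesFormatError(f"{path}: missing required timing tag {tag}")
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise SeriesFormatError(f"{path}: multi-frame DICOM is not supported")
    return ds


def read_series(
    paths: Iterable[str | Path],
    mode: SeriesMode,
    *,
    fixed_time_tol: float = 0.01,
) -> RelaxationSeries:
    """Load DICOM files into a series sorted by the varied time parameter.

    Rescale slope/intercept are applied, the held-constant time is
    verified constant to within ``fixed_time_tol`` ms, and frames with
    duplicate varied times are averaged with a warning. The result is
    independent of the on-disk file order.
    """
    path_list = [Path(p) for p in paths]
    if not path_list:
        raise ValueError("no input files")

    frames: list[np.ndarray] = []
    varied: list[float] = []
    fixed: list[float] = []
    ids: list[str] = []
    spacing: tuple[float, float] | None = None
    shape: tuple[int, int] | None = None

    for path in path_list:
        ds = _read_one(path)
        arr = ds.pixel_array.astype(float)
        if arr.ndim != 2:
            raise SeriesFormatError(f"{path}: expected a 2-D image")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise SeriesShapeError(
                f"{path}: matrix {arr.shape} differs from first file's {shape}"
            )
        frames.append(arr)
        varied.append(float(getattr(ds, mode.varied_tag)))
        fixed.append(float(getattr(ds, mode.fixed_tag)))
        ids.append(str(getattr(ds, "SOPInstanceUID", path.name)))
        if spacing is None and getattr(ds, "PixelSpacing", None) is not None:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))

    fixed_arr = np.asarray(fixed)
    if np.ptp(fixed_arr) > fixed_time_tol:
        raise SeriesProtocolError(
            f"{mode.fixed_tag} varies across the series "
            f"(range {fixed_arr.min()}..{fixed_arr.max()} ms); "
            "a relaxometry series must hold it constant"
        )

    order = np.argsort(np.asarray(varied), kind="stable")

    # Average re-acquired duplicate times into one frame.
    uniq_times: list[float] = []
    uniq_frames: list[np.ndarray] = []
    uniq_ids: list[str] = []
    for i in order:
        t = varied[i]
        if uniq_times and t == uniq_times[-1]:
            warnings.warn(
                f"duplicate varied time {t} ms: averaging re-acquired frames",
                stacklevel=2,
            )
            k = len(uniq_ids[-1].split("+"))
            uniq_frames[-1] = (uniq_frames[-1] * k + frames[i]) / (k + 1)
            uniq_ids[-1] = uniq_ids[-1] + "+" + ids[i]
        else:
            uniq_times.append(t)
            uniq_frames.append(frames[i])
            uniq_ids.append(ids[i])

    return RelaxationSeries(
        pixels=np.stack(uniq_frames, axis=-1),
        times=np.asarray(uniq_times),
        mode=mode,
        fixed_time=float(np.mean(fixed_arr)),
        pixel_spacing=spacing,
        source_ids=uniq_ids,
    )


def _storage_scaling(pixels: np.ndarray) -> tuple[float, float]:
    """Choose RescaleSlope/Intercept for 16-bit unsigned storage.

    Integer-valued data within range are stored verbatim (slope 1) so
    small fixtures round-trip bit-exactly; otherwise the range is mapped
    onto [0, 65535] and round-trip error is bounded by half a stored unit.
    """
    vmax = float(pixels.max()) if pixels.size else 0.0
    if vmax <= 65535 and np.allclose(pixels, np.round(pixels)):
        return 1.0, 0.0
    slope = vmax / 65535.0 if vmax > 0 else 1.0
    return slope, 0.0


def write_series(series: RelaxationSeries, out_dir: str | Path) -> list[Path]:
    """Write one single-frame MR DICOM per acquisition; deterministic names.

    Returns the written paths in frame order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slope, intercept = _storage_scaling(series.pixels)
    # UIDs are derived from the destination and contents: deterministic
    # across reruns, distinct across different series.
    stamp = [str(out.resolve()), series.mode.value, repr(series.pixels.sum())]
    series_uid = generate_uid(entropy_srcs=["relaxmap-series", *stamp])
    study_uid = generate_uid(entropy_srcs=["relaxmap-study", *stamp])

    paths: list[Path] = []
    for k in range(series.n_frames):
        frame = series.pixels[:, :, k]
        stored = np.round((frame - intercept) / slope).astype(np.uint16)

        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=["relaxmap-frame", *stamp, str(k)]
        )
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.PatientName = "PHANTOM"
        ds.PatientID = "RELAXMAP"
        ds.InstanceNumber = k + 1

        varied = float(series.times[k])
        if series.mode is SeriesMode.T1_SERIES:
            ds.RepetitionTime, ds.EchoTime = varied, series.fixed_time
        else:
            ds.RepetitionTime, ds.EchoTime = series.fixed_time, varied
        if series.pixel_spacing is not None:
            ds.PixelSpacing = list(series.pixel_spacing)

        ds.Rows, ds.Columns = frame.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = stored.tobytes()

        path = out / f"{series.mode.value}_{k:03d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def export_map(
    map_image: np.ndarray,
    path: str | Path,
    fmt: str = "npz",
    *,
    nan_fill: float | None = None,
) -> Path:
    """Export a 2-D map losslessly (``npz``/``csv``) or as 16-bit PNG.

    PNG output is linearly scaled onto [0, 65535]; the scaling is recorded
    in a ``<name>.scale.txt`` sidecar so values can be recovered.
    """
    arr = np.asarray(map_image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("map must be 2-D")
    if not np.all(np.isfinite(arr)):
        if nan_fill is None:
            raise ValueError("map contains non-finite values and no nan_fill set")
        arr = np.where(np.isfinite(arr), arr, nan_fill)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npz":
        np.savez_compressed(path, map=arr)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    if fmt == "csv":
        np.savetxt(path, arr, delimiter=",", fmt="%.10g")
        return path
    if fmt == "png16":
        from PIL import Image

        vmin, vmax = float(arr.min()), float(arr.max())
        scale = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
        stored = np.round((arr - vmin) / scale).astype(np.uint16)
        Image.fromarray(stored).save(path)
        sidecar = path.with_suffix(path.suffix + ".scale.txt")
        sidecar.write_text(
            f"value = stored * {scale!r} + {vmin!r}\nunits: as in source map\n"
        )
        return path
    raise ValueError(f"unknown export format {fmt!r}")
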