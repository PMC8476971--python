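"""DICOM and region-of-interest I/O with explicit unit and orientation rules.

Conventions
-----------
* A :class:`CTVolume` stacks single-frame axial CT slices sorted so that
  index 0 is the most cranial slice (apex); in DICOM patient coordinates the
  cranial direction is +z, so slices are sorted by descending z-position.
* Raw stored values are kept as integers; HU conversion
  (``HU = raw * RescaleSlope + RescaleIntercept``) is floating point.
* Prone acquisitions (Patient Position HFP/FFP, or an explicit flag) are
  corrected by a 180-degree rotation in the axial plane, applied identically
  to image and mask.

ROI files use an open format in place of proprietary contour files: either a
JSON polygon file ``{"slices":[{"index":i,"polygons":[[[x,y],...],...]},...]}``
with vertices in (column, row) pixel coordinates, or one 8-bit 0/255 PNG mask
per slice named ``<stem>_<index:04d>.png``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from PIL import Image

log = logging.getLogger(__name__)

PRONE_POSITIONS = {"HFP", "FFP"}
SUPINE_POSITIONS = {"HFS", "FFS"}


@dataclass
class CTSlice:
    """One axial CT slice: raw stored values plus the attributes CT-qa needs."""

    raw_pixels: np.ndarray  # 2-D integer grid, as stored
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing_mm: tuple[float, float]  # (row, col)
    slice_thickness_mm: float
    z_position_mm: float
    patient_position: str = "HFS"
    prone_flag: bool = False

    def __post_init__(self) -> None:
        self.raw_pixels = np.asarray(self.raw_pixels)
        if self.raw_pixels.ndim != 2:
            raise ValueError("raw_pixels must be a 2-D grid")
        if min(self.pixel_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")


@dataclass
class CTVolume:
    """Ordered cranial-to-caudal stack of slices with shared geometry."""

    slices: list[CTSlice]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a CTVolume needs at least one slice")
        shapes = {s.raw_pixels.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"mixed slice grid shapes: {sorted(shapes)}")
        zs = [s.z_position_mm for s in self.slices]
        if len(zs) > 1:
            dz = np.diff(zs)
            if not (np.all(dz < 0) or np.all(dz > 0)):
                raise ValueError("slice z-positions must be strictly monotone")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.slices),) + self.slices[0].raw_pixels.shape

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return self.slices[0].pixel_spacing_mm

    @property
    def slice_thickness_mm(self) -> float:
        return self.slices[0].slice_thickness_mm

    def hu(self) -> np.ndarray:
        """The whole stack converted to HU, shape (n_slices, rows, cols)."""
        return np.stack([raw_to_hu(s) for s in self.slices])


def raw_to_hu(sl: CTSlice) -> np.ndarray:
    """Convert stored values to HU: raw * slope + intercept (float)."""
    return sl.raw_pixels.astype(np.float64) * sl.rescale_slope + sl.rescale_intercept


def read_dicom_series(directory_path) -> CTVolume:
    """Read every single-frame CT DICOM file in a directory into a CTVolume.

    Slices are sorted cranial to caudal (descending patient z).  Mixed grid
    shapes, missing rescale attributes, or duplicate z-positions are errors.
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        files = sorted(p for p in directory_path.iterdir() if p.is_file())
    slices = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except Exception as exc:  # non-DICOM file mixed into the directory
            raise ValueError(f"could not read {path} as DICOM: {exc}") from exc
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"missing Rescale Slope/Intercept in {path}")
        z = None
        if "ImagePositionPatient" in ds:
            z = float(ds.ImagePositionPatient[2])
        elif "SliceLocation" in ds:
            z = float(ds.SliceLocation)
        if z is None:
            raise ValueError(f"no z position (ImagePositionPatient/SliceLocation) in {path}")
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        position = str(getattr(ds, "PatientPosition", "")) or "other"
        slices.append(
            CTSlice(
                raw_pixels=ds.pixel_array,
                rescale_slope=float(ds.RescaleSlope),
                rescale_intercept=float(ds.RescaleIntercept),
                pixel_spacing_mm=spacing,
                slice_thickness_mm=float(getattr(ds, "SliceThickness", 1.0)),
                z_position_mm=z,
                patient_position=position,
                prone_flag=position in PRONE_POSITIONS,
            )
        )
    zs = [s.z_position_mm for s in slices]
    if len(set(zs)) != len(zs):
        raise ValueError(f"duplicate slice z positions in {directory_path}")
    slices.sort(key=lambda s: -s.z_position_mm)  # cranial (largest z) first
    return CTVolume(slices=slices)


def write_dicom_series(
    volume: CTVolume,
    directory_path,
    slope: float = 1.0,
    intercept: float = -1024.0,
) -> list[Path]:
    """Write a CTVolume as one explicit-VR little-endian CT file per slice.

    Stored values are ``(HU - intercept) / slope`` rounded to the nearest
    integer; with the default encoding HU must lie in [-1024, 64511] so the
    unsigned 16-bit range suffices.  Files re-read by
    :func:`read_dicom_series` reproduce HU values exactly for integer HU.
    """
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for i, sl in enumerate(volume.slices):
        hu = raw_to_hu(sl)
        raw = np.rint((hu - intercept) / slope)
        if raw.min() < 0 or raw.max() > 65535:
            raise ValueError("HU values outside the encodable range for this slope/intercept")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientPosition = sl.patient_position if sl.patient_position != "other" else "HFS"
        ds.Rows, ds.Columns = sl.raw_pixels.shape
        ds.PixelSpacing = [str(sl.pixel_spacing_mm[0]), str(sl.pixel_spacing_mm[1])]
        ds.SliceThickness = str(sl.slice_thickness_mm)
        ds.ImagePositionPatient = ["0", "0", str(sl.z_position_mm)]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SliceLocation = str(sl.z_position_mm)
        ds.InstanceNumber = i + 1
        ds.RescaleSlope = str(slope)
        ds.RescaleIntercept = str(intercept)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = raw.astype(np.uint16).tobytes()
        path = directory_path / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# ROI contours and masks
# ---------------------------------------------------------------------------


@dataclass
class ROIContour:
    """Closed polygons per slice, vertices (x=column, y=row) in pixel coords."""

    slices: dict[int, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, list[np.ndarray]] = {}
        for idx, polys in self.slices.items():
            out = []
            for p in polys:
                arr = np.asarray(p, dtype=np.float64)
                if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                    raise ValueError(f"polygon on slice {idx} must be (n>=3, 2)")
                out.append(arr)
            clean[int(idx)] = out
        self.slices = clean


def read_roi(path, n_slices: int | None = None) -> ROIContour:
    """Read a polygon-JSON ROI file; optionally validate slice indices."""
    with open(path) as fh:
        data = json.load(fh)
    slices: dict[int, list[np.ndarray]] = {}
    for entry in data["slices"]:
        idx = int(entry["index"])
        if idx < 0 or (n_slices is not None and idx >= n_slices):
            raise ValueError(f"slice index {idx} out of volume range in {path}")
        slices[idx] = [np.asarray(p, dtype=np.float64) for p in entry["polygons"]]
    return ROIContour(slices=slices)


def write_roi(contour: ROIContour, path) -> None:
    data = {
        "slices": [
            {"index": idx, "polygons": [p.tolist() for p in polys]}
            for idx, polys in sorted(contour.slices.items())
        ]
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) inclusion test; boundary counts as inside."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    boundary = np.zeros(len(points), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # edge crossing of the rightward ray (even-odd, half-open in y)
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
        # boundary: point on the closed segment
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 == 0:
            on = (x == x1) & (y == y1)
        else:
            t = ((x - x1) * dx + (y - y1) * dy) / seg2
            cross = (x - x1) * dy - (y - y1) * dx
            on = (np.abs(cross) <= 1e-9 * max(1.0, np.sqrt(seg2))) & (t >= 0) & (t <= 1)
        boundary |= on
    return inside | boundary


def rasterize_polygons(polygons: list[np.ndarray], grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize polygons on a pixel grid: a pixel is set iff its center
    (col + 0, row + 0 — integer coordinates are the centers) lies inside or
    on any polygon, even-odd rule."""
    h, w = grid_shape
    mask = np.zeros((h, w), dtype=np.uint8)
    if not polygons:
        return mask
    cols, rows = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    pts = np.column_stack([cols.ravel(), rows.ravel()])
    for poly in polygons:
        lo = np.floor(poly.min(axis=0)) - 1
        hi = np.ceil(poly.max(axis=0)) + 1
        box = (
            (pts[:, 0] >= lo[0]) & (pts[:, 0] <= hi[0]) & (pts[:, 1] >= lo[1]) & (pts[:, 1] <= hi[1])
        )
        sel = np.flatnonzero(box)
        if sel.size:
            inside = _points_in_polygon(pts[sel], poly)
            mask.ravel()[sel[inside]] = 1
    return mask


def contour_to_mask(contour: ROIContour, volume_shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize an ROIContour into a binary lung mask aligned to a volume."""
    k, h, w = volume_shape
    mask = np.zeros(volume_shape, dtype=np.uint8)
    for idx, polys in contour.slices.items():
        if idx >= k:
            raise ValueError(f"contour slice index {idx} outside volume with {k} slices")
        mask[idx] = rasterize_polygons(polys, (h, w))
    return mask


def write_mask_pngs(mask: np.ndarray, directory_path, stem: str = "mask") -> list[Path]:
    """Write a 3-D binary mask as one 0/255 8-bit PNG per slice."""
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sl in enumerate(np.asarray(mask)):
        img = Image.fromarray((sl.astype(np.uint8) * 255), mode="L")
        p = directory_path / f"{stem}_{i:04d}.png"
        img.save(p)
        paths.append(p)
    return paths


def read_mask_pngs(directory_path, stem: str = "mask") -> np.ndarray:
    """Read per-slice PNG masks back into a binary 3-D array."""
    directory_path = Path(directory_path)
    paths = sorted(directory_path.glob(f"{stem}_*.png"))
    if not paths:
        raise FileNotFoundError(f"no {stem}_*.png files in {directory_path}")
    slices = [(np.asarray(Image.open(p)) > 127).astype(np.uint8) for p in paths]
    return np.stack(slices)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def rot180(grid: np.ndarray) -> np.ndarray:
    """180-degree rotation in the axial plane (last two axes)."""
    return np.flip(np.flip(grid, axis=-1), axis=-2)


def orient_supine(
    volume: CTVolume, mask: np.ndarray | None = None
) -> tuple[CTVolume, np.ndarray | None]:
    """Bring a prone acquisition into supine orientation.

    Prone slices (HFP/FFP or prone_flag) are rotated 180 degrees in-plane,
    identically for image and mask; supine slices pass through unchanged.
    Unknown position codes pass through with a logged warning.
    """
    out_slices = []
    rotated_any = False
    for sl in volume.slices:
        prone = sl.prone_flag or sl.patient_position in PRONE_POSITIONS
        known = prone or sl.patient_position in SUPINE_POSITIONS
        if not known:
            log.warning(
                "unknown patient position %r: passing slice through unrotated",
                sl.patient_position,
            )
        if prone:
            rotated_any = True
            out_slices.append(
                replace(
                    sl,
                    raw_pixels=rot180(sl.raw_pixels).copy(),
                    prone_flag=False,
                    patient_position="HFS" if sl.patient_position.startswith("HF") else "FFS",
                )
            )
        else:
            out_slices.append(sl)
    out_mask = mask
    if mask is not None and rotated_any:
        out_mask = mask.copy()
        for i, sl in enumerate(volume.slices):
            if sl.prone_flag or sl.patient_position in PRONE_POSITIONS:
                out_mask[i] = rot180(mask[i])
    return CTVolume(slices=out_slices), out_mask
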