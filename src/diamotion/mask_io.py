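"""Readers and writers for binary diaphragm-field mask series.

A mask series is a time-ordered stack of 2-D binary rasters from sagittal
thoracic MRI, one frame per acquired image, together with the acquisition
metadata needed downstream (frame rate in frames/s, isotropic in-plane pixel
spacing in mm/pixel).  Any nonzero pixel counts as foreground.

Supported on-disk layouts:

* multi-page TIFF, one page per frame;
* a directory of zero-padded PNG frames (lexicographic order = time order);
* a 3-D NIfTI volume with axes (Y, Z, time).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ReaderError

__all__ = ["MaskSeries", "read_mask_series", "write_mask_series"]


@dataclass
class MaskSeries:
    """A stack of per-frame binary masks plus acquisition metadata.

    Attributes
    ----------
    frames : ndarray, bool, shape (M_ori, n_rows, n_cols)
        Foreground = part of the segmented diaphragm field.  Image row 0 is
        the superior edge; columns run anterior (0) to posterior.
    frame_rate : float
        Acquisition rate in frames per second.
    pixel_spacing : float
        In-plane pixel size in mm (isotropic).
    subject_id : str
        Free-form label used in output artifacts.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: float
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ReaderError(
                f"mask series must be a 3-D (time, rows, cols) stack, got ndim={frames.ndim}"
            )
        self.frames = frames.astype(bool)
        if not self.frame_rate > 0:
            raise ReaderError(f"frame_rate must be positive, got {self.frame_rate}")
        if not self.pixel_spacing > 0:
            raise ReaderError(f"pixel_spacing must be positive, got {self.pixel_spacing}")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of a single frame."""
        return self.frames.shape[1:]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.frame_count) / self.frame_rate

    def valid_frame_mask(self) -> np.ndarray:
        """Boolean mask of frames containing at least one foreground pixel."""
        return self.frames.any(axis=(1, 2))


_META_DEFAULTS = {"frame_rate": 8.33, "pixel_spacing": 1.5}


def _load_sidecar(path: Path) -> dict:
    """Read ``<stem>.json`` metadata next to a mask file if present."""
    for candidate in (path.with_suffix(".json"), path / "meta.json" if path.is_dir() else None):
        if candidate is not None and candidate.is_file():
            with open(candidate) as fh:
                return json.load(fh)
    return {}


def read_mask_series(
    path: str | Path,
    frame_rate: float | None = None,
    pixel_spacing: float | None = None,
    subject_id: str | None = None,
) -> MaskSeries:
    """Read a mask series from TIFF, a PNG directory, or NIfTI.

    Explicit ``frame_rate`` / ``pixel_spacing`` arguments override a JSON
    sidecar, which overrides the defaults (8.33 f/s, 1.5 mm/px).
    """
    path = Path(path)
    if not path.exists():
        raise ReaderError(f"no such mask series: {path}")
    meta = dict(_META_DEFAULTS)
    meta.update(_load_sidecar(path))
    if frame_rate is not None:
        meta["frame_rate"] = frame_rate
    if pixel_spacing is not None:
        meta["pixel_spacing"] = pixel_spacing

    if path.is_dir():
        frames = _read_png_dir(path)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        frames = _read_tiff(path)
    elif path.suffix.lower() == ".nii" or path.name.lower().endswith(".nii.gz"):
        frames = _read_nifti(path)
    else:
        raise ReaderError(f"unrecognized mask series format: {path}")

    return MaskSeries(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        pixel_spacing=float(meta["pixel_spacing"]),
        subject_id=subject_id or meta.get("subject_id", path.stem.replace(".nii", "")),
    )


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile

    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ReaderError(f"failed to read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr != 0


def _read_png_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise ReaderError(f"no PNG frames found in {path}")
    # guard against unpadded numbering silently reordering time
    nums = [re.findall(r"\d+", p.stem) for p in files]
    if all(n for n in nums):
        order = np.argsort([int(n[-1]) for n in nums], kind="stable")
        files = [files[i] for i in order]
    frames = []
    shape = None
    for f in files:
        try:
            img = np.asarray(iio.imread(f))
        except Exception as exc:  # pragma: no cover
            raise ReaderError(f"failed to read PNG {f}: {exc}") from exc
        if img.ndim == 3:  # collapse RGB(A)
            img = img[..., :3].max(axis=-1)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ReaderError(f"frame {f.name} shape {img.shape} differs from {shape}")
        frames.append(img != 0)
    return np.stack(frames)


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    try:
        vol = np.asanyarray(nib.load(path).dataobj)
    except Exception as exc:  # pragma: no cover
        raise ReaderError(f"failed to read NIfTI {path}: {exc}") from exc
    if vol.ndim != 3:
        raise ReaderError(f"NIfTI mask volume must be 3-D (Y, Z, time), got ndim={vol.ndim}")
    # stored (Y=cols, Z=rows, time) -> (time, rows, cols)
    return np.transpose(vol != 0, (2, 1, 0))


def write_mask_series(masks: MaskSeries, path: str | Path, fmt: str = "tiff") -> Path:
    """Write a mask series to ``path`` with a JSON metadata sidecar.

    ``fmt`` is one of ``tiff`` or ``nifti``.  Returns the main output path.
    """
    path = Path(path)
    if fmt == "tiff":
        import tifffile

        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, masks.frames.astype(np.uint8), photometric="minisblack")
        sidecar = path.with_suffix(".json")
    elif fmt == "nifti":
        import nibabel as nib

        path.parent.mkdir(parents=True, exist_ok=True)
        vol = np.transpose(masks.frames.astype(np.uint8), (2, 1, 0))
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), path)
        sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    else:
        raise ReaderError(f"unknown mask output format: {fmt}")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "subject_id": masks.subject_id,
                "frame_rate": masks.frame_rate,
                "pixel_spacing": masks.pixel_spacing,
                "frame_count": masks.frame_count,
            },
            fh,
            indent=1,
        )
    return path
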