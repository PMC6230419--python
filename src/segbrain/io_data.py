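"""Reading, writing and preparing the formats the pipeline touches.

Volumes come in as Analyze 7.5 (.hdr/.img) or NIfTI-1 (.nii/.nii.gz) via
nibabel and are kept in on-disk axis order; nothing is silently reoriented.
Label maps travel as raw class indices {0,1,2,3} in single-channel 8-bit
PNGs, intensity slices as 16-bit grayscale PNGs, so every round trip is
bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

VALID_LABELS = frozenset({0, 1, 2, 3})


@dataclass
class Volume:
    """A 3D scalar volume in the axis order stored on disk."""

    data: np.ndarray
    voxel_order: str  # documentation of the index convention
    source_format: str  # "analyze" | "nifti"


@dataclass
class SlicePair:
    """One 2D intensity slice paired with its label map."""

    image: np.ndarray
    labels: np.ndarray
    identifier: str = ""
    zero_centered: bool = False

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != label shape {self.labels.shape}"
            )
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"label values outside {{0,1,2,3}}: {sorted(bad)}")


def read_volume(path: str | Path) -> Volume:
    """Read an Analyze 7.5 pair or NIfTI-1 file as a 3D volume.

    The array is returned exactly as stored (no reorientation); the
    ``voxel_order`` field documents that the indices are the on-disk
    (i, j, k) axes of the file.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if path.suffix in {".hdr", ".img"}:
        counterpart = path.with_suffix(".img" if path.suffix == ".hdr" else ".hdr")
        if not counterpart.exists():
            raise FileNotFoundError(
                f"Analyze pair incomplete: {path} present but {counterpart} missing"
            )
        fmt = "analyze"
    elif suffixes.endswith((".nii", ".nii.gz")):
        fmt = "nifti"
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if not path.exists():
        raise FileNotFoundError(str(path))

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)  # Analyze files often carry a trailing singleton dim
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape} from {path.name}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path.name} contains non-finite values")
    return Volume(data=np.asarray(data, dtype=np.float64),
                  voxel_order="on-disk (i,j,k) axes as stored by the file",
                  source_format=fmt)


def write_volume(path: str | Path, data: np.ndarray) -> None:
    """Write a 3D array as NIfTI-1 (.nii/.nii.gz) or Analyze (.hdr/.img)."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {arr.shape}")
    if path.suffix in {".hdr", ".img"}:
        img = nib.AnalyzeImage(arr, affine=None)
    else:
        img = nib.Nifti1Image(arr, affine=np.eye(4))
    nib.save(img, str(path))


def extract_slice(vol: Volume, axis: int, index: int | None = None) -> np.ndarray:
    """Take one 2D slice from a volume along ``axis``.

    ``index=None`` selects the mid-plane.  Negative indices are rejected:
    slicing a scan must be explicit, not python-wrapped.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    size = vol.data.shape[axis]
    if index is None:
        index = size // 2
    if not (0 <= index < size):
        raise IndexError(f"slice index {index} out of range [0, {size}) on axis {axis}")
    return np.take(vol.data, index, axis=axis)


def zero_center(image: np.ndarray) -> np.ndarray:
    """Subtract the image mean (the input-layer normalization of the network)."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot zero-center an empty image")
    return image - image.mean()


@dataclass
class CropRecord:
    """Inverse of :func:`pad_to_multiple`: the slice that restores the original."""

    original_shape: tuple
    top: int
    left: int
    pad_h: int = 0
    pad_w: int = 0

    @property
    def empty(self) -> bool:
        return self.pad_h == 0 and self.pad_w == 0

    def crop(self, arr: np.ndarray) -> np.ndarray:
        h, w = self.original_shape
        return arr[self.top:self.top + h, self.left:self.left + w]


def pad_to_multiple(pair: SlicePair, factor: int = 4) -> tuple[SlicePair, CropRecord]:
    """Symmetrically pad image and labels so both dims divide ``factor``.

    Labels are padded with background (0); images with 0.0, which is the
    background fill once zero-centering has pushed background to the mean.
    """
    h, w = pair.image.shape
    ph = (-h) % factor
    pw = (-w) % factor
    top, left = ph // 2, pw // 2
    record = CropRecord(original_shape=(h, w), top=top, left=left, pad_h=ph, pad_w=pw)
    if ph == 0 and pw == 0:
        return pair, record
    pad = ((top, ph - top), (left, pw - left))
    return (
        SlicePair(
            image=np.pad(pair.image, pad, constant_values=0.0),
            labels=np.pad(pair.labels, pad, constant_values=0),
            identifier=pair.identifier,
            zero_centered=pair.zero_centered,
        ),
        record,
    )


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as a single-channel 8-bit PNG of raw class indices."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - VALID_LABELS
    if bad:
        raise ValueError(f"refusing to write label values outside {{0,1,2,3}}: {sorted(bad)}")
    Image.fromarray(labels.astype(np.uint8), mode="L").save(str(path))


def read_label_png(path: str | Path) -> np.ndarray:
    """Read a label PNG, rejecting any value outside {0,1,2,3}."""
    with Image.open(str(path)) as im:
        arr = np.asarray(im.convert("L"))
    bad = set(np.unique(arr)) - VALID_LABELS
    if bad:
        raise ValueError(f"label PNG {Path(path).name} contains invalid value(s) {sorted(bad)}")
    return arr.astype(np.uint8)


def write_image_png(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    image = np.asarray(image, dtype=np.float64)
    scaled = np.round(np.clip(image, 0.0, 1.0) * 65535.0).astype(np.uint16)
    Image.fromarray(scaled).save(str(path))  # uint16 -> 16-bit grayscale PNG


def read_image_png(path: str | Path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back to a [0, 1] float image."""
    with Image.open(str(path)) as im:
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image in {Path(path).name}")
    return arr / 65535.0
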