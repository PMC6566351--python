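"""Slice I/O, Hounsfield-unit windowing, intensity normalization and
training-time augmentation.

A "gray slice" throughout the package is a 2-D float64 array with values
in [0, 255]; 8-bit quantization (round-half-up) happens only when a file
is written.  CT volumes arriving in raw Hounsfield units are first
windowed (default: length 80 HU, center 40 HU — the brain window that
maximizes soft-tissue contrast) onto that 8-bit scale.

Augmentation follows the training recipe: horizontal flip with
probability 0.5, zero-pad then random crop back to the target size
(286 from 256, scaled proportionally for other sizes), and rotation by a
uniform angle in [-5, 5] degrees.  Members of a registered pair must be
transformed with the SAME sampled parameters to preserve registration;
unpaired slices draw parameters independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, DataError, ShapeError

__all__ = [
    "HUVolume",
    "PairedSample",
    "AugmentParams",
    "window_hu",
    "to_network_domain",
    "from_network_domain",
    "quantize_u8",
    "pad_margin",
    "sample_augment_params",
    "apply_augment",
    "read_png",
    "write_png",
    "read_nifti",
    "write_nifti",
    "load_manifest",
]

WINDOW_CENTER_DEFAULT = 40.0   # HU
WINDOW_LENGTH_DEFAULT = 80.0   # HU
ROTATION_MAX_DEG = 5.0
PAD_MARGIN_256 = 30            # 256 -> 286


@dataclass(frozen=True)
class HUVolume:
    """A raw CT volume in Hounsfield units with voxel spacing in mm."""

    voxels: np.ndarray            # (slices, H, W)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("voxel spacing components must be > 0")
        if np.asarray(self.voxels).ndim != 3:
            raise ShapeError("HUVolume expects a 3-D (slices, H, W) array")


@dataclass
class PairedSample:
    """A registered (CT, MR) gray-slice pair from one subject."""

    ct: np.ndarray
    mr: np.ndarray
    subject_id: str
    slice_index: int = 0
    masks: dict | None = None

    def __post_init__(self):
        if self.ct.shape != self.mr.shape:
            raise ShapeError("paired CT and MR slices must have identical shapes")


@dataclass(frozen=True)
class AugmentParams:
    """One draw of the stochastic augmentation transform."""

    flip: bool
    pad_to: int
    crop_offset: tuple[int, int]
    rotation_deg: float

    def validate(self, target_size: int) -> None:
        margin = self.pad_to - target_size
        r, c = self.crop_offset
        if margin < 0 or not (0 <= r <= margin and 0 <= c <= margin):
            raise ConfigurationError(
                f"crop offset {self.crop_offset} inadmissible for pad_to={self.pad_to}, "
                f"target={target_size}"
            )


# ---------------------------------------------------------------------------
# intensity transforms
# ---------------------------------------------------------------------------

def window_hu(volume: HUVolume | np.ndarray, center: float = WINDOW_CENTER_DEFAULT,
              length: float = WINDOW_LENGTH_DEFAULT) -> np.ndarray:
    """Map the HU interval [center - length/2, center + length/2] linearly
    onto [0, 255], clipping outside.  Returns float slices in [0, 255]."""
    if length <= 0:
        raise ConfigurationError(f"window length must be > 0, got {length}")
    voxels = volume.voxels if isinstance(volume, HUVolume) else np.asarray(volume, float)
    lo = center - length / 2.0
    return np.clip((voxels - lo) / length * 255.0, 0.0, 255.0)


def to_network_domain(sl: np.ndarray) -> np.ndarray:
    """Affine map [0, 255] -> [-1, 1] (0 -> -1, 255 -> +1)."""
    sl = np.asarray(sl, dtype=np.float64)
    if sl.min() < 0.0 or sl.max() > 255.0:
        raise DataError("gray slice values must lie in [0, 255]")
    return sl / 127.5 - 1.0


def from_network_domain(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_network_domain`, clipped to [0, 255]."""
    return np.clip((np.asarray(x, dtype=np.float64) + 1.0) * 127.5, 0.0, 255.0)


def quantize_u8(sl: np.ndarray) -> np.ndarray:
    """Round-half-up quantization to uint8 (file-writing convention)."""
    return np.clip(np.floor(np.asarray(sl, float) + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def pad_margin(target_size: int) -> int:
    """Pad margin scaled proportionally from the 256 -> 286 convention."""
    return int(round(target_size * PAD_MARGIN_256 / 256.0))


def sample_augment_params(target_size: int, rng: np.random.Generator) -> AugmentParams:
    """Draw flip ~ Bernoulli(0.5), a uniform admissible crop offset and a
    uniform rotation in [-5, 5] degrees."""
    margin = pad_margin(target_size)
    flip = bool(rng.random() < 0.5)
    off = (int(rng.integers(0, margin + 1)), int(rng.integers(0, margin + 1)))
    rot = float(rng.uniform(-ROTATION_MAX_DEG, ROTATION_MAX_DEG))
    return AugmentParams(flip=flip, pad_to=target_size + margin,
                         crop_offset=off, rotation_deg=rot)


def apply_augment(sl: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Deterministically apply one augmentation draw.

    Order of operations: flip -> zero-pad -> crop -> rotate (bilinear,
    zero fill).  Applying the same params to both members of a
    registered pair preserves their alignment.
    """
    sl = np.asarray(sl, dtype=np.float64)
    target = sl.shape[0]
    if sl.shape[0] != sl.shape[1]:
        raise ShapeError("augmentation expects square slices")
    params.validate(target)
    out = sl[:, ::-1] if params.flip else sl
    pad_total = params.pad_to - target
    out = np.pad(out, ((0, pad_total), (0, pad_total)))
    # symmetric placement: shift content by half the margin, then crop
    out = np.roll(out, (pad_total // 2, pad_total // 2), axis=(0, 1))
    r, c = params.crop_offset
    out = out[r:r + target, c:c + target]
    if params.rotation_deg != 0.0:
        out = ndimage.rotate(out, params.rotation_deg, reshape=False,
                             order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 255.0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_png(path: str) -> np.ndarray:
    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=np.float64)


def write_png(sl: np.ndarray, path: str) -> None:
    Image.fromarray(quantize_u8(sl), mode="L").save(path)


def read_nifti(path: str) -> np.ndarray:
    """Read a NIfTI volume as a (slices, H, W) float stack in [0, 255].

    The last axis of the on-disk array is taken as the slice axis (axial
    stacking convention used by the writer below).
    """
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ShapeError(f"expected a 3-D NIfTI volume, got {data.ndim}-D")
    return np.transpose(data, (2, 0, 1))


def write_nifti(stack: np.ndarray, path: str,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ShapeError("write_nifti expects a (slices, H, W) stack")
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.transpose(stack, (1, 2, 0)), affine), path)


def load_manifest(manifest_path: str):
    """Load a phantom-dataset manifest directory.

    Returns ``(paired, unpaired_ct, unpaired_mr)`` where ``paired`` is a
    list of :class:`PairedSample` and the pools are lists of slices.
    """
    base = os.path.dirname(os.path.abspath(manifest_path))
    rows = []
    with open(manifest_path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    if not rows:
        raise DataError(f"manifest {manifest_path} lists no slices")
    paired_ct: dict[tuple[str, int], np.ndarray] = {}
    paired_mr: dict[tuple[str, int], np.ndarray] = {}
    unpaired_ct: list[np.ndarray] = []
    unpaired_mr: list[np.ndarray] = []
    for row in rows:
        img = read_png(os.path.join(base, row["path"]))
        key = (row["subject_id"], int(row["slice_index"]))
        role = row["role"]
        if role == "paired_ct":
            paired_ct[key] = img
        elif role == "paired_mr":
            paired_mr[key] = img
        elif role == "unpaired_ct":
            unpaired_ct.append(img)
        elif role == "unpaired_mr":
            unpaired_mr.append(img)
        else:
            raise DataError(f"unknown manifest role {role!r}")
    if set(paired_ct) != set(paired_mr):
        raise DataError("manifest pairs incomplete: CT/MR keys differ")
    paired = [PairedSample(ct=paired_ct[k], mr=paired_mr[k], subject_id=k[0],
                           slice_index=k[1])
              for k in sorted(paired_ct)]
    return paired, unpaired_ct, unpaired_mr
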