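"""Synthetic two-modality head phantoms.

Real training data for CT-to-MR synthesis consists of (a) registered
CT/MR slice pairs from the same subject and (b) much larger pools of
CT-only and MR-only slices from different subjects.  This module
generates desk-scale datasets with exactly that statistical structure:

* each slice is a simple head geometry — one outer elliptical "skull"
  ring and a few random interior "soft tissue" ellipses;
* the CT rendering shows a bright skull and low-contrast interior; the
  MR rendering of the *same* geometry is produced by a fixed, known
  CT-to-MR intensity transfer function (bright interior contrast, dark
  skull), so a trained network's recovery of the mapping can be checked
  against ground truth;
* paired samples share one geometry; every unpaired slice gets a fresh,
  independently drawn geometry.

No anatomical realism is attempted: the goal is a dataset on which the
full training procedure converges in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .preprocess import PairedSample, write_png

__all__ = [
    "IntensityMap",
    "PhantomParams",
    "PhantomDataset",
    "get_intensity_map",
    "generate_phantom_pair",
    "generate_dataset",
    "write_dataset",
]

# CT intensity bands used by the renderer (8-bit gray levels)
_CT_BACKGROUND = 0.0
_CT_INTERIOR_BASE = 100.0
_CT_BLOB_DELTA = (-20.0, 40.0)   # blob contrast relative to interior base
_CT_SKULL = (220.0, 245.0)


@dataclass(frozen=True)
class IntensityMap:
    """Piecewise-linear CT→MR intensity transfer, stored by id.

    Monotone increasing over the soft-tissue band (stretching its low CT
    contrast into high MR contrast) with an inversion over the skull
    band (bright CT bone maps to dark MR bone).
    """

    map_id: str
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __call__(self, ct: np.ndarray) -> np.ndarray:
        return np.interp(ct, self.x, self.y)


_INTENSITY_MAPS = {
    "piecewise_v1": IntensityMap(
        "piecewise_v1",
        x=(0.0, 80.0, 150.0, 210.0, 255.0),
        y=(0.0, 50.0, 230.0, 60.0, 15.0),
    ),
    # identity mapping, useful for debugging the pipeline
    "identity": IntensityMap("identity", x=(0.0, 255.0), y=(0.0, 255.0)),
}


def get_intensity_map(map_id: str) -> IntensityMap:
    try:
        return _INTENSITY_MAPS[map_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown intensity_map_id {map_id!r}; known: {sorted(_INTENSITY_MAPS)}"
        ) from None


@dataclass(frozen=True)
class PhantomParams:
    """Knobs of the phantom generator.

    ``n_structures`` is the inclusive range the per-slice count of
    interior soft-tissue ellipses is drawn from.  ``misalignment_px``
    emulates residual registration error: the MR member of a pair is
    translated by a random integer offset of at most that many pixels.
    ``noise_sd`` is additive Gaussian noise in gray levels, applied to
    each rendering independently after the intensity mapping.
    """

    image_size: int = 256
    n_structures: tuple[int, int] = (2, 6)
    skull_thickness_range: tuple[float, float] = (2.0, 5.0)
    intensity_map_id: str = "piecewise_v1"
    misalignment_px: int = 0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 4 != 0:
            raise ConfigurationError(
                f"image_size must be >= 32 and divisible by 4, got {self.image_size}"
            )
        if self.misalignment_px < 0:
            raise ConfigurationError("misalignment_px must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.n_structures
        if not (1 <= lo <= hi):
            raise ConfigurationError("n_structures range must satisfy 1 <= lo <= hi")
        get_intensity_map(self.intensity_map_id)


@dataclass
class PhantomDataset:
    paired: list[PairedSample]
    unpaired_ct: list[np.ndarray]
    unpaired_mr: list[np.ndarray]
    ground_truth_map: IntensityMap
    provenance: PhantomParams
    manifest: list[dict] = field(default_factory=list)
    unpaired_ct_masks: list[dict] = field(default_factory=list)
    unpaired_mr_masks: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry rendering
# ---------------------------------------------------------------------------

def _draw_geometry(params: PhantomParams, rng: np.random.Generator):
    """Render a CT slice and its skull/interior/background masks."""
    n = params.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = n / 2 + rng.uniform(-0.03, 0.03) * n
    cx = n / 2 + rng.uniform(-0.03, 0.03) * n
    a = rng.uniform(0.36, 0.44) * n   # semi-axis along x
    b = rng.uniform(0.32, 0.40) * n   # semi-axis along y
    theta = rng.uniform(-0.4, 0.4)
    ct_, st_ = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct_ + (yy - cy) * st_
    yr = -(xx - cx) * st_ + (yy - cy) * ct_
    r2 = (xr / a) ** 2 + (yr / b) ** 2

    thickness = rng.uniform(*params.skull_thickness_range)
    # inner ellipse scaled so the ring is ~thickness pixels wide
    shrink = 1.0 - thickness / min(a, b)
    inner = (xr / (a * shrink)) ** 2 + (yr / (b * shrink)) ** 2
    skull_mask = (r2 <= 1.0) & (inner > 1.0)
    interior_mask = inner <= 1.0

    ct = np.full((n, n), _CT_BACKGROUND)
    ct[interior_mask] = _CT_INTERIOR_BASE
    n_blobs = int(rng.integers(params.n_structures[0], params.n_structures[1] + 1))
    blob_mask = np.zeros((n, n), dtype=bool)
    for _ in range(n_blobs):
        bcy = cy + rng.uniform(-0.5, 0.5) * b * shrink
        bcx = cx + rng.uniform(-0.5, 0.5) * a * shrink
        ba = rng.uniform(0.05, 0.18) * n
        bb = rng.uniform(0.05, 0.18) * n
        bth = rng.uniform(-np.pi, np.pi)
        bct, bst = np.cos(bth), np.sin(bth)
        bxr = (xx - bcx) * bct + (yy - bcy) * bst
        byr = -(xx - bcx) * bst + (yy - bcy) * bct
        m = ((bxr / ba) ** 2 + (byr / bb) ** 2 <= 1.0) & interior_mask
        delta = rng.uniform(*_CT_BLOB_DELTA)
        ct[m] = _CT_INTERIOR_BASE + delta
        blob_mask |= m
    ct[skull_mask] = rng.uniform(*_CT_SKULL)
    ct = np.clip(ct, 0.0, 255.0)
    masks = {
        "skull": skull_mask,
        "interior": interior_mask,
        "background": ~(skull_mask | interior_mask),
        "blobs": blob_mask,
    }
    return ct, masks


def _shift2d(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys, yd = (dy, 0) if dy < 0 else (0, dy)
    xs, xd = (dx, 0) if dx < 0 else (0, dx)
    hh = h - abs(dy)
    ww = w - abs(dx)
    out[yd:yd + hh, xd:xd + ww] = img[-ys if ys else 0:(-ys if ys else 0) + hh,
                                      -xs if xs else 0:(-xs if xs else 0) + ww]
    return out


def generate_phantom_pair(params: PhantomParams, rng: np.random.Generator,
                          subject_id: str = "pair-000",
                          slice_index: int = 0) -> PairedSample:
    """One registered (CT, MR) pair from a shared geometry.

    With ``noise_sd == 0`` and ``misalignment_px == 0`` the MR member is
    exactly the ground-truth intensity map applied pixelwise to the CT
    member.
    """
    gt_map = get_intensity_map(params.intensity_map_id)
    ct, masks = _draw_geometry(params, rng)
    mr = gt_map(ct)
    if params.misalignment_px > 0:
        dy = int(rng.integers(-params.misalignment_px, params.misalignment_px + 1))
        dx = int(rng.integers(-params.misalignment_px, params.misalignment_px + 1))
        mr = _shift2d(mr, dy, dx)
    if params.noise_sd > 0:
        ct = ct + rng.normal(0.0, params.noise_sd, ct.shape)
        mr = mr + rng.normal(0.0, params.noise_sd, mr.shape)
    ct = np.clip(ct, 0.0, 255.0)
    mr = np.clip(mr, 0.0, 255.0)
    return PairedSample(ct=ct, mr=mr, subject_id=subject_id,
                        slice_index=slice_index, masks=masks)


def generate_dataset(params: PhantomParams, n_paired: int, n_unpaired_ct: int,
                     n_unpaired_mr: int) -> PhantomDataset:
    """Generate a full mixed-regime dataset.

    Every unpaired slice is rendered from a freshly drawn geometry, so
    unpaired CT and MR pools are statistically independent of each other
    and of the paired set — the regime the training algorithm assumes.
    """
    for name, v in (("n_paired", n_paired), ("n_unpaired_ct", n_unpaired_ct),
                    ("n_unpaired_mr", n_unpaired_mr)):
        if v < 0:
            raise ConfigurationError(f"{name} must be >= 0, got {v}")
    if n_paired + n_unpaired_ct + n_unpaired_mr == 0:
        raise ConfigurationError("at least one of the three slice counts must be > 0")

    rng = np.random.default_rng(params.seed)
    gt_map = get_intensity_map(params.intensity_map_id)
    manifest: list[dict] = []

    paired = []
    for i in range(n_paired):
        sid = f"pair-{i:03d}"
        paired.append(generate_phantom_pair(params, rng, subject_id=sid, slice_index=i))
        manifest.append({"role": "paired", "subject_id": sid, "slice_index": i})

    unpaired_ct, ct_masks = [], []
    for i in range(n_unpaired_ct):
        ct, masks = _draw_geometry(params, rng)
        if params.noise_sd > 0:
            ct = ct + rng.normal(0.0, params.noise_sd, ct.shape)
        unpaired_ct.append(np.clip(ct, 0.0, 255.0))
        ct_masks.append(masks)
        manifest.append({"role": "unpaired_ct", "subject_id": f"ct-{i:03d}",
                         "slice_index": i})

    unpaired_mr, mr_masks = [], []
    for i in range(n_unpaired_mr):
        ct, masks = _draw_geometry(params, rng)
        mr = gt_map(ct)
        if params.noise_sd > 0:
            mr = mr + rng.normal(0.0, params.noise_sd, mr.shape)
        unpaired_mr.append(np.clip(mr, 0.0, 255.0))
        mr_masks.append(masks)
        manifest.append({"role": "unpaired_mr", "subject_id": f"mr-{i:03d}",
                         "slice_index": i})

    return PhantomDataset(
        paired=paired,
        unpaired_ct=unpaired_ct,
        unpaired_mr=unpaired_mr,
        ground_truth_map=gt_map,
        provenance=params,
        manifest=manifest,
        unpaired_ct_masks=ct_masks,
        unpaired_mr_masks=mr_masks,
    )


def write_dataset(dataset: PhantomDataset, out_dir: str) -> str:
    """Write a dataset as 8-bit PNG slices plus a TSV manifest.

    Returns the manifest path.  Layout::

        out_dir/
          manifest.tsv        role <TAB> subject_id <TAB> slice_index <TAB> path
          paired_ct/…png  paired_mr/…png  unpaired_ct/…png  unpaired_mr/…png
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in dataset.paired:
        for modality, img in (("paired_ct", s.ct), ("paired_mr", s.mr)):
            sub = os.path.join(out_dir, modality)
            os.makedirs(sub, exist_ok=True)
            path = os.path.join(sub, f"{s.subject_id}_{s.slice_index:04d}.png")
            write_png(img, path)
            rows.append((modality, s.subject_id, s.slice_index,
                         os.path.relpath(path, out_dir)))
    for modality, pool in (("unpaired_ct", dataset.unpaired_ct),
                           ("unpaired_mr", dataset.unpaired_mr)):
        sub = os.path.join(out_dir, modality)
        if pool:
            os.makedirs(sub, exist_ok=True)
        prefix = "ct" if modality == "unpaired_ct" else "mr"
        for i, img in enumerate(pool):
            path = os.path.join(sub, f"{prefix}-{i:03d}_{i:04d}.png")
            write_png(img, path)
            rows.append((modality, f"{prefix}-{i:03d}", i,
                         os.path.relpath(path, out_dir)))
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("role\tsubject_id\tslice_index\tpath\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    params_path = os.path.join(out_dir, "params.json")
    import json
    with open(params_path, "w") as fh:
        json.dump(dataclasses.asdict(dataset.provenance), fh, indent=2)
    return manifest_path
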