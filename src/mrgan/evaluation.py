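"""Image-quality metrics between reference and synthesized MR stacks.

Three complementary metrics on the 8-bit scale:

* MAE — mean over slices of the per-slice mean absolute pixel
  difference;
* PSNR — 10·log10(MAX² / MSE) with MAX = 255 and MSE the mean over
  slices of the per-slice mean squared difference; identical stacks
  yield an +inf sentinel that report averages exclude;
* SSIM — per-slice structural similarity computed from GLOBAL
  (whole-slice, population) means, variances and covariance, averaged
  over slices.  This is deliberately not the sliding-window SSIM; a
  windowed variant is available behind an explicit flag for comparison
  only.

Reports are per-patient tables with a final column-average row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ShapeError

__all__ = [
    "MetricConfig",
    "MetricReport",
    "mae",
    "psnr",
    "ssim",
    "build_report",
]


@dataclass(frozen=True)
class MetricConfig:
    max_intensity: float = 255.0
    c1: float | None = None        # default (0.01·MAX)²
    c2: float | None = None        # default (0.03·MAX)²
    mae_per_pixel: bool = True
    foreground_mask: bool = False  # reserved; metrics default to full slices

    def __post_init__(self):
        if self.max_intensity <= 0:
            raise ConfigurationError("max_intensity must be > 0")
        if (self.c1 is not None and self.c1 <= 0) or \
                (self.c2 is not None and self.c2 <= 0):
            raise ConfigurationError("C1 and C2 must be > 0")

    @property
    def C1(self) -> float:
        return self.c1 if self.c1 is not None else (0.01 * self.max_intensity) ** 2

    @property
    def C2(self) -> float:
        return self.c2 if self.c2 is not None else (0.03 * self.max_intensity) ** 2


def _stacks(reference, synthesized) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=np.float64)
    syn = np.asarray(synthesized, dtype=np.float64)
    if ref.ndim == 2:
        ref, syn = ref[None], syn[None]
    if ref.shape != syn.shape:
        raise ShapeError(f"stack shape mismatch: {ref.shape} vs {syn.shape}")
    if ref.ndim != 3 or ref.shape[0] < 1:
        raise ShapeError("expected non-empty (N, H, W) stacks")
    return ref, syn


def mae(reference, synthesized, cfg: MetricConfig | None = None) -> float:
    """Mean absolute error averaged over slices (per pixel by default)."""
    cfg = cfg or MetricConfig()
    ref, syn = _stacks(reference, synthesized)
    per_slice = np.abs(ref - syn).sum(axis=(1, 2))
    if cfg.mae_per_pixel:
        per_slice = per_slice / (ref.shape[1] * ref.shape[2])
    return float(per_slice.mean())


def psnr(reference, synthesized, cfg: MetricConfig | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical stacks."""
    cfg = cfg or MetricConfig()
    ref, syn = _stacks(reference, synthesized)
    mse = float(np.square(ref - syn).mean(axis=(1, 2)).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(cfg.max_intensity ** 2 / mse))


def _ssim_slice(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()              # population variance
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx * mx + my * my + c1) * (vx + vy + c2)))


def ssim(reference, synthesized, cfg: MetricConfig | None = None,
         windowed: bool = False, window_size: int = 7) -> float:
    """Structural similarity averaged over slices.

    The default uses whole-slice statistics.  ``windowed=True`` computes
    a local sliding-window SSIM instead (comparison use only — it is a
    different quantity from the default).
    """
    cfg = cfg or MetricConfig()
    ref, syn = _stacks(reference, synthesized)
    if windowed:
        from skimage.metrics import structural_similarity

        vals = [structural_similarity(
                    r, s, data_range=cfg.max_intensity, win_size=window_size,
                    gaussian_weights=False)
                for r, s in zip(ref, syn)]
        return float(np.mean(vals))
    vals = [_ssim_slice(s, r, cfg.C1, cfg.C2) for r, s in zip(ref, syn)]
    return float(np.mean(vals))


@dataclass
class MetricReport:
    table: pd.DataFrame   # one row per patient plus an "Average" row

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def build_report(per_patient: dict[str, tuple[np.ndarray, np.ndarray]],
                 cfg: MetricConfig | None = None) -> MetricReport:
    """Per-patient MAE/PSNR/SSIM table with column averages.

    ``per_patient`` maps patient id to a (reference, synthesized) stack
    pair.  Non-finite PSNR values (identical stacks) are excluded from
    the PSNR column average.
    """
    cfg = cfg or MetricConfig()
    if not per_patient:
        raise DataError("report requires at least one patient")
    rows = []
    for pid, (ref, syn) in per_patient.items():
        rows.append({"patient": pid,
                     "MAE": mae(ref, syn, cfg),
                     "PSNR": psnr(ref, syn, cfg),
                     "SSIM": ssim(ref, syn, cfg)})
    df = pd.DataFrame(rows)
    psnr_vals = df["PSNR"][np.isfinite(df["PSNR"])]
    avg = {"patient": "Average",
           "MAE": df["MAE"].mean(),
           "PSNR": psnr_vals.mean() if len(psnr_vals) else float("inf"),
           "SSIM": df["SSIM"].mean()}
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return MetricReport(table=df)
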