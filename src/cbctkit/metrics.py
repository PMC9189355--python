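"""Evaluation metrics: NMI, NCC, DSC, MAE, RMSE, PSNR, SSIM and the organ
volume-difference statistic used to stratify cases by anatomical mismatch.

All image metrics accept plain 3D arrays or :class:`~cbctkit.core_io.ImageVolume`
objects. NMI is computed from a joint histogram over a fixed shared HU range so
values are comparable across cases; entropies use the natural logarithm (NMI is
a ratio of entropies, so the base cancels).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_io import ImageVolume


def _arr(x) -> np.ndarray:
    if isinstance(x, ImageVolume):
        return x.voxels
    return np.asarray(x)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclasses.dataclass
class MetricsConfig:
    """Knobs for the histogram/window based metrics.

    nmi_bins / nmi_range
        Joint-histogram resolution and the shared HU range used for binning.
    ssim_window
        Side length (voxels) of the square in-plane SSIM window.
    ssim_k1, ssim_k2
        Constants defining c1=(k1·L)² and c2=(k2·L)² with L the dynamic range
        of the reference image.
    """

    nmi_bins: int = 64
    nmi_range: tuple[float, float] = (-1000.0, 1500.0)
    ssim_window: int = 11
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03

    def __post_init__(self) -> None:
        if self.nmi_bins < 2:
            raise ValueError("nmi_bins must be >= 2")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.ssim_k1 <= 0 or self.ssim_k2 <= 0:
            raise ValueError("SSIM constants must be positive")


def dsc(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 when both empty."""
    a = _arr(a).astype(bool)
    b = _arr(b).astype(bool)
    _check_same_shape(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (na + nb)


def nmi(i1, i2, cfg: MetricsConfig | None = None) -> float:
    """Normalized mutual information 2·MI(I1,I2)/(H(I1)+H(I2))."""
    cfg = cfg or MetricsConfig()
    a, b = _arr(i1).ravel(), _arr(i2).ravel()
    _check_same_shape(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("NMI undefined for a constant image (zero entropy)")
    lo, hi = cfg.nmi_range
    joint, _, _ = np.histogram2d(
        np.clip(a, lo, hi), np.clip(b, lo, hi), bins=cfg.nmi_bins, range=[[lo, hi], [lo, hi]]
    )
    p = joint / joint.sum()
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(p1, p2)
    mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
    h1 = float(-np.sum(p1[p1 > 0] * np.log(p1[p1 > 0])))
    h2 = float(-np.sum(p2[p2 > 0] * np.log(p2[p2 > 0])))
    if h1 + h2 == 0:
        raise ValueError("degenerate entropies")
    return 2.0 * mi / (h1 + h2)


def ncc(i1, i2) -> float:
    """Normalized cross-correlation with population standard deviations."""
    a = _arr(i1).astype(np.float64).ravel()
    b = _arr(i2).astype(np.float64).ravel()
    _check_same_shape(a, b)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("NCC undefined for a constant image (zero variance)")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def error_metrics(i1, i2) -> tuple[float, float, float]:
    """(MAE, RMSE, PSNR); ``i1`` is the reference defining MAX for PSNR."""
    a = _arr(i1).astype(np.float64)
    b = _arr(i2).astype(np.float64)
    _check_same_shape(a, b)
    diff = a - b
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if rmse == 0:
        return mae, rmse, float("inf")
    mx = float(np.max(a))
    psnr = 10.0 * np.log10(mx**2 / rmse**2)
    return mae, rmse, float(psnr)


def mae(i1, i2) -> float:
    return error_metrics(i1, i2)[0]


def _ssim_window_means(x: np.ndarray, w: int) -> np.ndarray:
    # mean over all w×w in-plane windows for every slice: (nz, ny-w+1, nx-w+1)
    v = sliding_window_view(x, (w, w), axis=(1, 2))
    return v.mean(axis=(-2, -1))


def ssim(i1, i2, cfg: MetricsConfig | None = None) -> float:
    """Mean local structural similarity over sliding in-plane windows.

    Windows are 2D (per slice) because the slice spacing is several times the
    in-plane spacing; the local statistics follow the standard luminance ×
    contrast/structure product with c1=(k1·L)², c2=(k2·L)².
    """
    cfg = cfg or MetricsConfig()
    a = _arr(i1).astype(np.float64)
    b = _arr(i2).astype(np.float64)
    _check_same_shape(a, b)
    w = cfg.ssim_window
    if a.shape[1] < w or a.shape[2] < w:
        raise ValueError(f"ssim window {w} larger than in-plane shape {a.shape[1:]}")
    L = float(np.ptp(a))
    if L == 0:
        L = 1.0  # constant reference: c1/c2 scale is arbitrary, terms reduce to ratios
    c1 = (cfg.ssim_k1 * L) ** 2
    c2 = (cfg.ssim_k2 * L) ** 2
    mu1 = _ssim_window_means(a, w)
    mu2 = _ssim_window_means(b, w)
    mu11 = _ssim_window_means(a * a, w)
    mu22 = _ssim_window_means(b * b, w)
    mu12 = _ssim_window_means(a * b, w)
    var1 = mu11 - mu1**2
    var2 = mu22 - mu2**2
    cov = mu12 - mu1 * mu2
    s = ((2 * mu1 * mu2 + c1) * (2 * cov + c2)) / ((mu1**2 + mu2**2 + c1) * (var1 + var2 + c2))
    return float(s.mean())


def ssim_global(i1, i2, cfg: MetricsConfig | None = None) -> float:
    """Single-window SSIM computed from global image statistics."""
    cfg = cfg or MetricsConfig()
    a = _arr(i1).astype(np.float64).ravel()
    b = _arr(i2).astype(np.float64).ravel()
    _check_same_shape(a, b)
    L = float(np.ptp(a)) or 1.0
    c1 = (cfg.ssim_k1 * L) ** 2
    c2 = (cfg.ssim_k2 * L) ** 2
    mu1, mu2 = a.mean(), b.mean()
    var1, var2 = a.var(), b.var()
    cov = np.mean((a - mu1) * (b - mu2))
    return float(
        ((2 * mu1 * mu2 + c1) * (2 * cov + c2)) / ((mu1**2 + mu2**2 + c1) * (var1 + var2 + c2))
    )


def volume_diff(v_a: float, v_b: float) -> float:
    """Volume-difference statistic |Va − Vb| / min(Va, Vb) × 100 (percent).

    Used to stratify cases by organ volume mismatch between the planning CT
    and the CBCT; volumes are in mm³ (or any common unit).
    """
    if v_a <= 0 or v_b <= 0:
        raise ValueError("volumes must be positive")
    return float(abs(v_a - v_b) / min(v_a, v_b) * 100.0)


def mask_volume_mm3(mask: np.ndarray, spacing) -> float:
    """Physical volume of a boolean mask given voxel spacing (sz, sy, sx)."""
    return float(np.sum(mask)) * float(np.prod(spacing))
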