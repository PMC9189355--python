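"""Independent brute-force oracle implementations used only by the tests.

Every function here is written as explicit scalar loops over voxels/bins so
it shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def dsc_loops(a, b) -> float:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    inter = na = nb = 0
    for x, y in zip(a.ravel(), b.ravel()):
        na += bool(x)
        nb += bool(y)
        inter += bool(x) and bool(y)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def ncc_loops(i1, i2) -> float:
    a = np.asarray(i1, dtype=np.float64).ravel()
    b = np.asarray(i2, dtype=np.float64).ravel()
    n = len(a)
    mu1 = sum(a) / n
    mu2 = sum(b) / n
    s1 = math.sqrt(sum((x - mu1) ** 2 for x in a) / n)
    s2 = math.sqrt(sum((x - mu2) ** 2 for x in b) / n)
    acc = 0.0
    for x, y in zip(a, b):
        acc += (x - mu1) * (y - mu2)
    return acc / n / (s1 * s2)


def nmi_loops(i1, i2, bins: int, lo: float, hi: float) -> float:
    a = np.asarray(i1, dtype=np.float64).ravel()
    b = np.asarray(i2, dtype=np.float64).ravel()
    joint = np.zeros((bins, bins))
    width = (hi - lo) / bins
    for x, y in zip(a, b):
        ix = min(int((min(max(x, lo), hi) - lo) / width), bins - 1)
        iy = min(int((min(max(y, lo), hi) - lo) / width), bins - 1)
        joint[ix, iy] += 1
    joint /= joint.sum()
    p1 = joint.sum(axis=1)
    p2 = joint.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log(joint[i, j] / (p1[i] * p2[j]))
    h1 = -sum(p * math.log(p) for p in p1 if p > 0)
    h2 = -sum(p * math.log(p) for p in p2 if p > 0)
    return 2.0 * mi / (h1 + h2)


def error_metrics_loops(i1, i2):
    a = np.asarray(i1, dtype=np.float64).ravel()
    b = np.asarray(i2, dtype=np.float64).ravel()
    n = len(a)
    mae = sum(abs(x - y) for x, y in zip(a, b)) / n
    rmse = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / n)
    if rmse == 0:
        return mae, rmse, float("inf")
    mx = max(a)
    return mae, rmse, 10.0 * math.log10(mx**2 / rmse**2)


def ssim_loops(i1, i2, window: int, k1: float, k2: float) -> float:
    """Windowed SSIM with explicit per-window statistics (2D windows/slice)."""
    a = np.asarray(i1, dtype=np.float64)
    b = np.asarray(i2, dtype=np.float64)
    L = a.max() - a.min()
    if L == 0:
        L = 1.0
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    nz, ny, nx = a.shape
    vals = []
    for z in range(nz):
        for y0 in range(ny - window + 1):
            for x0 in range(nx - window + 1):
                wa = a[z, y0 : y0 + window, x0 : x0 + window].ravel()
                wb = b[z, y0 : y0 + window, x0 : x0 + window].ravel()
                mu1, mu2 = wa.mean(), wb.mean()
                v1 = ((wa - mu1) ** 2).mean()
                v2 = ((wb - mu2) ** 2).mean()
                cov = ((wa - mu1) * (wb - mu2)).mean()
                vals.append(
                    ((2 * mu1 * mu2 + c1) * (2 * cov + c2))
                    / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
                )
    return float(np.mean(vals))


def smoothness_loops(field) -> float:
    """Mean squared forward-difference gradients, trailing edge zero."""
    f = np.asarray(field, dtype=np.float64)
    nz, ny, nx, _ = f.shape
    total = 0.0
    count = 0
    for d in range(3):
        for ax in range(3):
            for z in range(nz):
                for y in range(ny):
                    for x in range(nx):
                        idx = [z, y, x]
                        nxt = list(idx)
                        nxt[ax] += 1
                        if nxt[ax] < f.shape[ax]:
                            diff = f[nxt[0], nxt[1], nxt[2], d] - f[z, y, x, d]
                        else:
                            diff = 0.0
                        total += diff * diff
                        count += 1
    return total / count


def shift_warp_loops(vol, shift, fill=-1000.0):
    """Integer-shift warp oracle: out[x] = in[x + shift] with constant fill."""
    v = np.asarray(vol)
    out = np.full_like(v, fill)
    nz, ny, nx = v.shape
    dz, dy, dx = shift
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                sz, sy, sx = z + dz, y + dy, x + dx
                if 0 <= sz < nz and 0 <= sy < ny and 0 <= sx < nx:
                    out[z, y, x] = v[sz, sy, sx]
    return out
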