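"""Independent brute-force oracles the tests check the pipeline against.

Everything here is deliberately naive (loops, O(N^2) transforms, flood fill)
and shares no code with the package paths it validates.
"""
from __future__ import annotations

import numpy as np


def dft_amplitudes(series: np.ndarray) -> np.ndarray:
    """One-sided amplitudes from an O(N^2) direct DFT."""
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    k_max = n // 2
    amps = np.empty(k_max + 1)
    t = np.arange(n)
    for k in range(k_max + 1):
        re = np.sum(x * np.cos(2 * np.pi * k * t / n))
        im = -np.sum(x * np.sin(2 * np.pi * k * t / n))
        mag = np.sqrt(re**2 + im**2) / n
        coef = 1.0 if k == 0 or (n % 2 == 0 and k == k_max) else 2.0
        amps[k] = coef * mag
    return amps


def full_dft_power(series: np.ndarray) -> float:
    """(1/N) * sum_k |DFT_k|^2 over the full (two-sided) DFT, O(N^2)."""
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    t = np.arange(n)
    total = 0.0
    for k in range(n):
        re = np.sum(x * np.cos(2 * np.pi * k * t / n))
        im = -np.sum(x * np.sin(2 * np.pi * k * t / n))
        total += re**2 + im**2
    return total / n


def band_amplitude(series: np.ndarray, tr: float, f_lo: float, f_hi: float) -> float:
    """Mean one-sided amplitude over bins with f_lo <= k/(N*TR) <= f_hi."""
    amps = dft_amplitudes(series)
    n = len(series)
    vals = [
        amps[k]
        for k in range(len(amps))
        if f_lo - 1e-12 <= k / (n * tr) <= f_hi + 1e-12
    ]
    return float(np.mean(vals))


def detrend(series: np.ndarray) -> np.ndarray:
    """Least-squares line removal via explicit normal equations."""
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    t = np.arange(n, dtype=np.float64)
    A = np.column_stack([np.ones(n), t])
    coef = np.linalg.solve(A.T @ A, A.T @ x)
    return x - A @ coef


def project_out(series: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residual of series against design columns via pseudoinverse."""
    beta = np.linalg.pinv(design) @ series
    return series - design @ beta


def benjamini_hochberg(p: np.ndarray, q: float) -> np.ndarray:
    """Step-up BH by the book: largest r with p_(r) <= r*q/m, reject p <= p_(r)."""
    p = np.asarray(p, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = None
    for r in range(m, 0, -1):
        if sorted_p[r - 1] <= r * q / m:
            thresh = sorted_p[r - 1]
            break
    if thresh is None:
        return np.zeros(m, dtype=bool)
    return p <= thresh


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by explicit flood fill under 6/18/26 connectivity."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    todo = {tuple(v) for v in np.argwhere(mask)}
    components = []
    while todo:
        stack = [todo.pop()]
        comp = set(stack)
        while stack:
            cx, cy, cz = stack.pop()
            for dx, dy, dz in offsets:
                nb = (cx + dx, cy + dy, cz + dz)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(comp)
    return components


def nearest_neighbor(volume: np.ndarray, target_shape) -> np.ndarray:
    """Voxel-centre NN resample, one output voxel at a time."""
    out = np.empty(target_shape, dtype=volume.dtype)
    for i in range(target_shape[0]):
        for j in range(target_shape[1]):
            for k in range(target_shape[2]):
                src = []
                for t_idx, nt, ns in ((i, target_shape[0], volume.shape[0]),
                                      (j, target_shape[1], volume.shape[1]),
                                      (k, target_shape[2], volume.shape[2])):
                    s = int(round((t_idx + 0.5) * ns / nt - 0.5))
                    src.append(min(max(s, 0), ns - 1))
                out[i, j, k] = volume[tuple(src)]
    return out


def gaussian_convolve(volume: np.ndarray, sigma) -> np.ndarray:
    """Direct zero-padded discrete Gaussian convolution (truncate 4 sigma)."""
    out = np.array(volume, dtype=np.float64)
    for axis, s in enumerate(sigma):
        radius = int(np.ceil(4 * s))
        x = np.arange(-radius, radius + 1)
        kern = np.exp(-(x**2) / (2 * s**2))
        kern /= kern.sum()
        moved = np.moveaxis(out, axis, -1)
        padded = np.concatenate(
            [np.zeros(moved.shape[:-1] + (radius,)), moved,
             np.zeros(moved.shape[:-1] + (radius,))], axis=-1
        )
        conv = np.empty_like(moved)
        for idx in range(moved.shape[-1]):
            conv[..., idx] = np.sum(padded[..., idx:idx + 2 * radius + 1] * kern, axis=-1)
        out = np.moveaxis(conv, -1, axis)
    return out
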