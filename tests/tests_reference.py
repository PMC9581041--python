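"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (explicit loops, no vectorized shortcuts) so they stay
independent of the library code paths they check.
"""

import numpy as np

from densestorm.density_estimation import anisotropic_kernel, local_covariance


def brute_force_gaussian(values, sigma, truncate=6.0):
    """Per-pixel double-loop isotropic Gaussian scatter (zero padding)."""
    h, w = values.shape
    r = int(truncate * sigma + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    out = np.zeros_like(values)
    for i in range(h):
        for j in range(w):
            if values[i, j] == 0:
                continue
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        out[ii, jj] += values[i, j] * kernel[di + r, dj + r]
    return out


def brute_force_anisotropic(values, window):
    """Per-pixel scatter through individually evaluated adaptive kernels."""
    h, w = values.shape
    half = window.half
    out = np.zeros_like(values)
    for i in range(h):
        for j in range(w):
            if values[i, j] == 0:
                continue
            cov = local_covariance(values, window, (i, j))
            kernel = anisotropic_kernel(cov, window)
            for di in range(window.size):
                for dj in range(window.size):
                    ii, jj = i + di - half, j + dj - half
                    if 0 <= ii < h and 0 <= jj < w:
                        out[ii, jj] += values[i, j] * kernel[di, dj]
    return out
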