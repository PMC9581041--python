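"""Fourier Ring Correlation (FRC) curves, cut-off resolution, and area statistic.

FRC compares two images of the same structure in frequency space: the
centered 2-D Fourier transforms are cross-correlated ring by ring,

    FRC(r) = Re[ sum_{(u,v) in ring r} F_x(u,v) conj(F_y(u,v)) ]
             / sqrt( sum |F_x|^2 * sum |F_y|^2 ),

where ring ``r`` collects the spectrum samples at rounded integer radius
``r`` from the DC bin. Frequencies are reported as ``f = r / N`` cycles per
pixel (Nyquist = 0.5). For split-half renderings of a localization dataset
the first frequency at which the curve drops below 1/7 is the conventional
resolution estimate. The mean of the curve up to a frequency bound
("area-FRC") is a similarity statistic between a sparse or reconstructed
image and a dense reference; identical images give 1, unrelated noise gives
~0.

The DC term is excluded from every ring (it encodes total intensity only),
and samples beyond the Nyquist ring ``N // 2`` are discarded.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np

__all__ = [
    "FRCCurve",
    "ring_masks",
    "ring_labels",
    "frc_curve",
    "cutoff_frequency",
    "area_frc",
]

DEFAULT_THRESHOLD = 1.0 / 7.0


@dataclasses.dataclass(frozen=True)
class FRCCurve:
    """Per-ring correlation values indexed by spatial frequency.

    ``frequencies[i] = r_i / N`` with ``r_i`` the 1-based ring radius;
    ``ring_counts[i]`` is the number of Fourier samples in ring ``r_i``.
    ``values`` may contain NaN where a ring has zero energy in either image.
    """

    frequencies: np.ndarray
    values: np.ndarray
    ring_counts: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        n = np.asarray(self.ring_counts, dtype=int)
        if not (f.shape == v.shape == n.shape) or f.ndim != 1:
            raise ValueError("curve arrays must be 1-D and equally long")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ring_counts", n)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def nyquist(self) -> float:
        return 0.5


@lru_cache(maxsize=32)
def ring_labels(image_size: int) -> np.ndarray:
    """(N, N) integer map of rounded ring radii on the centered spectrum.

    Label 0 marks the DC bin, labels 1..N//2 the retained rings; samples
    beyond Nyquist (corners) are labelled -1.
    """
    if image_size < 4:
        raise ValueError("image size must be >= 4")
    n = image_size
    center = n // 2  # DC bin position after fftshift
    idx = np.arange(n) - center
    u, v = np.meshgrid(idx, idx, indexing="ij")
    radius = np.rint(np.sqrt(u.astype(float) ** 2 + v**2)).astype(int)
    radius[radius > n // 2] = -1
    return radius


def ring_masks(image_size: int) -> list[np.ndarray]:
    """Boolean masks of the centered spectrum for rings r = 1 .. N//2."""
    labels = ring_labels(image_size)
    return [labels == r for r in range(1, image_size // 2 + 1)]


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(getattr(a, "values", getattr(a, "counts", a)), dtype=float)
    b = np.asarray(getattr(b, "values", getattr(b, "counts", b)), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("FRC requires square 2-D images")
    return a, b


def frc_curve(img_x, img_y) -> FRCCurve:
    """Fourier Ring Correlation curve of an image pair.

    Accepts plain arrays, ``HistogramImage`` or ``DensityImage``. Rings with
    zero energy in either spectrum yield NaN values.
    """
    a, b = _check_pair(img_x, img_y)
    n = a.shape[0]
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))

    labels = ring_labels(n)
    n_rings = n // 2
    flat = labels.ravel()
    keep = flat >= 1
    lab = flat[keep] - 1  # 0-based ring index

    cross = np.bincount(lab, weights=(fa * np.conj(fb)).real.ravel()[keep], minlength=n_rings)
    pow_a = np.bincount(lab, weights=(np.abs(fa) ** 2).ravel()[keep], minlength=n_rings)
    pow_b = np.bincount(lab, weights=(np.abs(fb) ** 2).ravel()[keep], minlength=n_rings)
    counts = np.bincount(lab, minlength=n_rings)

    denom = np.sqrt(pow_a * pow_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, cross / denom, np.nan)

    radii = np.arange(1, n_rings + 1)
    return FRCCurve(frequencies=radii / n, values=values, ring_counts=counts)


def cutoff_frequency(
    curve: FRCCurve,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    pixel_size: float | None = None,
    smooth_window: int = 1,
) -> dict:
    """First frequency at which the FRC drops below ``threshold``.

    Returns a dict with ``frequency`` (cycles/pixel), ``crossed`` (False if
    the curve never drops below the threshold, in which case the Nyquist
    frequency is reported), and, when ``pixel_size`` (nm) is given,
    ``resolution_nm = pixel_size / frequency``. ``smooth_window`` > 1
    applies a centered moving average before thresholding.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    values = curve.values
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        values = np.convolve(np.nan_to_num(values), kernel, mode="same")
    below = np.nonzero(values < threshold)[0]
    if below.size:
        frequency = float(curve.frequencies[below[0]])
        crossed = True
    else:
        frequency = curve.nyquist
        crossed = False
    out = {"frequency": frequency, "crossed": crossed}
    if pixel_size is not None:
        out["resolution_nm"] = pixel_size / frequency
    return out


def area_frc(curve: FRCCurve, f_limit: float = 0.2) -> float:
    """Mean FRC value over rings with frequency <= ``f_limit`` * Nyquist.

    Normalized by the number of included rings so identical images give 1
    for any ``f_limit`` and image size; the corresponding training loss is
    ``1 - area_frc``. NaN rings (zero energy) are excluded from the mean.
    """
    if not 0 < f_limit <= 1:
        raise ValueError("f_limit must be in (0, 1]")
    include = curve.frequencies <= f_limit * curve.nyquist + 1e-12
    values = curve.values[include]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no rings below the frequency limit")
    return float(values.mean())
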