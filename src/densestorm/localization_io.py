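"""Localization tables, histogram rendering, and sparse/dense splits.

The native data product of SMLM is a *localization table*: one row per
fitted emitter blink with sub-pixel coordinates, the acquisition frame it
appeared in, and optionally photon count and localization precision.
Coordinates are kept in nanometres throughout the package; files written by
camera-pixel-based fitters are converted on read using the camera pixel size
(108 nm by default, a typical 100x EMCCD configuration).

Conventions
-----------
- Images are indexed ``[row, col]`` = ``[y, x]``; the origin is the low
  corner of the rendered extent, x runs rightward (columns), y downward
  (rows).
- Pixel bins are half-open ``[lo, hi)``: a localization exactly on an
  interior bin boundary belongs to the higher-index pixel.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LocalizationTable",
    "HistogramImage",
    "read_localizations",
    "write_localizations",
    "render_histogram",
    "remove_isolated",
    "split_by_frame_window",
    "split_half",
    "write_histogram_tiff",
    "write_density_tiff",
]

DEFAULT_CAMERA_PIXEL_NM = 108.0

#: accepted aliases for the required/optional columns (lower-cased)
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "x": ("x", "x [nm]", "x_nm", "xnm", "position_x"),
    "y": ("y", "y [nm]", "y_nm", "ynm", "position_y"),
    "frame": ("frame", "frames", "t"),
    "photons": ("photons", "intensity", "photon_count"),
    "precision": ("precision", "lpx", "uncertainty", "uncertainty [nm]", "sigma"),
}


class FormatError(ValueError):
    """A localization file does not conform to the expected table layout."""


@dataclasses.dataclass(frozen=True)
class LocalizationTable:
    """Immutable table of localizations with coordinates in nanometres.

    Row order carries no meaning; all operations on tables are
    permutation-invariant.
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    photons: np.ndarray | None = None
    precision: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        frame = np.asarray(self.frame)
        if not (x.shape == y.shape == frame.shape) or x.ndim != 1:
            raise ValueError("x, y, frame must be 1-D arrays of equal length")
        if x.size and not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("coordinates must be finite")
        if frame.size:
            if np.any(frame != np.floor(frame)) or np.any(frame < 0):
                raise ValueError("frame indices must be nonnegative integers")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "frame", frame.astype(np.int64))
        for name in ("photons", "precision"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != x.shape:
                    raise ValueError(f"{name} must match coordinate length")
                object.__setattr__(self, name, v)

    def __len__(self) -> int:
        return self.x.size

    def select(self, mask: np.ndarray) -> "LocalizationTable":
        """Return the sub-table of rows where ``mask`` is true."""
        return LocalizationTable(
            x=self.x[mask],
            y=self.y[mask],
            frame=self.frame[mask],
            photons=None if self.photons is None else self.photons[mask],
            precision=None if self.precision is None else self.precision[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"x": self.x, "y": self.y, "frame": self.frame}
        if self.photons is not None:
            data["photons"] = self.photons
        if self.precision is not None:
            data["precision"] = self.precision
        return pd.DataFrame(data)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) in nm; raises on empty tables."""
        if len(self) == 0:
            raise ValueError("empty table has no bounds")
        return (
            float(self.x.min()),
            float(self.x.max()),
            float(self.y.min()),
            float(self.y.max()),
        )


@dataclasses.dataclass(frozen=True)
class HistogramImage:
    """2-D localization-count grid at a stated pixel size.

    ``counts[row, col]`` is the number of localizations falling into the
    half-open pixel; ``origin`` is the (x0, y0) nm position of the low
    corner of pixel ``[0, 0]``.
    """

    counts: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def _resolve_columns(
    columns: Iterable[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lowered = {c.lower().strip(): c for c in columns}
    found: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lowered:
                found[canonical] = lowered[name]
                break
    return found


def read_localizations(
    path: str | Path,
    dialect: str | None = None,
    *,
    units: str = "px",
    camera_pixel_nm: float = DEFAULT_CAMERA_PIXEL_NM,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> LocalizationTable:
    """Read a localization table from CSV or HDF5.

    Parameters
    ----------
    path:
        Input file. ``dialect`` is inferred from the suffix when omitted.
    dialect:
        ``"csv"`` (comma-separated with header) or ``"hdf5"`` (a single
        structured dataset named ``"locs"``, the convention of common SMLM
        fitting software).
    units:
        ``"px"`` if coordinates are stored in camera pixels (they are
        multiplied by ``camera_pixel_nm``), ``"nm"`` if already metric.
    """
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if units not in {"px", "nm"}:
        raise ValueError("units must be 'px' or 'nm'")
    aliases = dict(DEFAULT_ALIASES, **(aliases or {}))

    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise FormatError(f"{path}: no 'locs' dataset")
            df = pd.DataFrame(f["locs"][()])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    resolved = _resolve_columns(df.columns, aliases)
    for required in ("x", "y", "frame"):
        if required not in resolved:
            raise FormatError(f"{path}: missing required column '{required}'")

    def _numeric(canonical: str) -> np.ndarray:
        col = df[resolved[canonical]]
        values = pd.to_numeric(col, errors="coerce").to_numpy()
        bad = np.nonzero(~np.isfinite(values))[0]
        if bad.size and len(col):
            raise FormatError(
                f"{path}: non-numeric value in column '{resolved[canonical]}'"
                f" at row {int(bad[0])}"
            )
        return values

    scale = camera_pixel_nm if units == "px" else 1.0
    return LocalizationTable(
        x=_numeric("x") * scale,
        y=_numeric("y") * scale,
        frame=df[resolved["frame"]].to_numpy() if len(df) else np.empty(0, int),
        photons=_numeric("photons") if "photons" in resolved else None,
        precision=_numeric("precision") if "precision" in resolved else None,
    )


def write_localizations(
    table: LocalizationTable, path: str | Path, dialect: str | None = None
) -> None:
    """Write a table (coordinates in nm) as CSV or as an HDF5 'locs' dataset."""
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    df = table.to_dataframe()
    if dialect == "csv":
        df.to_csv(path, index=False)
    elif dialect == "hdf5":
        rec = df.to_records(index=False)
        with h5py.File(path, "w") as f:
            f.create_dataset("locs", data=rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def render_histogram(
    locs: LocalizationTable,
    pixel_size: float,
    extent: tuple[float, float, float, float] | None = None,
    *,
    shape: tuple[int, int] | None = None,
) -> HistogramImage:
    """Bin localizations into a 2-D count image.

    ``extent`` is ``(x_min, x_max, y_min, y_max)`` in nm; when omitted it is
    taken from the data bounds. ``shape`` forces the output grid size
    (rows, cols), otherwise it is ``ceil(extent / pixel_size)``.
    Localizations outside the grid are dropped (their number is available on
    the returned image as ``n_dropped``).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if extent is None:
        if len(locs) == 0:
            raise ValueError("cannot infer extent from an empty table")
        x0, x1, y0, y1 = locs.bounds
    else:
        x0, x1, y0, y1 = extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError("extent must be a nonempty rectangle")
    if shape is None:
        n_rows = max(1, int(np.ceil((y1 - y0) / pixel_size)))
        n_cols = max(1, int(np.ceil((x1 - x0) / pixel_size)))
    else:
        n_rows, n_cols = shape

    col = np.floor((locs.x - x0) / pixel_size).astype(np.int64)
    row = np.floor((locs.y - y0) / pixel_size).astype(np.int64)
    inside = (col >= 0) & (col < n_cols) & (row >= 0) & (row < n_rows)
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    np.add.at(counts, (row[inside], col[inside]), 1)

    img = HistogramImage(counts=counts, pixel_size=pixel_size, origin=(x0, y0))
    object.__setattr__(img, "n_dropped", int((~inside).sum()))
    return img


def remove_isolated(
    locs: LocalizationTable, radius: float = 50.0, min_neighbors: int = 2
) -> LocalizationTable:
    """Drop localizations with fewer than ``min_neighbors`` others within ``radius`` nm.

    A simple neighbor-count filter: stray single blinks far from any
    structure carry no density information and would otherwise teach a
    reconstruction network to reproduce noise.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    if len(locs) == 0:
        return locs
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([locs.x, locs.y]))
    # counts include the point itself
    n_within = tree.query_ball_point(
        np.column_stack([locs.x, locs.y]), r=radius, return_length=True
    )
    return locs.select(n_within - 1 >= min_neighbors)


def split_by_frame_window(
    locs: LocalizationTable,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[LocalizationTable, tuple[int, int]]:
    """Select a contiguous frame window holding ~``fraction`` of the localizations.

    The window start frame is drawn uniformly among starts from which the
    target count is reachable; the end frame is then chosen so the window
    count is as close as possible to ``fraction * len(locs)``. This
    preserves the temporal blinking structure of a real sub-acquisition.

    Returns the sub-table and the inclusive frame range ``(first, last)``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(locs) == 0:
        raise ValueError("cannot split an empty table")
    if fraction == 1.0:
        return locs, (int(locs.frame.min()), int(locs.frame.max()))

    f_min, f_max = int(locs.frame.min()), int(locs.frame.max())
    n_frames = f_max - f_min + 1
    per_frame = np.bincount(locs.frame - f_min, minlength=n_frames)
    cum = np.concatenate([[0], np.cumsum(per_frame)])  # cum[i] = count of frames < i
    target = fraction * len(locs)

    # valid starts: enough localizations remain from this frame onward
    remaining = cum[-1] - cum[:-1]
    valid = np.nonzero(remaining >= target)[0]
    start = int(rng.choice(valid)) if valid.size else 0
    # window [start, end] count = cum[end+1] - cum[start]; pick best end
    window_counts = cum[start + 1 :] - cum[start]
    end = start + int(np.argmin(np.abs(window_counts - target)))

    mask = (locs.frame >= f_min + start) & (locs.frame <= f_min + end)
    return locs.select(mask), (f_min + start, f_min + end)


def split_half(
    locs: LocalizationTable, rng: np.random.Generator
) -> tuple[LocalizationTable, LocalizationTable]:
    """Randomly partition a table into two disjoint halves (sizes differ by <= 1)."""
    n = len(locs)
    if n < 2:
        raise ValueError("need at least 2 localizations to split")
    perm = rng.permutation(n)
    first = np.zeros(n, dtype=bool)
    first[perm[: n // 2]] = True
    return locs.select(first), locs.select(~first)


def write_histogram_tiff(hist: HistogramImage, path: str | Path) -> None:
    """Write a count image as 16-bit TIFF (counts above 65535 are clipped)."""
    counts = hist.counts
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        warnings.warn("histogram counts exceed 16-bit range; clipping", stacklevel=2)
    tifffile.imwrite(
        str(path),
        np.clip(counts, 0, np.iinfo(np.uint16).max).astype(np.uint16),
        resolution=(1e7 / hist.pixel_size, 1e7 / hist.pixel_size),
    )


def write_density_tiff(values: np.ndarray, pixel_size: float, path: str | Path) -> None:
    """Write a real-valued density image as float32 TIFF."""
    tifffile.imwrite(
        str(path),
        np.asarray(values, dtype=np.float32),
        resolution=(1e7 / pixel_size, 1e7 / pixel_size),
    )
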