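"""Synthetic microtubule-like localization datasets with known ground truth.

The simulator provides every input the rest of the package needs without
real acquisitions: smooth filament geometries, and localization tables that
emulate the dSTORM measurement process on them:

1. Fluorophore binding sites are placed along each filament as a uniform
   Poisson process at the labeling density (sites per nm of arc length).
2. Each site sits on the microtubule surface: it is displaced from the
   filament axis along the local normal by ``linkage_radius * sin(phi)``
   with ``phi`` uniform — the 2-D projection of a label on a tube of that
   radius (default 12.5 nm, the microtubule radius).
3. Each site blinks a Poisson number of times; every blink is assigned a
   uniformly random acquisition frame and localized with isotropic Gaussian
   error of the localization precision (default 10 nm, a typical dSTORM
   value).

Filament geometry is a discretized worm-like chain: a 2-D random walk of
fixed step whose heading diffuses with variance ``step / persistence``, so
large persistence lengths give nearly straight filaments.

All outputs are fully determined by (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from densestorm.localization_io import LocalizationTable

__all__ = [
    "FilamentScene",
    "generate_filaments",
    "simulate_localizations",
    "simulate_filament_pair",
]

#: polyline discretization step (nm); well below any feature of interest
_STEP_NM = 10.0


@dataclasses.dataclass(frozen=True)
class FilamentScene:
    """Ground-truth filament geometry plus the imaging parameters.

    ``filaments`` is a list of (n_points, 2) arrays of (x, y) polyline
    vertices in nm, densely sampled (10 nm step) so chord-length sums
    approximate arc length well.
    """

    filaments: list[np.ndarray]
    field_size: float
    labeling_density: float = 0.5  # antibody sites per nm of filament
    linkage_radius: float = 12.5  # nm; microtubule radius
    localization_precision: float = 10.0  # nm
    frames: int = 20000
    mean_blinks_per_fluorophore: float = 2.0

    def __post_init__(self) -> None:
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")
        for name in ("labeling_density", "localization_precision", "frames",
                     "mean_blinks_per_fluorophore"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.linkage_radius < 0:
            raise ValueError("linkage_radius must be nonnegative")
        filaments = [np.asarray(f, dtype=float) for f in self.filaments]
        for f in filaments:
            if f.ndim != 2 or f.shape[1] != 2 or f.shape[0] < 2:
                raise ValueError("each filament must be an (n>=2, 2) polyline")
        object.__setattr__(self, "filaments", filaments)

    def arc_lengths(self) -> np.ndarray:
        """Total chord length per filament (nm)."""
        return np.array(
            [np.linalg.norm(np.diff(f, axis=0), axis=1).sum() for f in self.filaments]
        )

    def to_json(self, path: str | Path) -> None:
        """Ground-truth control points and parameters as JSON."""
        payload = dataclasses.asdict(self)
        payload["filaments"] = [f.tolist() for f in self.filaments]
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FilamentScene":
        payload = json.loads(Path(path).read_text())
        payload["filaments"] = [np.asarray(f) for f in payload["filaments"]]
        return cls(**payload)


def _wormlike_path(
    rng: np.random.Generator,
    field: float,
    persistence: float,
    min_length: float,
) -> np.ndarray:
    """One worm-like-chain polyline crossing the field.

    Starts on a uniformly random edge point heading inward (± 60 degrees)
    and walks until it leaves the field, retrying until the in-field arc
    length reaches ``min_length``.
    """
    sigma_theta = np.sqrt(_STEP_NM / persistence) if np.isfinite(persistence) else 0.0
    max_steps = int(4 * field / _STEP_NM)
    for _ in range(64):
        edge = rng.integers(4)
        t = rng.uniform(0.05, 0.95) * field
        start, inward = {
            0: ((t, 0.0), np.pi / 2),
            1: ((t, field), -np.pi / 2),
            2: ((0.0, t), 0.0),
            3: ((field, t), np.pi),
        }[edge]
        theta = inward + rng.uniform(-np.pi / 3, np.pi / 3)
        steps = sigma_theta * rng.standard_normal(max_steps)
        headings = theta + np.cumsum(steps)
        deltas = _STEP_NM * np.column_stack([np.cos(headings), np.sin(headings)])
        points = np.vstack([start, start + np.cumsum(deltas, axis=0)])
        inside = (
            (points[:, 0] >= 0)
            & (points[:, 0] <= field)
            & (points[:, 1] >= 0)
            & (points[:, 1] <= field)
        )
        exit_idx = np.argmin(inside) if not inside.all() else len(points)
        points = points[: max(exit_idx, 2)]
        if (len(points) - 1) * _STEP_NM >= min_length:
            return points
    # fall back to a straight chord (pathological persistence settings)
    return points


def generate_filaments(
    n: int,
    field: float,
    curvature: float = 2.0e5,
    rng: np.random.Generator | None = None,
    *,
    min_length_fraction: float = 0.5,
    **scene_kwargs,
) -> FilamentScene:
    """Random smooth filaments spanning a square field.

    ``curvature`` is the persistence length in nm (larger = straighter;
    ``np.inf`` gives exact straight lines). Each filament's arc length is at
    least ``min_length_fraction * field``.
    """
    if n < 1:
        raise ValueError("need at least one filament")
    rng = rng or np.random.default_rng()
    filaments = [
        _wormlike_path(rng, field, curvature, min_length_fraction * field)
        for _ in range(n)
    ]
    return FilamentScene(filaments=filaments, field_size=field, **scene_kwargs)


def simulate_localizations(
    scene: FilamentScene, rng: np.random.Generator | None = None
) -> LocalizationTable:
    """Sample a localization table from a filament scene (see module docs)."""
    rng = rng or np.random.default_rng()
    xs, ys, frames, precisions = [], [], [], []
    for filament in scene.filaments:
        seg = np.diff(filament, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        total = seg_len.sum()
        n_sites = rng.poisson(total * scene.labeling_density)
        if n_sites == 0:
            continue
        # uniform arc-length positions -> segment + offset
        s = rng.uniform(0.0, total, n_sites)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = (s - cum[seg_idx]) / seg_len[seg_idx]
        base = filament[seg_idx] + frac[:, None] * seg[seg_idx]
        tangent = seg[seg_idx] / seg_len[seg_idx][:, None]
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
        # projected tube-surface offset: R * sin(phi), phi uniform
        offset = scene.linkage_radius * np.sin(rng.uniform(0, 2 * np.pi, n_sites))
        sites = base + offset[:, None] * normal

        blinks = rng.poisson(scene.mean_blinks_per_fluorophore, n_sites)
        repeat_sites = np.repeat(sites, blinks, axis=0)
        n_blinks = repeat_sites.shape[0]
        noise = scene.localization_precision * rng.standard_normal((n_blinks, 2))
        coords = repeat_sites + noise
        xs.append(coords[:, 0])
        ys.append(coords[:, 1])
        frames.append(rng.integers(0, scene.frames, n_blinks))
        precisions.append(np.full(n_blinks, scene.localization_precision))

    if not xs:
        return LocalizationTable(
            x=np.empty(0), y=np.empty(0), frame=np.empty(0, dtype=int)
        )
    return LocalizationTable(
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        frame=np.concatenate(frames),
        precision=np.concatenate(precisions),
    )


def simulate_filament_pair(
    distance: float,
    field: float = 2000.0,
    rng: np.random.Generator | None = None,
    **scene_kwargs,
) -> tuple[LocalizationTable, FilamentScene]:
    """Two parallel straight filaments at an exact center-to-center distance.

    The pair is vertical and centered in the field (axes at
    ``field/2 ± distance/2``); ``distance = 0`` degenerates to a single
    effective filament (allowed). Returns the sampled localizations and the
    ground-truth scene.
    """
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    rng = rng or np.random.default_rng()
    n_pts = max(2, int(field / _STEP_NM) + 1)
    y = np.linspace(0.0, field, n_pts)
    x_left = np.full(n_pts, field / 2 - distance / 2)
    x_right = np.full(n_pts, field / 2 + distance / 2)
    scene = FilamentScene(
        filaments=[np.column_stack([x_left, y]), np.column_stack([x_right, y])],
        field_size=field,
        **scene_kwargs,
    )
    return simulate_localizations(scene, rng), scene
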