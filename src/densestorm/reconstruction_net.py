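"""U-Net-style generator mapping sparse localization histograms to densities.

Architecture: the encoder downsamples with strided 4x4 convolutions
(stride 2, LeakyReLU 0.2), doubling the filter count up to a plateau
(default schedule 64-128-256-512-512-512-512-512, eight levels); the
decoder mirrors it with 4x4 transposed convolutions (ReLU) and skip
connections concatenating each encoder output to the decoder level of the
same size; a final transposed convolution with tanh produces the output
image at input resolution.

Besides the full eight-level profile, a reduced "desk" profile (five
levels, 64-256 filters, 64-px patches) and a "tiny" profile (three levels)
are first-class configurations for CPU-scale experiments.

Data pipeline: targets are KDE density estimates of the full localization
dataset; inputs are histograms of contiguous frame windows holding 5-30%
of the localizations. Registered random crops are taken from both, rotated
by a continuous random angle, and center-cropped so rotation voids stay
outside the training patch. Images are normalized to [-1, 1] by a robust
(99.9th percentile) intensity scale; losses are evaluated after mapping
back to density units.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from densestorm.density_estimation import DensityImage, KernelWindow, anisotropic_kde, gaussian_kde
from densestorm.localization_io import (
    HistogramImage,
    LocalizationTable,
    remove_isolated,
    render_histogram,
    split_by_frame_window,
)
from densestorm.losses import LossConfig, combined_loss
from densestorm.nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Module, Tensor, concat, no_grad

__all__ = [
    "GeneratorConfig",
    "TrainingConfig",
    "TrainingPair",
    "Generator",
    "build_generator",
    "layer_shapes",
    "make_training_pairs",
    "train",
    "predict",
    "save_model",
    "load_model",
]

FULL_FILTERS = (64, 128, 256, 512, 512, 512, 512, 512)


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Shape of the encoder/decoder generator.

    ``filters[i]`` is the output channel count of encoder level ``i``;
    the decoder mirrors the schedule. ``norm`` is "batch" (default; running
    statistics are used at inference, so prediction is deterministic and
    tile-independent) or "none" (a purely local network).
    """

    depth: int = 8
    filters: tuple[int, ...] = FULL_FILTERS
    kernel_size: int = 4
    stride: int = 2
    in_channels: int = 1
    out_channels: int = 1
    norm: str = "batch"
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if len(self.filters) != self.depth:
            raise ValueError("filters must have one entry per level")
        if self.norm not in {"batch", "none"}:
            raise ValueError("norm must be 'batch' or 'none'")

    @classmethod
    def desk(cls) -> "GeneratorConfig":
        """Reduced profile for CPU-scale runs (64-px patches)."""
        return cls(depth=5, filters=(64, 128, 256, 256, 256))

    @classmethod
    def tiny(cls) -> "GeneratorConfig":
        """Minimal profile for fast experiments and tests."""
        return cls(depth=3, filters=(16, 32, 64))


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    """Optimization and data-pipeline settings."""

    lr: float = 2e-4
    beta1: float = 0.5
    epochs: int = 1000
    batch_size: int = 4
    patch_crop: int = 750
    patch_train: int = 512
    sparse_fraction_range: tuple[float, float] = (0.05, 0.30)
    pixel_size: float = 5.0
    seed: int = 0
    rotate: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.sparse_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("sparse fractions must satisfy 0 < lo <= hi <= 1")
        if self.patch_train > self.patch_crop:
            raise ValueError("patch_train must not exceed patch_crop")


@dataclasses.dataclass
class TrainingPair:
    """One registered (sparse input, dense target) patch pair in [-1, 1] units."""

    input_patch: np.ndarray
    target_patch: np.ndarray
    input_scale: float
    target_scale: float
    provenance: dict


class _EncoderBlock(Module):
    def __init__(self, c_in, c_out, cfg: GeneratorConfig, rng, use_norm: bool):
        self.conv = Conv2d(c_in, c_out, cfg.kernel_size, cfg.stride, pad=1, rng=rng)
        self.norm = BatchNorm2d(c_out) if use_norm else None
        self.slope = cfg.leaky_slope

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return x.leaky_relu(self.slope)


class _DecoderBlock(Module):
    def __init__(self, c_in, c_out, cfg: GeneratorConfig, rng, use_norm: bool):
        self.conv = ConvTranspose2d(c_in, c_out, cfg.kernel_size, cfg.stride, pad=1, rng=rng)
        self.norm = BatchNorm2d(c_out) if use_norm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return x.relu()


class Generator(Module):
    """Encoder/decoder with skip connections; output shape equals input shape."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        use_norm = cfg.norm == "batch"
        self.encoders: list[_EncoderBlock] = []
        c_prev = cfg.in_channels
        for i, f in enumerate(cfg.filters):
            # first encoder level conventionally has no normalization
            self.encoders.append(_EncoderBlock(c_prev, f, cfg, rng, use_norm and i > 0))
            c_prev = f
        self.decoders: list[_DecoderBlock] = []
        for i in range(cfg.depth - 1, 0, -1):
            self.decoders.append(_DecoderBlock(c_prev, cfg.filters[i - 1], cfg, rng, use_norm))
            c_prev = 2 * cfg.filters[i - 1]  # skip concatenation doubles channels
        self.head = ConvTranspose2d(c_prev, cfg.out_channels, cfg.kernel_size, cfg.stride, pad=1, rng=rng)
        # metadata filled by `train`, used by `predict`
        self.meta: dict = {}

    def forward(self, x: Tensor) -> Tensor:
        side = x.shape[-1]
        if side % (self.cfg.stride**self.cfg.depth) != 0 or min(x.shape[-2:]) < 2**self.cfg.depth:
            raise ValueError(
                f"input side {x.shape[-2:]} must be a multiple of "
                f"{self.cfg.stride ** self.cfg.depth} (stride^depth)"
            )
        skips = []
        for encoder in self.encoders:
            x = encoder(x)
            skips.append(x)
        for i, decoder in enumerate(self.decoders):
            x = decoder(x)
            x = concat([x, skips[-(i + 2)]], axis=1)
        return self.head(x).tanh()


def build_generator(
    cfg: GeneratorConfig = GeneratorConfig(), seed: int | None = None
) -> Generator:
    """Construct a generator with seeded Gaussian(0, 0.02) weight init."""
    return Generator(cfg, np.random.default_rng(seed))


def layer_shapes(cfg: GeneratorConfig, input_size: int) -> list[dict]:
    """Programmatic enumeration of layer output shapes (no weights built).

    Returns one record per layer with keys ``name``, ``out_channels``,
    ``size`` (spatial side). Raises if ``input_size`` is not divisible by
    ``stride ** depth``.
    """
    if input_size % (cfg.stride**cfg.depth) != 0:
        raise ValueError("input size must be divisible by stride^depth")
    records = []
    size = input_size
    for i, f in enumerate(cfg.filters):
        size //= cfg.stride
        records.append({"name": f"enc{i + 1}", "out_channels": f, "size": size})
    channels = cfg.filters[-1]
    for j, i in enumerate(range(cfg.depth - 1, 0, -1)):
        size *= cfg.stride
        f = cfg.filters[i - 1]
        records.append({"name": f"dec{j + 1}", "out_channels": f, "size": size})
        records.append({"name": f"skip{j + 1}", "out_channels": 2 * f, "size": size})
        channels = 2 * f
    size *= cfg.stride
    records.append({"name": "head(tanh)", "out_channels": cfg.out_channels, "size": size})
    return records


# ---------------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------------

def _robust_scale(values: np.ndarray, percentile: float = 99.9) -> float:
    scale = float(np.percentile(values[values > 0], percentile)) if np.any(values > 0) else 1.0
    return scale if scale > 0 else 1.0


def _count_scale(counts: np.ndarray) -> float:
    """Intensity scale for sparse count histograms.

    At SMLM sparsity most occupied pixels hold a single localization, so the
    median positive count (usually 1) maps occupancy to full signal; higher
    counts are clipped by the normalization.
    """
    positive = counts[counts > 0]
    return float(np.median(positive)) if positive.size else 1.0


def _normalize(values: np.ndarray, scale: float) -> np.ndarray:
    return 2.0 * np.clip(values / scale, 0.0, 1.0) - 1.0

def _denormalize(values: np.ndarray, scale: float) -> np.ndarray:
    return np.clip((values + 1.0) * (scale / 2.0), 0.0, None)


def rotate_and_center_crop(
    patch: np.ndarray, angle_deg: float, out_size: int
) -> np.ndarray:
    """Rotate by a continuous angle (bilinear, reflection padding) and center-crop.

    The crop margin exists exactly so rotation voids stay outside the
    returned patch; axis-aligned angles (multiples of 90 degrees) are exact.
    """
    if angle_deg % 360.0:
        patch = ndimage.rotate(patch, angle_deg, reshape=False, order=1, mode="reflect")
    margin = (patch.shape[0] - out_size) // 2
    return patch[margin : margin + out_size, margin : margin + out_size]


def make_target_field(
    locs: LocalizationTable,
    kde: str,
    cfg: TrainingConfig,
    *,
    extent: tuple[float, float, float, float] | None = None,
    shape: tuple[int, int] | None = None,
    kde_sigma_px: float = 1.0,
    kde_window: KernelWindow = KernelWindow(size=11, scale=2.0),
    isolation_radius: float = 50.0,
    min_neighbors: int = 2,
) -> tuple[HistogramImage, DensityImage]:
    """Full-data histogram (isolated localizations removed) and its KDE density."""
    cleaned = remove_isolated(locs, isolation_radius, min_neighbors)
    hist = render_histogram(cleaned, cfg.pixel_size, extent, shape=shape)
    if kde == "gaussian":
        density = gaussian_kde(hist, kde_sigma_px)
    elif kde == "anisotropic":
        density = anisotropic_kde(hist, kde_window)
    else:
        raise ValueError("kde must be 'gaussian' or 'anisotropic'")
    return hist, density


def make_training_pairs(
    locs: LocalizationTable,
    kde: str,
    cfg: TrainingConfig,
    rng: np.random.Generator,
    n_pairs: int,
    **target_kwargs,
) -> list[TrainingPair]:
    """Registered (sparse histogram, dense KDE) patch pairs for training.

    For each pair: a contiguous frame window holding a uniform-random
    fraction of the localizations is rendered on the full-field grid; a
    random ``patch_crop`` crop is taken at the same offset from the sparse
    histogram and the target density; both are rotated by the same
    continuous random angle (bilinear, reflection padding) and
    center-cropped to ``patch_train``.
    """
    hist, density = make_target_field(locs, kde, cfg, **target_kwargs)
    field = np.asarray(hist.counts, dtype=float)
    target = density.values
    h, w = field.shape
    if min(h, w) < cfg.patch_crop:
        raise ValueError(
            f"rendered field {field.shape} smaller than patch_crop {cfg.patch_crop}"
        )
    target_scale = _robust_scale(target)
    lo, hi = cfg.sparse_fraction_range

    pairs: list[TrainingPair] = []
    for k in range(n_pairs):
        fraction = rng.uniform(lo, hi)
        sparse, window = split_by_frame_window(locs, fraction, rng)
        sparse_hist = render_histogram(
            sparse, cfg.pixel_size, (hist.origin[0], hist.origin[0] + w * cfg.pixel_size,
                                     hist.origin[1], hist.origin[1] + h * cfg.pixel_size),
            shape=field.shape,
        )
        sparse_field = np.asarray(sparse_hist.counts, dtype=float)
        input_scale = _count_scale(sparse_field)

        # redraw crops that land on (near-)empty regions: an all-zero target
        # patch has no FRC normalization and teaches nothing
        for _attempt in range(64):
            r0 = int(rng.integers(0, h - cfg.patch_crop + 1))
            c0 = int(rng.integers(0, w - cfg.patch_crop + 1))
            in_patch = sparse_field[r0 : r0 + cfg.patch_crop, c0 : c0 + cfg.patch_crop]
            tg_patch = target[r0 : r0 + cfg.patch_crop, c0 : c0 + cfg.patch_crop]

            angle = float(rng.uniform(0.0, 360.0)) if cfg.rotate else 0.0
            in_patch = rotate_and_center_crop(in_patch, angle, cfg.patch_train)
            tg_patch = rotate_and_center_crop(tg_patch, angle, cfg.patch_train)
            if np.count_nonzero(tg_patch > 0) >= 0.01 * tg_patch.size:
                break

        pairs.append(
            TrainingPair(
                input_patch=_normalize(in_patch, input_scale),
                target_patch=_normalize(tg_patch, target_scale),
                input_scale=input_scale,
                target_scale=target_scale,
                provenance={
                    "pair": k,
                    "crop": (r0, c0),
                    "rotation_deg": angle,
                    "fraction": fraction,
                    "frame_window": window,
                },
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _batch_loss(model, batch: Sequence[TrainingPair], loss_cfg: LossConfig):
    x = Tensor(np.stack([p.input_patch for p in batch])[:, None])
    target_scale = batch[0].target_scale
    target = np.stack([p.target_patch for p in batch])[:, None]
    pred = model(x)
    # evaluate the loss in density units (invert the [-1, 1] mapping)
    half = target_scale / 2.0
    pred_density = (pred + 1.0) * half
    target_density = (Tensor(target) + 1.0) * half
    return combined_loss(pred_density, target_density, loss_cfg, data_range=target_scale)


def train(
    model: Generator,
    pairs: Sequence[TrainingPair],
    cfg: TrainingConfig,
    loss_cfg: LossConfig = LossConfig(),
    validation_pairs: Sequence[TrainingPair] = (),
) -> pd.DataFrame:
    """ADAM training loop; returns the per-epoch loss history.

    Logs every loss term for training (and validation when provided) per
    epoch and restores the parameters with the best validation total loss
    (best training loss when no validation pairs are given) at the end.
    Aborts with a diagnostic on a non-finite loss.
    """
    if not pairs:
        raise ValueError("empty training stream")
    optimizer = Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best = (np.inf, None)
    model.set_training(True)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        epoch_terms: list[dict] = []
        for start in range(0, len(pairs), cfg.batch_size):
            batch = [pairs[i] for i in order[start : start + cfg.batch_size]]
            optimizer.zero_grad()
            total, terms = _batch_loss(model, batch, loss_cfg)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch pairs "
                    f"{[p.provenance.get('pair') for p in batch]}: {terms}"
                )
            total.backward()
            optimizer.step()
            epoch_terms.append(terms)
        record = {"epoch": epoch}
        for key in ("frc", "mssim", "l1", "total"):
            record[f"train_{key}"] = float(np.mean([t[key] for t in epoch_terms]))
        if validation_pairs:
            model.set_training(False)
            with no_grad():
                _, val_terms = _batch_loss(model, list(validation_pairs), loss_cfg)
            model.set_training(True)
            for key in ("frc", "mssim", "l1", "total"):
                record[f"val_{key}"] = val_terms[key]
            score = record["val_total"]
        else:
            score = record["train_total"]
        if score < best[0]:
            best = (score, model.state_dict())
        history.append(record)

    if best[1] is not None:
        model.load_state_dict(best[1])
    model.meta = {
        "target_scale": float(pairs[0].target_scale),
        "patch_train": cfg.patch_train,
        "pixel_size": cfg.pixel_size,
    }
    return pd.DataFrame(history)


def predict(
    model: Generator,
    hist: HistogramImage | np.ndarray,
    *,
    tile: int | None = None,
    overlap_fraction: float = 0.25,
) -> DensityImage:
    """Reconstruct a density image from a (sparse) histogram.

    The input is normalized by its own robust intensity scale, padded to a
    multiple of ``stride ** depth``, and passed through the network; the
    tanh output is mapped back to density units with the target scale
    recorded at training time. Inputs larger than ``tile`` (default: the
    training patch size) are processed in overlapping tiles blended with
    linear ramps.
    """
    values = np.asarray(getattr(hist, "counts", getattr(hist, "values", hist)), dtype=float)
    pixel_size = getattr(hist, "pixel_size", model.meta.get("pixel_size", 1.0))
    target_scale = model.meta.get("target_scale", 1.0)
    tile = tile or model.meta.get("patch_train", 512)
    step = model.cfg.stride**model.cfg.depth

    scale_in = _count_scale(values)
    normed = _normalize(values, scale_in)

    model.set_training(False)

    def run(patch: np.ndarray) -> np.ndarray:
        h, w = patch.shape
        ph = (-h) % step, (-w) % step
        padded = np.pad(patch, ((0, ph[0]), (0, ph[1])), mode="reflect") if any(ph) else patch
        with no_grad():
            out = model(Tensor(padded[None, None])).data[0, 0]
        return out[:h, :w]

    h, w = normed.shape
    if max(h, w) <= tile:
        out = run(normed)
    else:
        overlap = max(step, int(tile * overlap_fraction) // step * step)
        stride_px = tile - overlap
        out = np.zeros_like(normed)
        weight = np.zeros_like(normed)
        ramp = np.minimum(np.arange(1, tile + 1), overlap) / overlap

        def ramp1d(lo: int, hi: int, full: int) -> np.ndarray:
            r = np.ones(hi - lo)
            if lo > 0:
                r = np.minimum(r, ramp[: hi - lo])
            if hi < full:
                r = np.minimum(r, ramp[: hi - lo][::-1])
            return r

        for r0 in range(0, max(h - overlap, 1), stride_px):
            for c0 in range(0, max(w - overlap, 1), stride_px):
                r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
                r0a, c0a = max(0, r1 - tile), max(0, c1 - tile)
                block = run(normed[r0a:r1, c0a:c1])
                wgt = np.outer(ramp1d(r0a, r1, h), ramp1d(c0a, c1, w))
                out[r0a:r1, c0a:c1] += block * wgt
                weight[r0a:r1, c0a:c1] += wgt
                if c1 == w:
                    break
            if r1 == h:
                break
        out /= np.maximum(weight, 1e-12)

    return DensityImage(values=_denormalize(out, target_scale), pixel_size=pixel_size)


def save_model(model: Generator, path: str | Path) -> None:
    """Checkpoint: weights plus config/meta as an .npz archive."""
    payload = {f"param_{i}": p for i, p in enumerate(model.state_dict())}
    payload["meta_json"] = np.frombuffer(
        json.dumps({"cfg": dataclasses.asdict(model.cfg), "meta": model.meta}).encode(),
        dtype=np.uint8,
    )
    np.savez(str(path), **payload)


def load_model(path: str | Path) -> Generator:
    with np.load(str(path)) as archive:
        info = json.loads(bytes(archive["meta_json"].tobytes()).decode())
        cfg_dict = info["cfg"]
        cfg_dict["filters"] = tuple(cfg_dict["filters"])
        cfg_dict["sparse_fraction_range"] = cfg_dict.get("sparse_fraction_range")
        cfg_dict.pop("sparse_fraction_range", None)
        cfg = GeneratorConfig(**cfg_dict)
        model = Generator(cfg, np.random.default_rng(0))
        n = len(model.state_dict())  # parameters plus normalization buffers
        model.load_state_dict([archive[f"param_{i}"] for i in range(n)])
        model.meta = info["meta"]
    return model
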