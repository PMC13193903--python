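"""Quality filtering and image standardization.

Raw frames from the acquisition are arbitrary rectangles. The pipeline
standardizes them in three steps:

1. :func:`center_crop_square` — crop to the centered short-edge square;
2. :func:`qc_filter` — discard frames whose shorter edge is below 50 px
   (at that scale frames are mostly debris and carry no usable morphology);
3. :func:`to_model_input` — replicate grayscale to 3 channels, resize to
   224 x 224 (bilinear) and normalize with fixed constants.

:func:`augment` implements the training-only augmentation stack: random
horizontal flip, small rotations (+-10 deg), and a random resized crop
retaining 80-100 % of the area with up to +-10 % translation. All
augmentations are label-preserving by construction and deterministic given
a seed.

A ``CellImage`` is any 2-D uint8/float array; a ``ModelInput`` is a
224 x 224 x 3 float32 array (channels identical before augmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from functools import lru_cache

from skimage.transform import AffineTransform, warp

MODEL_SIZE = 224


@lru_cache(maxsize=64)
def _resize_matrix(n_in: int, n_out: int) -> "np.ndarray":
    """1-D bilinear interpolation matrix (n_out x n_in), edge-clamped.

    Output pixel centres map to input coordinates via the standard
    half-pixel convention: x = (i + 0.5) * n_in / n_out - 0.5.
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    x = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    x = np.clip(x, 0.0, n_in - 1.0)
    lo = np.floor(x).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = x - lo
    m[np.arange(n_out), lo] += 1.0 - w
    m[np.arange(n_out), hi] += w
    return m


def bilinear_resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Separable bilinear resize of a 2-D image (edge-clamped)."""
    r = _resize_matrix(img.shape[0], shape[0])
    c = _resize_matrix(img.shape[1], shape[1])
    return (r @ img.astype(np.float32)) @ c.T
#: fixed normalization constants, applied identically at train and test time
NORM_MEAN = 0.5
NORM_STD = 0.25
#: default QC threshold: frames with shorter edge < 50 px are discarded
MIN_SHORT_EDGE = 50


def load_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF frame as a 2-D uint8 array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse an incidental RGB save; channels identical
        img = img[..., 0]
    return img


def center_crop_square(img: np.ndarray) -> np.ndarray:
    """Crop to the centered S x S window, S = min(height, width).

    Odd remainders use the floor-based offset, so for a 60 x 100 input the
    retained columns are 20..79. Idempotent on square inputs.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    h, w = img.shape
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    return img[top : top + s, left : left + s]


def image_sizes(
    manifest: pd.DataFrame, loader=load_image
) -> pd.DataFrame:
    """Resolve (height, width) for every manifest row.

    Uses explicit ``height`` / ``width`` columns when present, otherwise
    reads the file at ``path``. An unreadable file raises, naming the row.
    """
    if {"height", "width"}.issubset(manifest.columns):
        return manifest[["height", "width"]].astype(int)
    heights, widths = [], []
    for idx, row in manifest.iterrows():
        try:
            img = loader(row["path"])
        except Exception as exc:  # noqa: BLE001 - re-raise with row context
            raise OSError(
                f"manifest row {idx} (image_id={row.get('image_id', '?')}): "
                f"cannot read image at {row.get('path', '?')!r}: {exc}"
            ) from exc
        heights.append(img.shape[0])
        widths.append(img.shape[1])
    return pd.DataFrame({"height": heights, "width": widths}, index=manifest.index)


def qc_report(
    manifest: pd.DataFrame,
    min_short_edge: int = MIN_SHORT_EDGE,
    loader=load_image,
) -> pd.DataFrame:
    """Per-row QC report: image_id, height, width, kept flag, reason."""
    sizes = image_sizes(manifest, loader=loader)
    short = np.minimum(sizes["height"], sizes["width"])
    kept = short >= min_short_edge
    return pd.DataFrame(
        {
            "image_id": manifest.get("image_id", pd.Series(manifest.index)),
            "height": sizes["height"],
            "width": sizes["width"],
            "kept": kept,
            "reason": np.where(
                kept, "", f"short_edge<{min_short_edge}"
            ),
        },
        index=manifest.index,
    )


def qc_filter(
    manifest: pd.DataFrame,
    min_short_edge: int = MIN_SHORT_EDGE,
    loader=load_image,
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose image's shorter edge is strictly below the threshold.

    The rule is strict: a frame whose shorter edge equals the threshold is
    kept. Row order is preserved; returns (kept manifest, rejected count).
    """
    if len(manifest) == 0:
        return manifest.copy(), 0
    report = qc_report(manifest, min_short_edge=min_short_edge, loader=loader)
    kept = manifest.loc[report["kept"]]
    return kept, int(len(manifest) - len(kept))


def to_model_input(img: np.ndarray) -> np.ndarray:
    """Standardize one grayscale frame into a 224 x 224 x 3 model input.

    Intensities are scaled to [0, 1] (divide by 255), resized with bilinear
    interpolation, normalized as (x - 0.5) / 0.25, and replicated across
    three channels. Deterministic.
    """
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    x = img / 255.0
    if x.shape != (MODEL_SIZE, MODEL_SIZE):
        x = bilinear_resize(x, (MODEL_SIZE, MODEL_SIZE))
    x = (x - NORM_MEAN) / NORM_STD
    return np.repeat(x[:, :, None], 3, axis=2)


@dataclass(frozen=True)
class AugmentPolicy:
    """Training-only augmentation ranges.

    hflip_prob: probability of a horizontal mirror (default 0.5);
    rot_deg_max: rotation sampled uniformly on [-rot_deg_max, +rot_deg_max];
    rrc_area_range: random-resized-crop retained-area interval;
    translate_frac_max: crop-centre translation as a fraction of the side.
    """

    hflip_prob: float = 0.5
    rot_deg_max: float = 10.0
    rrc_area_range: tuple[float, float] = (0.8, 1.0)
    translate_frac_max: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")
        lo, hi = self.rrc_area_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("rrc_area_range must be within (0, 1]")


def draw_augment_params(
    policy: AugmentPolicy, rng: np.random.Generator
) -> dict:
    """Sample one augmentation parameter set from the policy's ranges."""
    lo, hi = policy.rrc_area_range
    return {
        "flip": bool(rng.random() < policy.hflip_prob),
        "angle_deg": float(rng.uniform(-policy.rot_deg_max, policy.rot_deg_max)),
        "area": float(rng.uniform(lo, hi)),
        "dx_frac": float(
            rng.uniform(-policy.translate_frac_max, policy.translate_frac_max)
        ),
        "dy_frac": float(
            rng.uniform(-policy.translate_frac_max, policy.translate_frac_max)
        ),
    }


def apply_augment_params(x: np.ndarray, params: dict) -> np.ndarray:
    """Apply a drawn parameter set: flip -> rotate -> resized crop.

    Out-of-frame pixels are filled with the border-median intensity rather
    than black, which would be an artifact alien to brightfield frames.
    """
    size = x.shape[0]
    chan = x[:, :, 0]
    border = np.concatenate(
        [chan[0, :], chan[-1, :], chan[:, 0], chan[:, -1]]
    )
    fill = float(np.median(border))
    out = chan
    if params["flip"]:
        out = out[:, ::-1]
    if params["angle_deg"]:
        c = (size - 1) / 2.0
        ang = np.deg2rad(params["angle_deg"])
        tf = (
            AffineTransform(translation=(-c, -c))
            + AffineTransform(rotation=ang)
            + AffineTransform(translation=(c, c))
        )
        out = warp(out, tf.inverse, order=1, cval=fill, mode="constant")
    side = size * np.sqrt(params["area"])
    cx = (size - 1) / 2.0 + params["dx_frac"] * size
    cy = (size - 1) / 2.0 + params["dy_frac"] * size
    half = side / 2.0
    x0 = int(np.clip(np.floor(cx - half), 0, size - 2))
    y0 = int(np.clip(np.floor(cy - half), 0, size - 2))
    x1 = int(np.clip(np.ceil(cx + half), x0 + 1, size))
    y1 = int(np.clip(np.ceil(cy + half), y0 + 1, size))
    out = out[y0:y1, x0:x1]
    if out.shape != (size, size):
        out = bilinear_resize(out, (size, size))
    return np.repeat(out[:, :, None].astype(np.float32), 3, axis=2)


def augment(
    x: np.ndarray, policy: AugmentPolicy, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Randomly augment one model input; identity when policy is disabled.

    Operates on channel 0 and replicates (channels are identical by the
    model-input contract), so the output keeps the replication invariant.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("expected a H x W x 3 model input")
    if not policy.enabled:
        return x
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return apply_augment_params(x, draw_augment_params(policy, rng))
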