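"""Deterministic preprocessing and real-time (on-draw) image augmentation.

Preprocessing center-crops each photograph to a 4:3 aspect ratio, resizes it
to 256x192 px and rescales intensities to [0, 1].  Augmentation applies, per
draw, one random affine warp composed of a small rotation (default up to
5 degrees), horizontal/vertical shifts (up to 5% of the image size), shear
(intensity up to 0.05) and zoom (up to 5%), with out-of-bounds pixels filled
by the nearest edge value.  The four transforms are composed into a single
affine matrix so the image is resampled only once (bilinear), avoiding
cumulative interpolation blur.

"Real-time" means the warp is drawn when the image is selected into a batch:
two epochs see two different warps of the same photograph, unlike offline
augmentation which fixes a finite augmented pool up front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import InvalidInputError

__all__ = ["AugmentConfig", "PreprocessSpec", "preprocess", "augment"]


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random affine warp; all draws are uniform in +/- range."""

    rotation_max_deg: float = 5.0
    shift_max_frac: float = 0.05
    shear_max: float = 0.05
    zoom_max_frac: float = 0.05
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rotation_max_deg", "shift_max_frac", "shear_max", "zoom_max_frac"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.fill_mode != "nearest":
            raise InvalidInputError(f"unsupported fill_mode {self.fill_mode!r}")


@dataclass(frozen=True)
class PreprocessSpec:
    """Target raster geometry: 256x192 px (4:3), intensities in [0, 1]."""

    target_width: int = 256
    target_height: int = 192

    @property
    def aspect(self) -> float:
        return self.target_width / self.target_height


def preprocess(image, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Center-crop to the target aspect ratio, resize, scale to [0, 1].

    Accepts a PIL image or an HxWx3 array (uint8 in [0,255] or float already
    in [0,1]); returns a float64 array of shape (target_height, target_width, 3).
    """
    if isinstance(image, Image.Image):
        arr = np.asarray(image.convert("RGB"))
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise InvalidInputError(f"expected a non-empty HxWx3 RGB raster, got shape {arr.shape}")

    h, w = arr.shape[:2]
    if w / h > spec.aspect:  # too wide: crop width
        new_w = max(1, int(round(h * spec.aspect)))
        x0 = (w - new_w) // 2
        arr = arr[:, x0 : x0 + new_w]
    else:  # too tall: crop height
        new_h = max(1, int(round(w / spec.aspect)))
        y0 = (h - new_h) // 2
        arr = arr[y0 : y0 + new_h]

    if np.issubdtype(arr.dtype, np.floating):
        arr8 = np.clip(arr * 255.0, 0, 255).astype(np.uint8) if arr.max() <= 1.0 else np.clip(
            arr, 0, 255
        ).astype(np.uint8)
    else:
        arr8 = arr.astype(np.uint8)
    resized = Image.fromarray(arr8).resize(
        (spec.target_width, spec.target_height), Image.BILINEAR
    )
    return np.asarray(resized, dtype=np.float64) / 255.0


def _affine_matrix(
    angle_deg: float, shift_rows: float, shift_cols: float, shear: float, zoom: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse (output -> input) mapping for the composed warp, about center.

    Forward application order: rotate, shift, shear, zoom.
    Coordinates are (row, col).
    """
    theta = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0.0], [np.sin(theta), np.cos(theta), 0.0], [0, 0, 1.0]]
    )
    shift = np.array([[1.0, 0, shift_rows], [0, 1.0, shift_cols], [0, 0, 1.0]])
    shr = np.array([[1.0, shear, 0], [0, 1.0, 0], [0, 0, 1.0]])
    zm = np.array([[zoom, 0, 0], [0, zoom, 0], [0, 0, 1.0]])
    forward = zm @ shr @ shift @ rot
    center = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    inv = np.linalg.inv(forward)
    matrix = inv[:2, :2]
    offset = center + inv[:2, 2] - matrix @ center
    return matrix, offset


def augment(
    image: np.ndarray,
    config: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One random affine warp of a preprocessed [0,1] raster.

    Output shape equals input shape; pixels stay in [0, 1]; deterministic
    given the generator state.  With all ranges zero the input is returned
    unchanged (identity warp).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected an HxWx3 raster, got shape {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise InvalidInputError("image must be preprocessed to [0, 1]")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    h, w = arr.shape[:2]
    angle = rng.uniform(-config.rotation_max_deg, config.rotation_max_deg)
    shift_r = rng.uniform(-config.shift_max_frac, config.shift_max_frac) * h
    shift_c = rng.uniform(-config.shift_max_frac, config.shift_max_frac) * w
    shear = rng.uniform(-config.shear_max, config.shear_max)
    zoom = 1.0 + rng.uniform(-config.zoom_max_frac, config.zoom_max_frac)

    if angle == 0.0 and shift_r == 0.0 and shift_c == 0.0 and shear == 0.0 and zoom == 1.0:
        return arr.copy()

    matrix, offset = _affine_matrix(angle, shift_r, shift_c, shear, zoom, (h, w))
    out = np.empty_like(arr)
    for c in range(3):  # bilinear warp; nearest-edge fill out of bounds
        out[:, :, c] = ndimage.affine_transform(
            arr[:, :, c], matrix, offset=offset, order=1, mode="nearest"
        )
    return np.clip(out, 0.0, 1.0)
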