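"""Seeded generator of imbalanced two-class lesion-like image datasets.

Each image is a skin-tone textured background carrying one elliptical
"lesion" whose border irregularity, asymmetry (elongation), darkness and
size are drawn from class-conditional distributions.  The positive
("melanoma-like") class shifts those distributions towards darker, larger,
more irregular and more asymmetric lesions by an amount controlled by
``separability`` in [0, 1]: at 0 the two classes are identically
distributed (chance-level AUC); at 1 the class-parameter distributions are
well separated and a handcrafted border-roughness/darkness feature alone
ranks the classes almost perfectly.

The goal is controllable statistical structure for testing an imbalance-
aware training pipeline offline, not photorealism.

Also provided: a binormal score generator (:func:`generate_scores`) whose
expected ROC AUC equals a requested target — the standard tool for
exercising ROC/threshold machinery without training a model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.stats import norm

from .errors import InvalidInputError

__all__ = [
    "SynthConfig",
    "generate_arrays",
    "generate_dataset",
    "generate_scores",
    "mclass_like_benchmark",
    "lesion_border_roughness",
]

# class-conditional parameter ranges: (negative-class mean, positive-class
# mean at separability=1); spreads are common to both classes
_PARAM_RANGES = {
    "darkness": (0.25, 0.60, 0.10),  # how much darker the lesion is than skin
    "irregularity": (0.05, 0.30, 0.05),  # amplitude of the border perturbation
    "asymmetry": (0.05, 0.45, 0.08),  # elongation of the ellipse
    "radius_frac": (0.22, 0.32, 0.04),  # lesion radius as fraction of min(H, W)
}


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 20
    n_neg: int = 80
    image_height: int = 192
    image_width: int = 256
    separability: float = 0.8
    noise_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InvalidInputError("n_pos and n_neg must be >= 1")
        if not (0.0 <= self.separability <= 1.0):
            raise InvalidInputError("separability must lie in [0, 1]")
        if self.noise_level < 0:
            raise InvalidInputError("noise_level must be >= 0")
        if self.image_height < 16 or self.image_width < 16:
            raise InvalidInputError("images must be at least 16x16")


def _draw_params(label: int, config: SynthConfig, rng: np.random.Generator) -> dict:
    params = {}
    for name, (neg_mean, pos_mean_full, sd) in _PARAM_RANGES.items():
        mean = neg_mean + (pos_mean_full - neg_mean) * config.separability * label
        params[name] = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
    params["angle"] = float(rng.uniform(0, np.pi))
    params["n_lobes"] = int(rng.integers(4, 9))
    params["phase"] = float(rng.uniform(0, 2 * np.pi))
    params["cx_frac"] = float(rng.uniform(0.4, 0.6))
    params["cy_frac"] = float(rng.uniform(0.4, 0.6))
    return params


def _render(params: dict, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_height, config.image_width
    # skin-tone background with smooth speckle
    base = np.array([0.86, 0.64, 0.54])
    speckle = ndimage.gaussian_filter(rng.normal(0, 1, size=(h, w)), sigma=max(2, h // 32))
    speckle = 0.04 * speckle / (np.abs(speckle).max() + 1e-9)
    img = np.clip(base[None, None, :] + speckle[:, :, None], 0, 1)

    # lesion mask: perturbed ellipse in rotated coordinates
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = params["cy_frac"] * h, params["cx_frac"] * w
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(params["angle"]), np.sin(params["angle"])
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    r0 = params["radius_frac"] * min(h, w)
    elong = 1.0 + params["asymmetry"]
    theta = np.arctan2(v * elong, u)
    rr = np.sqrt((u / elong) ** 2 + (v * elong) ** 2)
    boundary = r0 * (
        1.0 + params["irregularity"] * np.sin(params["n_lobes"] * theta + params["phase"])
    )
    edge_width = max(1.0, 0.02 * min(h, w))
    blend = np.clip((boundary - rr) / edge_width + 0.5, 0.0, 1.0)  # soft edge

    lesion_color = np.clip(base * (1.0 - params["darkness"]) - 0.1 * params["darkness"], 0, 1)
    img = img * (1 - blend[:, :, None]) + lesion_color[None, None, :] * blend[:, :, None]

    if config.noise_level > 0:
        img = img + rng.normal(0, 0.05 * config.noise_level, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def lesion_border_roughness(params: dict) -> float:
    """Handcrafted feature from generator parameters: a weighted sum of
    border irregularity, darkness, asymmetry and size.  Used as an oracle
    for separability checks, not by any classifier."""
    return (
        params["irregularity"] / 0.3
        + params["darkness"] / 0.6
        + params["asymmetry"] / 0.45
        + params["radius_frac"] / 0.32
    )


def _stratified_splits(n: int, rng: np.random.Generator) -> list[str]:
    """80/10/10 train/val/test assignment for one class, shuffled."""
    n_val = max(1, int(round(0.1 * n))) if n >= 3 else 0
    n_test = max(1, int(round(0.1 * n))) if n >= 3 else 0
    n_train = n - n_val - n_test
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    rng.shuffle(splits)
    return splits


def generate_arrays(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, list[str], list[dict]]:
    """In-memory dataset: (images NHWC float64 in [0,1], labels, splits,
    per-image generator parameters).  Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    labels = np.array([1] * config.n_pos + [0] * config.n_neg, dtype=np.int64)
    split_pos = _stratified_splits(config.n_pos, rng)
    split_neg = _stratified_splits(config.n_neg, rng)
    splits = split_pos + split_neg
    images = np.empty(
        (config.n_pos + config.n_neg, config.image_height, config.image_width, 3)
    )
    all_params = []
    for i, label in enumerate(labels):
        params = _draw_params(int(label), config, rng)
        images[i] = _render(params, config, rng)
        all_params.append(params)
    # shuffle example order so splits/classes are not positionally grouped
    order = rng.permutation(labels.size)
    images = images[order]
    labels = labels[order]
    splits = [splits[i] for i in order]
    all_params = [all_params[i] for i in order]
    return images, labels, splits, all_params


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> Path:
    """Render the dataset to PNG files plus a ``manifest.csv``.

    The manifest has columns ``path,label,split``; a ``config.json`` echo
    records all parameters and the seed.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, labels, splits, _ = generate_arrays(config)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        for i, (label, split) in enumerate(zip(labels, splits)):
            name = f"img_{i:05d}.png"
            Image.fromarray((images[i] * 255).round().astype(np.uint8)).save(out_dir / name)
            writer.writerow([name, int(label), split])
    with open(out_dir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a manifest written by :func:`generate_dataset` back into arrays.

    Returns (images NHWC in [0,1], labels, splits).
    """
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path)
    for col in ("path", "label", "split"):
        if col not in frame.columns:
            raise InvalidInputError(f"manifest missing column {col!r}")
    root = manifest_path.parent
    images = np.stack(
        [np.asarray(Image.open(root / p), dtype=np.float64) / 255.0 for p in frame["path"]]
    )
    return images, frame["label"].to_numpy(np.int64), frame["split"].to_numpy(str)


def mclass_like_benchmark(
    image_height: int = 192, image_width: int = 256, separability: float = 0.8, seed: int = 97,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out 20-positive / 80-negative benchmark set (images, labels),
    generated with an independent seed, mirroring a 100-image dermoscopic
    benchmark with 20% melanoma prevalence."""
    config = SynthConfig(
        n_pos=20, n_neg=80, image_height=image_height, image_width=image_width,
        separability=separability, seed=seed,
    )
    images, labels, _, _ = generate_arrays(config)
    return images, labels


def generate_scores(
    n_pos: int, n_neg: int, auc_target: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Binormal score generator with a prescribed expected AUC.

    Negative raw scores ~ N(0,1), positives ~ N(mu,1) with
    mu = sqrt(2) * Phi^{-1}(auc_target); the binormal identity gives
    P(pos > neg) = Phi(mu / sqrt(2)) = auc_target.  Raw scores are mapped
    through a sigmoid into [0,1], which preserves AUC (strictly monotone).
    """
    if not (0.5 <= auc_target <= 1.0):
        raise InvalidInputError("auc_target must lie in [0.5, 1]")
    if n_pos < 1 or n_neg < 1:
        raise InvalidInputError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    mu = np.sqrt(2.0) * norm.ppf(auc_target)
    raw = np.concatenate([rng.normal(mu, 1.0, n_pos), rng.normal(0.0, 1.0, n_neg)])
    labels = np.concatenate([np.ones(n_pos, dtype=np.int64), np.zeros(n_neg, dtype=np.int64)])
    scores = 1.0 / (1.0 + np.exp(-raw))
    return scores, labels
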