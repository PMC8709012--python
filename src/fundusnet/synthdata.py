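"""Synthetic data with known ground truth: feature tables and fundus phantoms.

Two generators make every downstream stage testable without clinical data:

``generate_feature_table``
    Multi-class Gaussian feature tables in which a known subset of columns
    carries class signal (class means placed on a regular simplex, scaled so
    the closest pair of class means sits ``effect_size`` noise standard
    deviations apart) and the remaining columns are pure noise.

``generate_phantom_images``
    Eight-class retinal phantoms: a dark circular fundus field with an optic
    disc, vessel arcs, and class-specific structures loosely modelled on the
    clinical appearance of each disease (drusen cluster for AMD, global haze
    for cataract, scattered exudates for diabetic retinopathy, an enlarged
    bright disc for glaucoma, tortuous vessels for hypertension, a peripapillary
    crescent for pathological myopia, an irregular grey lesion for "Other").
    These are deliberately cartoonish — separable texture statistics, not
    anatomy — which is exactly what a pipeline test needs.

Both generators are bit-reproducible: one global seed feeds independent
per-stream generators, so adding a stream never perturbs existing outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

CLASS_NAMES = (
    "AMD",
    "Cataract",
    "Diabetes",
    "Glaucoma",
    "Hypertension",
    "Normal",
    "Other",
    "PM",
)

_TABLE_STREAM = 0
_IMAGE_STREAM = 1


class InvalidSpecError(ValueError):
    """Raised when a synthetic-data specification is internally inconsistent."""


@dataclass(frozen=True)
class SynthTableSpec:
    n_samples: int = 500
    n_features: int = 40
    n_informative: int = 8
    n_classes: int = 8
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise InvalidSpecError("n_samples and n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise InvalidSpecError(
                f"n_informative={self.n_informative} must lie in [0, n_features={self.n_features}]"
            )
        if self.n_classes < 2:
            raise InvalidSpecError("n_classes must be at least 2")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise InvalidSpecError("effect_size must be >= 0 and noise_sd > 0")


@dataclass(frozen=True)
class SynthImageSpec:
    n_per_class: int = 10
    class_names: tuple[str, ...] = CLASS_NAMES
    image_size: int = 125
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise InvalidSpecError("n_per_class must be positive")
        if self.image_size < 32:
            raise InvalidSpecError("image_size must be at least 32")
        unknown = [c for c in self.class_names if c not in CLASS_NAMES]
        if unknown:
            raise InvalidSpecError(
                f"unknown class name(s) {unknown}; valid names are {list(CLASS_NAMES)}"
            )
        if len(self.class_names) == 0:
            raise InvalidSpecError("class_names must be non-empty")


def _simplex_coords(n_classes: int) -> np.ndarray:
    """Vertices of a regular simplex, centred, unit pairwise distance, (C, C-1)."""
    E = np.eye(n_classes) - 1.0 / n_classes
    # The centred vertices span a (C-1)-dim subspace; project onto it.
    U, s, _ = np.linalg.svd(E)
    coords = U[:, : n_classes - 1] * s[: n_classes - 1]
    return coords / np.sqrt(2.0)  # pairwise distance of e_i - e_j is sqrt(2)


def class_means(spec: SynthTableSpec) -> np.ndarray:
    """Per-class mean vectors over the informative columns, (C, n_informative).

    Simplex coordinates are tiled cyclically across informative columns and
    rescaled so the minimum pairwise distance equals effect_size * noise_sd.
    """
    if spec.n_informative == 0:
        return np.zeros((spec.n_classes, 0))
    coords = _simplex_coords(spec.n_classes)
    tiled = np.empty((spec.n_classes, spec.n_informative))
    for j in range(spec.n_informative):
        tiled[:, j] = coords[:, j % coords.shape[1]]
    dists = [
        np.linalg.norm(tiled[a] - tiled[b])
        for a in range(spec.n_classes)
        for b in range(a + 1, spec.n_classes)
    ]
    min_dist = min(dists)
    if min_dist == 0:  # degenerate tiling cannot happen for a regular simplex
        raise InvalidSpecError("degenerate class-mean layout")
    return tiled * (spec.effect_size * spec.noise_sd / min_dist)


def generate_feature_table(
    spec: SynthTableSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a labelled feature table with a known informative subset.

    Returns ``(X, y, informative_mask)``: an (n, p) float matrix, integer
    class labels 0..C-1 balanced within one sample, and a boolean mask over
    columns marking which carry class signal.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, _TABLE_STREAM])
    n, p, C = spec.n_samples, spec.n_features, spec.n_classes

    base = n // C
    counts = np.full(C, base)
    counts[: n - base * C] += 1
    y = np.repeat(np.arange(C), counts)
    rng.shuffle(y)

    X = rng.normal(0.0, spec.noise_sd, size=(n, p))
    mask = np.zeros(p, dtype=bool)
    mask[: spec.n_informative] = True
    if spec.n_informative > 0:
        means = class_means(spec)
        X[:, mask] += means[y]
    return X, y, mask


# --------------------------------------------------------------------------
# Phantom fundus images
# --------------------------------------------------------------------------


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.arange(size, dtype=float)
    return np.meshgrid(c, c, indexing="ij")


def _disk(yy, xx, cy, cx, r) -> np.ndarray:
    return ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r


def _blob(yy, xx, cy, cx, r) -> np.ndarray:
    """Soft Gaussian bump with scale r, peak 1."""
    return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * r * r)))


def _add_color(img, mask_or_field, color, gain=1.0):
    for ch in range(3):
        img[..., ch] += gain * color[ch] * mask_or_field


def _draw_vessel(img, size, rng, start, angle, tortuosity, width, n_points=400):
    """One vessel arc: a jittered sine path from the disc toward the periphery."""
    yy0, xx0 = start
    length = 0.9 * size
    t = np.linspace(0, 1, n_points)
    amp = tortuosity * size
    freq = rng.uniform(2.0, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    ys = yy0 + length * t * np.sin(angle) + amp * np.sin(2 * np.pi * freq * t + phase) * np.cos(angle)
    xs = xx0 + length * t * np.cos(angle) - amp * np.sin(2 * np.pi * freq * t + phase) * np.sin(angle)
    ok = (ys >= 0) & (ys < size) & (xs >= 0) & (xs < size)
    ys, xs = ys[ok].astype(int), xs[ok].astype(int)
    w = max(1, int(round(width)))
    dark = np.array([0.45, 0.10, 0.08])
    for dy in range(-w, w + 1):
        for dx in range(-w, w + 1):
            yy = np.clip(ys + dy, 0, size - 1)
            xx = np.clip(xs + dx, 0, size - 1)
            img[yy, xx, 0] = np.minimum(img[yy, xx, 0], dark[0])
            img[yy, xx, 1] = np.minimum(img[yy, xx, 1], dark[1])
            img[yy, xx, 2] = np.minimum(img[yy, xx, 2], dark[2])


def _render_phantom(class_name: str, size: int, rng: np.random.Generator) -> np.ndarray:
    s = float(size)
    yy, xx = _grid(size)
    cy = cx = s / 2.0
    field_r = 0.48 * s

    img = np.zeros((size, size, 3))
    field = _disk(yy, xx, cy, cx, field_r)
    # reddish fundus base with a gentle radial falloff
    radial = 1.0 - 0.5 * np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / field_r
    base = np.array([0.72, 0.32, 0.18]) * (0.85 + 0.1 * rng.uniform())
    for ch in range(3):
        img[..., ch] = np.where(field, base[ch] * radial, 0.02)

    # optic disc: bright blob offset to one side
    disc_x = cx + (0.26 + 0.03 * rng.uniform()) * s * rng.choice([-1.0, 1.0])
    disc_y = cy + 0.05 * s * rng.uniform(-1, 1)
    disc_r = 0.055 * s
    disc_gain, cup = 0.9, 0.0
    n_vessels, tortuosity, width = 4, 0.01, 0.008 * s

    if class_name == "Glaucoma":
        disc_r = 0.12 * s * (1.0 + 0.1 * rng.uniform())   # enlarged, bright disc/cup
        disc_gain, cup = 1.3, 0.8
    elif class_name == "Hypertension":
        n_vessels, tortuosity, width = 7, 0.045, 0.012 * s  # crowded, tortuous vessels

    for k in range(n_vessels):
        ang = 2 * np.pi * (k / n_vessels) + rng.uniform(-0.25, 0.25)
        _draw_vessel(img, size, rng, (disc_y, disc_x), ang, tortuosity, width)

    _add_color(img, _blob(yy, xx, disc_y, disc_x, disc_r), (1.0, 0.9, 0.55), disc_gain)
    if cup > 0:
        _add_color(img, _blob(yy, xx, disc_y, disc_x, 0.5 * disc_r), (1.0, 1.0, 0.8), cup)

    if class_name == "AMD":
        # drusen: a tight cluster of yellow dots around the macula (centre)
        for _ in range(10):
            by = cy + 0.09 * s * rng.normal()
            bx = cx + 0.09 * s * rng.normal()
            _add_color(img, _blob(yy, xx, by, bx, 0.018 * s), (0.95, 0.85, 0.3), 0.9)
    elif class_name == "Diabetes":
        # hard exudates scattered over the field + a few dark haemorrhage dots
        for _ in range(14):
            ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0.1, 0.85) * field_r
            by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            _add_color(img, _blob(yy, xx, by, bx, 0.013 * s), (1.0, 0.95, 0.5), 1.0)
        for _ in range(5):
            ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0.1, 0.8) * field_r
            by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            _add_color(img, _blob(yy, xx, by, bx, 0.016 * s), (-0.6, -0.25, -0.12), 1.0)
    elif class_name == "Other":
        # one large irregular greyish lesion
        ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0.15, 0.55) * field_r
        ly, lx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        lesion = _blob(yy, xx, ly, lx, 0.09 * s * (1 + 0.3 * rng.uniform()))
        lesion *= 1.0 + 0.35 * np.sin(0.25 * yy + rng.uniform(0, 6)) * np.sin(0.25 * xx)
        _add_color(img, np.clip(lesion, 0, None), (0.35, 0.38, 0.36), 0.9)
    elif class_name == "PM":
        # pale peripapillary crescent beside the disc + tessellated pallor
        shift = 1.2 * disc_r * np.sign(disc_x - cx)
        crescent = _blob(yy, xx, disc_y, disc_x + shift, 1.6 * disc_r)
        crescent *= 1.0 - _blob(yy, xx, disc_y, disc_x, 1.1 * disc_r)
        _add_color(img, crescent, (0.9, 0.85, 0.75), 1.1)
        img[field] = img[field] * 0.85 + 0.12  # washed-out fundus

    if class_name == "Cataract":
        # media opacity: heavy blur + milky veil over everything
        from scipy.ndimage import gaussian_filter

        for ch in range(3):
            img[..., ch] = gaussian_filter(img[..., ch], sigma=0.03 * s)
        img = 0.55 * img + 0.38

    img += rng.normal(0.0, 0.02, size=img.shape)  # sensor noise
    return np.clip(img, 0.0, 1.0)


def generate_phantom_images(spec: SynthImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom image set.

    Returns ``(images, labels)``: an (N, size, size, 3) float array with
    values in [0, 1] and an array of class-name strings, N = n_per_class
    per listed class, grouped by class in the listed order.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, _IMAGE_STREAM])
    images, labels = [], []
    for name in spec.class_names:
        for _ in range(spec.n_per_class):
            images.append(_render_phantom(name, spec.image_size, rng))
            labels.append(name)
    return np.stack(images), np.asarray(labels)


# --------------------------------------------------------------------------
# On-disk formats: CSV feature tables, directory-per-class PNG image sets
# --------------------------------------------------------------------------


def save_feature_table(path: str | Path, X: np.ndarray, y: np.ndarray) -> None:
    """Write an (n, p) table and labels as CSV with header f1..fp,label."""
    X = np.asarray(X)
    df = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(X.shape[1])])
    df["label"] = np.asarray(y)
    df.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature CSV must contain a 'label' column")
    if not all(re.fullmatch(r"f\d+", c) for c in df.columns if c != "label"):
        raise ValueError(f"{path}: feature columns must be named f1..fp")
    y = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), y


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    pd.DataFrame({"keep": np.asarray(mask).astype(int)}).to_csv(path, index=False)


def load_mask(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["keep"].to_numpy().astype(bool)


def save_image_set(root: str | Path, images: np.ndarray, labels: np.ndarray) -> None:
    """Write images as 8-bit PNGs under <root>/<class_name>/<index>.png."""
    root = Path(root)
    counters: dict[str, int] = {}
    for img, label in zip(images, labels):
        d = root / str(label)
        d.mkdir(parents=True, exist_ok=True)
        idx = counters.get(label, 0)
        counters[label] = idx + 1
        arr = np.clip(np.asarray(img) * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(d / f"{idx}.png")


def load_image_set(root: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a directory-per-class image set back as float arrays in [0, 1]."""
    root = Path(root)
    images, labels = [], []
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    for d in class_dirs:
        for f in sorted(d.glob("*.png")) + sorted(d.glob("*.jpg")):
            images.append(np.asarray(Image.open(f).convert("RGB"), dtype=float) / 255.0)
            labels.append(d.name)
    return np.stack(images), np.asarray(labels)
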