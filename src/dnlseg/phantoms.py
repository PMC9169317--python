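"""Seeded curvilinear vessel phantoms with exact paired masks.

Each phantom is a set of smooth random curves (splines through jittered
waypoints) rasterised and dilated to a sampled width; the mask is the exact
union of the strokes, and the image is a two-level intensity map optionally
Gaussian-blurred and corrupted with Gaussian noise.  Two named presets
emulate the statistical shape of the real modalities the network targets:
a CTA-style slice (bright thin vessels on a dark background) and a
fundus-style patch (low-contrast vessels on a dark background).

Because the masks are exact by construction, a perfect predictor scores 1.0
on every metric — the generator doubles as the oracle for the evaluation
stack.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import interpolate as _interp
from scipy import ndimage as _ndi
from skimage import morphology as _skmorph

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "cta_preset", "fundus_preset", "write_dataset", "read_dataset"]

_MAX_FOREGROUND = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic vessel image.

    ``tortuosity`` scales the perpendicular waypoint jitter relative to the
    curve length; intensities are in [0, 1]; ``noise_sigma`` is the std of
    additive Gaussian noise applied after blurring.
    """
    size: tuple[int, int] = (64, 64)
    n_vessels: int = 4
    width_range: tuple[int, int] = (1, 3)
    tortuosity: float = 0.15
    vessel_intensity: float = 0.8
    background_intensity: float = 0.15
    noise_sigma: float = 0.05
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if self.width_range[1] > min(h, w) / 4:
            raise ValueError(
                f"max vessel width {self.width_range[1]} exceeds "
                f"min(H, W)/4 = {min(h, w) / 4:.1f}")
        if self.tortuosity < 0 or self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("tortuosity/noise_sigma/blur_sigma must be >= 0")


def cta_preset(size: tuple[int, int] = (512, 512), seed: int = 0,
               **overrides) -> PhantomSpec:
    """Bright vessels on a dark background, CTA-slice style."""
    base = PhantomSpec(size=size, n_vessels=max(size[0] // 16, 3),
                       width_range=(1, max(size[0] // 128, 3)),
                       vessel_intensity=0.7, background_intensity=0.25,
                       noise_sigma=0.12, blur_sigma=0.9, seed=seed)
    return replace(base, **overrides)


def fundus_preset(size: tuple[int, int] = (96, 96), seed: int = 0,
                  **overrides) -> PhantomSpec:
    """Low-contrast vessels on a dark background, fundus-patch style."""
    base = PhantomSpec(size=size, n_vessels=5, width_range=(1, 3),
                       vessel_intensity=0.45, background_intensity=0.25,
                       noise_sigma=0.03, blur_sigma=0.9, seed=seed)
    return replace(base, **overrides)


def _vessel_stroke(rng: np.random.Generator, h: int, w: int,
                   tortuosity: float) -> np.ndarray:
    """Boolean raster of one smooth curve spanning the image."""
    # endpoints on opposite-ish borders
    if rng.random() < 0.5:
        p0 = np.array([rng.uniform(0, h - 1), 0.0])
        p1 = np.array([rng.uniform(0, h - 1), w - 1.0])
    else:
        p0 = np.array([0.0, rng.uniform(0, w - 1)])
        p1 = np.array([h - 1.0, rng.uniform(0, w - 1)])
    n_way = 5
    ts = np.linspace(0, 1, n_way)
    base = p0[None] * (1 - ts[:, None]) + p1[None] * ts[:, None]
    length = float(np.linalg.norm(p1 - p0))
    direction = (p1 - p0) / (length + 1e-9)
    normal = np.array([-direction[1], direction[0]])
    jitter = rng.normal(0.0, tortuosity * length, size=n_way)
    jitter[0] = jitter[-1] = 0.0
    pts = base + jitter[:, None] * normal[None]
    tck, _ = _interp.splprep([pts[:, 0], pts[:, 1]], s=0, k=3)
    dense = np.linspace(0, 1, int(4 * max(length, 8)))
    ys, xs = _interp.splev(dense, tck)
    ys = np.clip(np.round(ys).astype(int), 0, h - 1)
    xs = np.clip(np.round(xs).astype(int), 0, w - 1)
    stroke = np.zeros((h, w), dtype=bool)
    stroke[ys, xs] = True
    return stroke


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (image, mask): float64 image in [0, 1] and uint8 binary mask.

    Fully deterministic for a given spec (including its seed).
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((h, w), dtype=bool)
    budget = _MAX_FOREGROUND * h * w
    for _ in range(spec.n_vessels):
        width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        stroke = _vessel_stroke(rng, h, w, spec.tortuosity)
        radius = width // 2
        if radius:
            stroke = _skmorph.dilation(stroke, _skmorph.disk(radius))
        if (mask | stroke).sum() > budget:
            break
        mask |= stroke
    if not mask.any():
        # degenerate draw (possible only for adversarial specs): one
        # deterministic straight centre line
        mask[h // 2, :] = True
    image = np.where(mask, spec.vessel_intensity, spec.background_intensity)
    image = image.astype(np.float64)
    if spec.blur_sigma > 0:
        image = _ndi.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask.astype(np.uint8)


def generate_dataset(n: int, spec: PhantomSpec, seed: int
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """n independent phantoms from per-item seeds derived from `seed`."""
    if n <= 0:
        return []
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [generate_phantom(replace(spec, seed=int(s))) for s in child_seeds]


# --------------------------------------------------------------------------
# On-disk layout consumed by the training CLI
# --------------------------------------------------------------------------

def write_dataset(pairs, spec: PhantomSpec, seed: int, out_dir) -> Path:
    """Write image/mask PNG pairs plus a manifest CSV; returns the directory."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["index", "image", "mask", "seed", "spec"])
    child_seeds = np.random.SeedSequence(seed).generate_state(len(pairs)) % (2 ** 31)
    for i, (img, msk) in enumerate(pairs):
        img_name = f"images/{i:05d}.png"
        msk_name = f"masks/{i:05d}.png"
        iio.imwrite(out / img_name,
                    np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16))
        iio.imwrite(out / msk_name, (msk * 255).astype(np.uint8))
        writer.writerow([i, img_name, msk_name, int(child_seeds[i]), repr(spec)])
    (out / "manifest.csv").write_text(buf.getvalue())
    return out


def read_dataset(data_dir) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load image/mask pairs written by `write_dataset` (or any directory
    with parallel images/ and masks/ subfolders)."""
    import imageio.v3 as iio

    data = Path(data_dir)
    images = sorted((data / "images").iterdir())
    masks = sorted((data / "masks").iterdir())
    if len(images) != len(masks):
        raise ValueError(f"{data}: {len(images)} images vs {len(masks)} masks")
    pairs = []
    for ipath, mpath in zip(images, masks):
        img = np.asarray(iio.imread(ipath), dtype=np.float64)
        img /= float(np.iinfo(np.uint16).max if img.max() > 255 else 255) \
            if img.max() > 1 else 1.0
        msk = (np.asarray(iio.imread(mpath)) > 127).astype(np.uint8)
        pairs.append((img, msk))
    return pairs
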