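"""Palette-mask I/O, synthetic scene generation, augmentation and splits.

The segmentation task has four classes annotated with a fixed RGB
palette: background [0,0,0], rice grains [128,128,128], stems [0,128,0]
and branches [128,0,0].  The real corpus (harvester sampling-box
photographs) is not redistributable, so :func:`generate_scene` emulates
its structure: a textured background littered with many small
ellipse-shaped grains, a few elongated curved stems and branched
structures, with occlusion and adhesion between shapes.  Everything is
deterministic per (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PALETTE", "CLASS_NAMES", "NUM_CLASSES", "SceneConfig", "DatasetSplit",
    "encode_mask", "decode_mask", "save_mask_png", "load_mask_png",
    "load_index_mask_png", "generate_scene", "generate_dataset", "augment",
    "split_dataset", "corpus_statistics", "normalize_images",
]

NUM_CLASSES = 4
CLASS_NAMES = ("background", "rice", "stem", "branch")
#: class index -> RGB triplet
PALETTE = np.array(
    [[0, 0, 0], [128, 128, 128], [0, 128, 0], [128, 0, 0]], dtype=np.uint8
)


# -- palette codec ------------------------------------------------------------

def encode_mask(mask: np.ndarray) -> np.ndarray:
    """Class-index map (H, W) -> RGB image (H, W, 3) via the fixed palette."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= NUM_CLASSES:
        bad = sorted(set(np.unique(mask)) - set(range(NUM_CLASSES)))
        raise ValueError(f"mask contains non-class values: {bad}")
    return PALETTE[mask]


def decode_mask(rgb: np.ndarray) -> np.ndarray:
    """RGB mask image -> class-index map; rejects off-palette pixels."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got {rgb.shape}")
    code = (rgb[..., 0].astype(np.int32) << 16) | (rgb[..., 1].astype(np.int32) << 8) | rgb[..., 2]
    pcodes = (PALETTE[:, 0].astype(np.int32) << 16) | (PALETTE[:, 1].astype(np.int32) << 8) | PALETTE[:, 2]
    out = np.full(code.shape, -1, dtype=np.int64)
    for idx, pc in enumerate(pcodes):
        out[code == pc] = idx
    if (out < 0).any():
        bad = np.unique(rgb.reshape(-1, 3)[(out < 0).ravel()], axis=0)
        raise ValueError(f"off-palette pixel values: {[tuple(b) for b in bad[:10]]}")
    return out


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(encode_mask(mask)).save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    return decode_mask(np.asarray(Image.open(path).convert("RGB")))


def load_index_mask_png(path: str | Path) -> np.ndarray:
    """Convenience reader for palette-indexed (mode "P") PNG masks."""
    img = Image.open(path)
    arr = np.asarray(img)
    if img.mode == "P":
        if arr.max() >= NUM_CLASSES:
            raise ValueError(f"index mask contains labels >= {NUM_CLASSES}")
        return arr.astype(np.int64)
    return decode_mask(np.asarray(img.convert("RGB")))


# -- synthetic scenes ---------------------------------------------------------

@dataclass
class SceneConfig:
    """Geometry and appearance ranges of a synthetic harvest-sample scene.

    Defaults emulate the photographed sampling-box scenes at 512x512:
    dozens of small rice grains (ellipse axes a few-to-twenty pixels),
    a handful of long thin stems and branched impurities, with later
    shapes occluding earlier ones.
    """

    image_size: tuple[int, int] = (512, 512)  # (H, W)
    grain_count: tuple[int, int] = (40, 90)
    grain_axes: tuple[int, int] = (5, 14)      # semi-axes range, px
    stem_count: tuple[int, int] = (2, 6)
    stem_length: tuple[int, int] = (120, 380)
    stem_width: tuple[int, int] = (5, 12)
    branch_count: tuple[int, int] = (1, 4)
    branch_degree: tuple[int, int] = (2, 5)    # side shoots per branch
    overlap: float = 0.5                       # cluster-attraction probability
    color_jitter: float = 18.0                 # per-shape RGB jitter (std)
    noise_level: float = 7.0                   # additive pixel noise (std)

    def __post_init__(self):
        h, w = self.image_size
        for name in ("grain_count", "grain_axes", "stem_count", "stem_length",
                     "stem_width", "branch_count", "branch_degree"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if 2 * self.grain_axes[1] > min(h, w) or self.stem_width[1] > min(h, w):
            raise ValueError("shape larger than image")


_BASE_COLORS = {
    1: np.array([208.0, 188.0, 142.0]),  # pale tan rice grain
    2: np.array([150.0, 158.0, 82.0]),   # green-yellow stem
    3: np.array([122.0, 84.0, 46.0]),    # brown branch
}


def _draw_ellipse(image, mask, cy, cx, a, b, theta, color, label, rng, jitter):
    h, w = mask.shape
    r = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():
        return
    shade = 1.0 - 0.35 * np.abs(u / a)  # lengthwise shading
    px = color[None, None, :] * shade[..., None]
    px = px + rng.normal(0.0, jitter * 0.4, size=px.shape)
    region = image[y0:y1, x0:x1]
    region[inside] = np.clip(px[inside], 0, 255)
    mask[y0:y1, x0:x1][inside] = label


def _draw_path(image, mask, pts, width, color, label, rng, jitter):
    """Stamp discs along a polyline; crude but fully deterministic."""
    radius = max(1, width // 2)
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        steps = max(2, int(np.hypot(y1 - y0, x1 - x0)))
        for t in np.linspace(0.0, 1.0, steps):
            cy, cx = y0 + t * (y1 - y0), x0 + t * (x1 - x0)
            _draw_ellipse(image, mask, int(round(cy)), int(round(cx)),
                          radius, radius, 0.0, color, label, rng, jitter)


def _stem_points(rng, h, w, length, segments=4):
    y = rng.uniform(0, h)
    x = rng.uniform(0, w)
    ang = rng.uniform(0, 2 * np.pi)
    pts = [(y, x)]
    step = length / segments
    for _ in range(segments):
        ang += rng.normal(0.0, 0.25)  # gentle curvature
        y += step * np.sin(ang)
        x += step * np.cos(ang)
        pts.append((y, x))
    return pts


def generate_scene(cfg: SceneConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic scene: (uint8 RGB image HxWx3, class-index mask HxW).

    Shapes are painted stems -> branches -> grains, so grains lie on top
    (as in a sampling box); within a family, later shapes occlude earlier
    ones and the mask always records the visible class.
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    base = np.array([46.0, 40.0, 33.0])
    image = base[None, None, :] + rng.normal(0.0, 12.0, size=(h, w, 3))
    image = gaussian_filter(image, sigma=(3, 3, 0))  # soft background texture
    mask = np.zeros((h, w), dtype=np.int64)

    jit = cfg.color_jitter

    def shape_color(label):
        return np.clip(_BASE_COLORS[label] + rng.normal(0.0, jit, 3), 0, 255)

    for _ in range(rng.integers(cfg.stem_count[0], cfg.stem_count[1] + 1)):
        length = rng.uniform(*cfg.stem_length)
        width = int(rng.integers(cfg.stem_width[0], cfg.stem_width[1] + 1))
        _draw_path(image, mask, _stem_points(rng, h, w, length),
                   width, shape_color(2), 2, rng, jit)

    for _ in range(rng.integers(cfg.branch_count[0], cfg.branch_count[1] + 1)):
        length = rng.uniform(*cfg.stem_length) * 0.6
        width = int(rng.integers(cfg.stem_width[0], cfg.stem_width[1] + 1))
        main = _stem_points(rng, h, w, length, segments=3)
        color = shape_color(3)
        _draw_path(image, mask, main, width, color, 3, rng, jit)
        for _ in range(rng.integers(cfg.branch_degree[0], cfg.branch_degree[1] + 1)):
            iy, ix = main[rng.integers(0, len(main))]
            ang = rng.uniform(0, 2 * np.pi)
            slen = length * rng.uniform(0.25, 0.5)
            shoot = [(iy, ix), (iy + slen * np.sin(ang), ix + slen * np.cos(ang))]
            _draw_path(image, mask, shoot, max(2, width - 2), color, 3, rng, jit)

    n_grain = rng.integers(cfg.grain_count[0], cfg.grain_count[1] + 1)
    anchor = None
    for _ in range(n_grain):
        if anchor is not None and rng.random() < cfg.overlap:
            cy = int(np.clip(anchor[0] + rng.normal(0, 3 * cfg.grain_axes[1]), 0, h - 1))
            cx = int(np.clip(anchor[1] + rng.normal(0, 3 * cfg.grain_axes[1]), 0, w - 1))
        else:
            cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
        anchor = (cy, cx)
        a = rng.uniform(cfg.grain_axes[0], cfg.grain_axes[1])
        b = a * rng.uniform(0.35, 0.55)  # rice grains are elongated
        _draw_ellipse(image, mask, cy, cx, a, b, rng.uniform(0, np.pi),
                      shape_color(1), 1, rng, jit)

    image = image + rng.normal(0.0, cfg.noise_level, size=image.shape)
    return np.clip(image, 0, 255).astype(np.uint8), mask


def generate_dataset(n: int, cfg: SceneConfig | None = None, seed: int = 0,
                     out_dir: str | Path | None = None):
    """Generate ``n`` scenes; optionally write image/mask PNG pairs + manifest.

    Returns (images, masks) as lists of arrays.  Scene i uses a seed
    derived deterministically from (seed, i).
    """
    cfg = cfg or SceneConfig()
    images, masks = [], []
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n)]
    for i in range(n):
        img, msk = generate_scene(cfg, child_seeds[i])
        images.append(img)
        masks.append(msk)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        lines = []
        for i, (img, msk) in enumerate(zip(images, masks)):
            ipath = out / "images" / f"scene_{i:05d}.png"
            mpath = out / "masks" / f"scene_{i:05d}.png"
            Image.fromarray(img).save(ipath)
            save_mask_png(msk, mpath)
            lines.append(f"{ipath}\t{mpath}")
        (out / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return images, masks


# -- augmentation -------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, seed: int, prob: float = 0.5,
            geometric: bool = True, photometric: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Training-time augmentation.

    Geometric transforms (horizontal/vertical flips) are applied to the
    image and mask together; photometric transforms (contrast,
    brightness, Gaussian blur, grayscale) touch the image only.  Each
    transform fires independently with probability ``prob``; the two
    families can be toggled separately.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask spatial shapes differ")
    rng = np.random.default_rng(seed)
    img = image.astype(np.float64)
    msk = mask.copy()
    if geometric:
        if rng.random() < prob:  # horizontal flip
            img = img[:, ::-1]
            msk = msk[:, ::-1]
        if rng.random() < prob:  # vertical flip
            img = img[::-1]
            msk = msk[::-1]
    if photometric:
        if rng.random() < prob:  # contrast
            f = rng.uniform(0.7, 1.4)
            img = (img - img.mean(axis=(0, 1))) * f + img.mean(axis=(0, 1))
        if rng.random() < prob:  # brightness
            img = img * rng.uniform(0.7, 1.4)
        if rng.random() < prob:  # Gaussian blur
            img = gaussian_filter(img, sigma=(rng.uniform(0.5, 1.5),) * 2 + (0,))
        if rng.random() < prob:  # grayscale
            gray = img @ np.array([0.299, 0.587, 0.114])
            img = np.repeat(gray[..., None], 3, axis=-1)
    return np.clip(img, 0, 255).astype(np.uint8), np.ascontiguousarray(msk)


# -- splits & normalization ---------------------------------------------------

@dataclass
class DatasetSplit:
    train: list[int]
    val: list[int]
    test: list[int]


def split_dataset(n: int, seed: int = 0) -> DatasetSplit:
    """Shuffled 8:1:1 split; val and test get floor(n/10), remainder to train."""
    if n < 10:
        raise ValueError(f"need at least 10 items for an 8:1:1 split, got {n}")
    k = n // 10
    order = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(
        train=sorted(int(i) for i in order[2 * k:]),
        val=sorted(int(i) for i in order[:k]),
        test=sorted(int(i) for i in order[k:2 * k]),
    )


def corpus_statistics(images) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std (0-255 scale) over a list of HxWx3 images."""
    stack = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return stack.mean(axis=(0, 1, 2)), stack.std(axis=(0, 1, 2)) + 1e-8


def normalize_images(images, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 images -> normalized float32 batch (B, 3, H, W)."""
    if isinstance(images, np.ndarray):
        batch = images.astype(np.float32)
        if batch.ndim == 3:
            batch = batch[None]
    else:
        batch = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    batch = (batch - mean.astype(np.float32)) / std.astype(np.float32)
    return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))
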