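"""Synthetic wound-image generator with exact ground-truth masks.

Real clinical wound photographs are heterogeneous: several consumer
cameras, uncontrolled illumination and exposure, and highly variable
backgrounds.  This module emulates that statistical structure — not
photorealism — so every stage of the training pipeline can be exercised
reproducibly with no downloads:

* a *wound* is a single connected reddish blob (union of 1-3 overlapping
  ellipses, smoothed) composited onto a textured background drawn from
  skin-like, fabric-like or flat-colour families;
* *lighting* variability is a per-image global gain and gamma;
* a *difficulty knob*: a configurable fraction of "hard" samples carry
  small wound-coloured *distractor* spots in the background, of graded
  strength.  A model that has not learned to suppress them predicts
  spurious foreground components and the mask is rejected outright;
  suppression is learnable from position and size cues.  Hard samples
  are what a source-domain model initially fails on, which is what
  gives the active semi-supervised loop room to grow;
* two *style families*: ``target`` (the working dataset) and ``base``
  (a disjoint source-domain look used to pre-train models, standing in
  for transfer learning from an external dataset).

Everything is a pure function of the config, including the seed: the same
``SyntheticConfig`` always produces byte-identical pixels and masks.

``corrupt_mask`` produces systematically wrong masks (under-coverage,
holes, spurious components, boundary jitter) for testing the acceptance
criteria of the validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "ImageSample",
    "CorruptionSpec",
    "generate_dataset",
    "generate_pretraining_set",
    "corrupt_mask",
]

_CAMERA_TAGS = ("phone-a", "phone-b", "phone-c", "compact-cam")

_STYLES = ("target", "base")

_CORRUPTION_MODES = ("under_coverage", "holes", "spurious", "boundary_jitter")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    n_images : int
        Number of samples to generate.
    image_size : int
        Side of the square output raster, pixels.
    wound_area_fraction_range : (float, float)
        Every ground-truth mask's foreground fraction falls in this open
        interval of (0, 1).
    background_palette : tuple of str
        Background texture families to draw from, subset of
        {"skin", "fabric", "flat"}.
    lighting_gain_range, lighting_gamma_range : (float, float)
        Per-image multiplicative gain and gamma exponent ranges.
    hard_fraction : float
        Fraction of samples rendered with background distractors.
    distractor_strength_range : (float, float)
        For hard samples, how far the distractor spots' colour is pulled
        from the local background toward the wound colour (0 = invisible,
        1 = full wound colour).  The wound itself stays untouched, so
        difficulty is binary per image — a model either suppresses the
        distractors or predicts spurious components — and accepted masks
        stay crisp.
    style : str
        "target" (default) or "base"; the base family uses a disjoint
        colour regime and serves as the source domain for pre-training.
    seed : int
        Root seed; per-sample streams are derived from (seed, index).
    """

    n_images: int
    image_size: int = 64
    wound_area_fraction_range: tuple[float, float] = (0.06, 0.25)
    background_palette: tuple[str, ...] = ("skin", "fabric", "flat")
    lighting_gain_range: tuple[float, float] = (0.75, 1.25)
    lighting_gamma_range: tuple[float, float] = (0.8, 1.25)
    hard_fraction: float = 0.5
    distractor_strength_range: tuple[float, float] = (0.3, 1.0)
    style: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.wound_area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                f"wound_area_fraction_range must satisfy 0 < lo < hi < 1, got {(lo, hi)}"
            )
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not (0.0 <= self.hard_fraction <= 1.0):
            raise ValueError("hard_fraction must be in [0, 1]")
        if self.style not in _STYLES:
            raise ValueError(f"style must be one of {_STYLES}, got {self.style!r}")
        unknown = set(self.background_palette) - {"skin", "fabric", "flat"}
        if unknown:
            raise ValueError(f"unknown background families: {sorted(unknown)}")


@dataclass
class ImageSample:
    """An RGB image with optional ground-truth mask and provenance."""

    sample_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    truth_mask: np.ndarray | None = None  # H x W, uint8 {0,1}
    camera_tag: str = ""
    hard: bool = False
    hard_degree: float = 0.0  # distractor strength, 0 if easy

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.truth_mask is not None and self.truth_mask.shape != self.pixels.shape[:2]:
            raise ValueError(
                f"mask shape {self.truth_mask.shape} != image shape {self.pixels.shape[:2]}"
            )


@dataclass(frozen=True)
class CorruptionSpec:
    """One way of damaging a mask, with a severity dial in [0, 1]."""

    mode: str
    severity: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")


# ---------------------------------------------------------------------------
# wound shape


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _wound_shape(rng: np.random.Generator, size: int, lo: float, hi: float) -> np.ndarray:
    """Single-connected-component blob with area fraction in [lo, hi]."""
    target = rng.uniform(lo, hi)
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    aspect = rng.uniform(0.55, 1.0)
    theta0 = rng.uniform(0, np.pi)
    # main ellipse plus 0-2 smaller satellites whose centres sit inside it,
    # so the union is always one connected component
    n_extra = rng.integers(0, 3)
    extras = [
        (rng.uniform(0, 2 * np.pi), rng.uniform(0.3, 0.8), rng.uniform(0.35, 0.6),
         rng.uniform(0.5, 1.0), rng.uniform(0, np.pi))
        for _ in range(n_extra)
    ]
    scale = np.sqrt(target * size * size / np.pi)
    for _ in range(10):
        a0 = min(scale / np.sqrt(aspect), 0.44 * size)
        b0 = min(scale * np.sqrt(aspect), 0.44 * size)
        mask = _ellipse_mask(size, cy, cx, a0, b0, theta0)
        for ang, rad_frac, size_frac, asp, th in extras:
            ecy = cy + rad_frac * b0 * np.sin(ang)
            ecx = cx + rad_frac * a0 * np.cos(ang)
            ea = max(size_frac * a0 / np.sqrt(asp), 1.5)
            eb = max(size_frac * b0 * np.sqrt(asp), 1.5)
            mask |= _ellipse_mask(size, ecy, ecx, ea, eb, th)
        smooth = ndimage.gaussian_filter(mask.astype(np.float64), sigma=size / 48.0)
        mask = smooth > 0.5
        frac = mask.mean()
        if lo <= frac <= hi and ndimage.label(mask)[1] == 1:
            return mask
        if frac <= 0:
            scale *= 1.5
        else:
            scale *= np.sqrt(target / frac)
    raise RuntimeError("wound shape generation failed to converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# appearance


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=sigma)
    sd = n.std()
    return n / sd if sd > 0 else n


def _background(rng: np.random.Generator, size: int, family: str, style: str) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float64)
    if family == "skin":
        base = (
            np.array([205.0, 165.0, 135.0]) if style == "target" else np.array([190.0, 150.0, 115.0])
        ) + rng.uniform(-25, 25, size=3)
        tex = _smooth_noise(rng, size, sigma=3.0)
        grad = np.linspace(-1, 1, size)[:, None] * rng.uniform(-10, 10)
        for c in range(3):
            img[..., c] = base[c] + 12.0 * tex + grad
    elif family == "fabric":
        if style == "target":
            base = np.array([rng.uniform(60, 140), rng.uniform(90, 170), rng.uniform(110, 200)])
        else:
            base = np.array([rng.uniform(90, 180), rng.uniform(90, 180), rng.uniform(60, 120)])
        angle = rng.uniform(0, np.pi)
        freq = rng.uniform(0.2, 0.7)
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        stripes = np.sin(freq * (xx * np.cos(angle) + yy * np.sin(angle)))
        tex = _smooth_noise(rng, size, sigma=1.5)
        for c in range(3):
            img[..., c] = base[c] + 18.0 * stripes + 6.0 * tex
    else:  # flat
        base = rng.uniform(70, 200, size=3)
        tex = _smooth_noise(rng, size, sigma=2.0)
        for c in range(3):
            img[..., c] = base[c] + 4.0 * tex
    return img


def _wound_texture(rng: np.random.Generator, size: int, style: str) -> np.ndarray:
    if style == "target":
        base = np.array([rng.uniform(140, 195), rng.uniform(25, 60), rng.uniform(30, 65)])
    else:
        base = np.array([rng.uniform(160, 210), rng.uniform(40, 80), rng.uniform(50, 90)])
    tex = _smooth_noise(rng, size, sigma=2.0)
    img = np.empty((size, size, 3), dtype=np.float64)
    for c in range(3):
        img[..., c] = base[c] + 14.0 * tex * (1.0 if c == 0 else 0.6)
    return img


def _render_sample(cfg: SyntheticConfig, index: int) -> ImageSample:
    rng = np.random.default_rng([cfg.seed, index, _STYLES.index(cfg.style)])
    size = cfg.image_size
    lo, hi = cfg.wound_area_fraction_range

    mask = _wound_shape(rng, size, lo, hi)
    family = cfg.background_palette[rng.integers(0, len(cfg.background_palette))]
    bg = _background(rng, size, family, cfg.style)
    wound = _wound_texture(rng, size, cfg.style)

    # soft-edged compositing so the wound boundary is not a hard step
    alpha = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.0)[..., None]
    img = bg * (1.0 - alpha) + wound * alpha

    hard = bool(rng.random() < cfg.hard_fraction)
    nu = 0.0
    if hard:
        nu = rng.uniform(*cfg.distractor_strength_range)
        img = _add_distractors(rng, img, wound, mask, nu)

    gain = rng.uniform(*cfg.lighting_gain_range)
    gamma = rng.uniform(*cfg.lighting_gamma_range)
    img = 255.0 * np.clip(gain * img / 255.0, 0.0, 1.0) ** gamma
    img = img + rng.normal(0.0, 2.5, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    tag = _CAMERA_TAGS[rng.integers(0, len(_CAMERA_TAGS))]
    return ImageSample(
        sample_id=f"{cfg.style}-{index:04d}",
        pixels=pixels,
        truth_mask=mask.astype(np.uint8),
        camera_tag=tag,
        hard=hard,
        hard_degree=nu,
    )


def _add_distractors(rng: np.random.Generator, img: np.ndarray, wound: np.ndarray,
                     mask: np.ndarray, strength: float) -> np.ndarray:
    """Blend 1-3 small wound-coloured spots into the background.

    Spots keep a clear margin from the wound so the ground-truth mask is
    unaffected; only the *appearance* of the background changes.
    """
    size = mask.shape[0]
    clearance = ndimage.distance_transform_edt(~mask.astype(bool))
    out = img
    n_spots = int(rng.integers(1, 4))
    for _ in range(n_spots):
        radius = rng.uniform(3.5, 7.0)
        eligible = np.flatnonzero((clearance > radius + 5.0).ravel())
        # keep spots off the raster border
        yy, xx = np.divmod(eligible, size)
        inside = (yy > radius + 1) & (yy < size - radius - 1) & \
                 (xx > radius + 1) & (xx < size - radius - 1)
        eligible = eligible[inside]
        if eligible.size == 0:
            break
        cy, cx = divmod(int(eligible[rng.integers(0, eligible.size)]), size)
        gy, gx = np.mgrid[0:size, 0:size].astype(np.float64)
        aspect = rng.uniform(0.6, 1.0)
        spot = ((gy - cy) / (radius * aspect)) ** 2 + ((gx - cx) / (radius / aspect)) ** 2 <= 1.0
        alpha = ndimage.gaussian_filter(spot.astype(np.float64), sigma=0.8)[..., None]
        out = out * (1.0 - strength * alpha) + wound * strength * alpha
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[list[ImageSample], pd.DataFrame]:
    """Generate ``config.n_images`` samples and their manifest.

    Returns the samples and a manifest DataFrame with one row per sample
    (columns: sample_id, image_path, mask_path, camera_tag, split_status;
    paths are filled in when the dataset is written to disk).
    """
    samples = [_render_sample(config, i) for i in range(config.n_images)]
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "image_path": ["" for _ in samples],
            "mask_path": ["" for _ in samples],
            "camera_tag": [s.camera_tag for s in samples],
            "split_status": ["unlabeled" for _ in samples],
        }
    )
    return samples, manifest


def generate_pretraining_set(
    n_images: int, image_size: int = 64, seed: int = 7_001
) -> list[ImageSample]:
    """Disjoint source-domain dataset for pre-training.

    Uses the ``base`` style family (different background and wound colour
    regimes, full contrast) and an unrelated seed, standing in for an
    external source-domain dataset in the transfer-learning structure.
    """
    cfg = SyntheticConfig(
        n_images=n_images,
        image_size=image_size,
        background_palette=("fabric", "flat"),
        hard_fraction=0.0,
        style="base",
        seed=seed,
    )
    samples, _ = generate_dataset(cfg)
    return samples


# ---------------------------------------------------------------------------
# mask corruption


def _check_corruptable(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("cannot corrupt an empty mask")
    return m


def corrupt_mask(mask: np.ndarray, spec: CorruptionSpec) -> np.ndarray:
    """Damage a binary mask in one of four characteristic ways.

    under_coverage
        Peels the boundary inward, strictly reducing foreground area by
        ~80% * severity of the original area (a coverage failure).
    holes
        Carves out the deepest interior pixels (~50% * severity of the
        area) while preserving the outer contour, creating >= 1 hole.
    spurious
        Adds 1 + floor(3*severity) small disjoint blobs in the
        background, away from the wound.
    boundary_jitter
        Displaces the contour with a smooth random field of amplitude
        12*severity px while keeping the area essentially unchanged.

    Severity 0 returns an identical copy in every mode.
    """
    m = _check_corruptable(mask)
    if spec.mode not in _CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {spec.mode!r}")
    if spec.severity == 0.0:
        return m.astype(np.uint8)
    out = {
        "under_coverage": _corrupt_under_coverage,
        "holes": _corrupt_holes,
        "spurious": _corrupt_spurious,
        "boundary_jitter": _corrupt_boundary_jitter,
    }[spec.mode](m, spec.severity, spec.seed)
    return out.astype(np.uint8)


def _corrupt_under_coverage(m: np.ndarray, severity: float, seed: int) -> np.ndarray:
    area = int(m.sum())
    k = min(max(1, round(0.8 * severity * area)), area - 1) if area > 1 else 1
    dist = ndimage.distance_transform_edt(m)
    flat = np.flatnonzero(m.ravel())
    order = flat[np.argsort(dist.ravel()[flat], kind="stable")]
    out = m.copy().ravel()
    out[order[:k]] = False
    return out.reshape(m.shape)


def _corrupt_holes(m: np.ndarray, severity: float, seed: int) -> np.ndarray:
    area = int(m.sum())
    dist = ndimage.distance_transform_edt(m)
    interior = np.flatnonzero((dist >= 2.0).ravel())
    if interior.size == 0:
        raise ValueError("mask too thin to carve interior holes")
    k = min(max(1, round(0.5 * severity * area)), interior.size)
    order = interior[np.argsort(-dist.ravel()[interior], kind="stable")]
    out = m.copy().ravel()
    out[order[:k]] = False
    return out.reshape(m.shape)


def _corrupt_spurious(m: np.ndarray, severity: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed, 2])
    n_blobs = 1 + int(3 * severity)
    radius = max(2.0, 0.1 * severity * np.sqrt(m.sum()) + 2.0)
    size = m.shape[0]
    dist_bg = ndimage.distance_transform_edt(~m)
    out = m.copy()
    yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]].astype(np.float64)
    for _ in range(n_blobs):
        eligible = np.flatnonzero(
            ((dist_bg > radius + 3.0) & (ndimage.distance_transform_edt(~out) > radius + 3.0)).ravel()
        )
        if eligible.size == 0:
            break
        c = eligible[rng.integers(0, eligible.size)]
        cy, cx = divmod(int(c), m.shape[1])
        out |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    if ndimage.label(out)[1] <= ndimage.label(m)[1]:
        raise RuntimeError("no room to place a spurious component")  # pragma: no cover
    return out


def _corrupt_boundary_jitter(m: np.ndarray, severity: float, seed: int) -> np.ndarray:
    from .validation import mean_boundary_distance

    rng = np.random.default_rng([seed, 3])
    sdf = ndimage.distance_transform_edt(m) - ndimage.distance_transform_edt(~m)
    noise = ndimage.gaussian_filter(rng.standard_normal(m.shape), sigma=4.0)
    noise /= max(noise.std(), 1e-12)
    area = int(m.sum())
    # displacement target grows linearly with severity (7% of the image
    # diagonal at severity 1); the amplitude escalates until the realised
    # mean contour displacement reaches it, because a random field of
    # fixed amplitude can under-displace on unlucky mask geometries
    target = 0.07 * severity * float(np.hypot(*m.shape))
    amp = 12.0 * severity
    out = m
    for _ in range(8):
        field = sdf + amp * noise
        # keep exactly the original area by thresholding at the field's
        # area-matching quantile
        thr = np.partition(field.ravel(), field.size - area)[field.size - area]
        out = field >= thr
        if mean_boundary_distance(out, m) >= target:
            break
        amp *= 1.6
    return out
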