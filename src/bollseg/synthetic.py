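"""Synthetic defoliated-cotton scenes with exact ground truth.

Real UAV frames of densely planted cotton after defoliation show bright,
clustered cotton bolls over a cluttered background: dark soil, highly
reflective plastic mulch film, and dark woody occluders (branches, stems,
leaf litter).  This module renders small RGB tiles that reproduce those
ingredients with a *known* binary boll mask, a controllable true boll pixel
ratio, and — at field level — sample yields drawn from a linear
ratio-to-yield model, so that every downstream stage (tiling, segmentation,
metrics, yield regression) can be exercised without field data.

Conventions
-----------
* Mask-level boll ratios are fractions in [0, 1]; the yield regression
  operates on the same quantity expressed in percent.  The single
  conversion boundary is :func:`generate_field_dataset`.
* Occluders remove boll pixels from both the image and the mask: an
  occluded boll pixel is background (visible-boll convention).
* One master seed per config; per-scene child seeds are spawned
  deterministically, so a fixed seed fixes every output bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "FieldSimConfig",
    "LabeledTile",
    "FieldSample",
    "FieldDataset",
    "generate_scene",
    "generate_field_dataset",
]

# Reference colours (8-bit RGB), loosely matched to defoliated-field imagery:
# sunlit loess soil, overexposed mulch film, raw cotton fibre, dry branch wood.
_SOIL_RGB = np.array([105.0, 85.0, 62.0])
_FILM_RGB = np.array([215.0, 225.0, 245.0])
_BOLL_RGB = np.array([240.0, 235.0, 222.0])
_BRANCH_RGB = np.array([60.0, 42.0, 28.0])


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one rendered tile.

    ``branch_density`` is expressed as occluders per 10^4 px^2 so that the
    amount of clutter is resolution-independent.  ``film_glare_fraction``
    is the approximate share of the tile covered by overexposed mulch film.
    """

    width: int = 64
    height: int = 64
    target_boll_ratio: float = 0.25
    boll_count_range: tuple[int, int] = (0, 400)
    boll_radius_range: tuple[float, float] = (2.0, 5.0)
    film_glare_fraction: float = 0.15
    soil_texture_scale: float = 8.0
    branch_density: float = 0.5
    illumination_jitter: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("width and height must be >= 32")
        if not 0.0 <= self.target_boll_ratio <= 1.0:
            raise ValueError("target_boll_ratio must lie in [0, 1]")
        for name in ("boll_count_range", "boll_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is degenerate: lo={lo} > hi={hi}")
        if not 0.0 <= self.film_glare_fraction <= 1.0:
            raise ValueError("film_glare_fraction must lie in [0, 1]")
        if self.boll_radius_range[0] <= 0:
            raise ValueError("boll radii must be positive")
        if self.branch_density < 0 or self.soil_texture_scale <= 0:
            raise ValueError("branch_density >= 0 and soil_texture_scale > 0 required")


@dataclass(frozen=True)
class FieldSimConfig:
    """Ratio-to-yield model for simulated sample plots.

    ``slope`` and ``intercept`` are in grams per sample plot with the boll
    pixel ratio expressed in percent; the defaults are the published field
    calibration y = 38.6 x + 34 for a 2.3 m^2 plot.  ``noise_sd`` defaults
    to 105 g, which under the default ratio range reproduces a fit R^2 of
    about 0.91 at n = 20.
    """

    n_samples: int = 20
    slope: float = 38.6
    intercept: float = 34.0
    noise_sd: float = 105.0
    ratio_range: tuple[float, float] = (0.10, 0.40)
    sample_area_m2: float = 2.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sample_area_m2 <= 0:
            raise ValueError("sample_area_m2 must be > 0")
        lo, hi = self.ratio_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ratio_range must satisfy 0 <= lo <= hi <= 1")


@dataclass
class LabeledTile:
    """An RGB tile paired with its aligned binary boll mask."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, uint8 in {0, 1}; 1 = cotton boll
    true_ratio: float

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask contains non-binary values {vals.tolist()}")
        expect = float(self.mask.mean())
        if self.true_ratio != expect:
            raise ValueError("true_ratio must equal mask.mean() exactly")


@dataclass(frozen=True)
class FieldSample:
    tile: LabeledTile
    yield_g: float  # grams per sample plot


@dataclass(frozen=True)
class FieldDataset:
    """Simulated sample plots plus the true generating coefficients."""

    samples: tuple[FieldSample, ...]
    slope: float
    intercept: float
    sample_area_m2: float

    @property
    def ratios_percent(self) -> np.ndarray:
        return np.array([100.0 * s.tile.true_ratio for s in self.samples])

    @property
    def yields_g(self) -> np.ndarray:
        return np.array([s.yield_g for s in self.samples])


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Zero-mean smooth random field, unit-ish amplitude."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=scale, mode="reflect")
    peak = np.abs(sm).max()
    return sm / peak if peak > 0 else sm


def _render_background(rng: np.random.Generator, cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Soil plus mulch-film strips.  Returns (image float HxWx3, glare mask)."""
    h, w = cfg.height, cfg.width
    img = np.empty((h, w, 3))
    tex = _smooth_noise(rng, (h, w), cfg.soil_texture_scale / 4.0)
    for c in range(3):
        img[:, :, c] = _SOIL_RGB[c] * (1.0 + 0.25 * tex)

    glare = np.zeros((h, w), dtype=bool)
    if cfg.film_glare_fraction > 0:
        # Mulch film lies in strips along the rows; render 1-3 vertical bands
        # that are bright and cool-tinted but nearly texture-free, so a pure
        # intensity threshold confuses them with bolls while colour/texture
        # still separates the classes.
        n_strips = int(rng.integers(1, 4))
        total = cfg.film_glare_fraction * w
        widths = np.maximum(1, rng.multinomial(int(round(total)), np.ones(n_strips) / n_strips))
        xs = np.sort(rng.choice(w, size=n_strips, replace=False))
        for x0, sw in zip(xs, widths):
            x1 = min(w, x0 + int(sw))
            glare[:, x0:x1] = True
        grad = 1.0 + 0.04 * _smooth_noise(rng, (h, w), cfg.soil_texture_scale)
        for c in range(3):
            ch = img[:, :, c]
            ch[glare] = _FILM_RGB[c] * grad[glare]
    return img, glare


def _branch_mask(rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    """Thin dark occluders: random line segments 1-2 px thick."""
    h, w = cfg.height, cfg.width
    occ = np.zeros((h, w), dtype=bool)
    n = int(round(cfg.branch_density * h * w / 1e4))
    for _ in range(n):
        x0, y0 = rng.uniform(0, w), rng.uniform(0, h)
        ang = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(0.3, 0.8) * min(h, w)
        thick = rng.uniform(0.5, 1.2)
        npts = max(2, int(length * 2))
        ts = np.linspace(0, 1, npts)
        xs = x0 + ts * length * math.cos(ang)
        ys = y0 + ts * length * math.sin(ang)
        for r in (-thick / 2, 0.0, thick / 2):
            xi = np.clip(np.round(xs + r * math.sin(ang)).astype(int), 0, w - 1)
            yi = np.clip(np.round(ys - r * math.cos(ang)).astype(int), 0, h - 1)
            inb = (xs + r >= 0) & (xs + r < w) & (ys >= 0) & (ys < h)
            occ[yi[inb], xi[inb]] = True
    return occ


def _blob_pixels(
    rng: np.random.Generator, cfg: SceneConfig
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """One irregular boll blob: union of a few jittered disks.

    Returns (rows, cols, cy, cx) of the blob's pixels within the canvas.
    """
    h, w = cfg.height, cfg.width
    r_lo, r_hi = cfg.boll_radius_range
    r0 = rng.uniform(r_lo, r_hi)
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    yy, xx = np.mgrid[0:h, 0:w]
    inside = np.zeros((h, w), dtype=bool)
    for _ in range(int(rng.integers(2, 5))):
        dy, dx = rng.normal(scale=r0 / 2, size=2)
        rr = r0 * rng.uniform(0.55, 1.0)
        inside |= (yy - (cy + dy)) ** 2 + (xx - (cx + dx)) ** 2 <= rr**2
    rows, cols = np.nonzero(inside)
    return rows, cols, cy, cx


def generate_scene(config: SceneConfig) -> LabeledTile:
    """Render one tile whose achieved boll ratio matches the target.

    Blobs are added until the visible (non-occluded) boll pixel count
    reaches ``round(target_boll_ratio * H * W)``; the last blob is trimmed
    from its rim inward so the achieved count is exact.  Raises
    ``ValueError`` naming the violated constraint when the target cannot be
    reached within ``boll_count_range`` or the non-occluded area.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    h, w = config.height, config.width
    n_px = h * w
    n_target = int(round(config.target_boll_ratio * n_px))

    img, _glare = _render_background(rng, config)
    occ = _branch_mask(rng, config)

    available = n_px - int(occ.sum())
    if n_target > available:
        raise ValueError(
            f"target_boll_ratio={config.target_boll_ratio} needs {n_target} px "
            f"but only {available} non-occluded px exist (branch_density too high)"
        )

    mask = np.zeros((h, w), dtype=bool)
    count_lo, count_hi = config.boll_count_range
    n_bolls = 0
    if n_target > 0:
        max_attempts = 50 * max(1, count_hi)
        attempts = 0
        while mask.sum() < n_target:
            if n_bolls >= count_hi or attempts >= max_attempts:
                raise ValueError(
                    f"could not reach target_boll_ratio={config.target_boll_ratio} "
                    f"with boll_count_range={config.boll_count_range} and "
                    f"boll_radius_range={config.boll_radius_range}"
                )
            attempts += 1
            rows, cols, cy, cx = _blob_pixels(rng, config)
            keep = ~(occ[rows, cols] | mask[rows, cols])
            rows, cols = rows[keep], cols[keep]
            if rows.size == 0:
                continue
            n_bolls += 1
            excess = int(mask.sum()) + rows.size - n_target
            if excess > 0:
                # trim the outermost pixels of this blob so the count is exact
                d2 = (rows - cy) ** 2 + (cols - cx) ** 2
                order = np.argsort(d2, kind="stable")[: rows.size - excess]
                rows, cols = rows[order], cols[order]
            mask[rows, cols] = True
    if n_bolls < count_lo:
        raise ValueError(
            f"reached the target with {n_bolls} bolls, below boll_count_range "
            f"minimum {count_lo}"
        )

    # Bolls: warm near-white fibre with per-pixel speckle.
    speckle = rng.normal(scale=6.0, size=(h, w))
    for c in range(3):
        ch = img[:, :, c]
        ch[mask] = _BOLL_RGB[c] + speckle[mask]
    # Branches overwrite whatever is beneath them (never a mask pixel).
    for c in range(3):
        ch = img[:, :, c]
        ch[occ] = _BRANCH_RGB[c] * (1.0 + 0.1 * speckle[occ] / 6.0)

    if config.illumination_jitter > 0:
        gain = 1.0 + config.illumination_jitter * _smooth_noise(
            rng, (h, w), max(2.0, min(h, w) / 4)
        )
        img *= gain[:, :, None]

    image = np.clip(img, 0, 255).astype(np.uint8)
    mask8 = mask.astype(np.uint8)
    return LabeledTile(image=image, mask=mask8, true_ratio=float(mask8.mean()))


def generate_field_dataset(
    scene_cfg: SceneConfig, field_cfg: FieldSimConfig
) -> FieldDataset:
    """Simulate manually harvested sample plots.

    Each sample draws a target boll ratio uniformly from
    ``field_cfg.ratio_range``, renders a scene for it (child seed spawned
    from the field seed), and assigns
    ``yield_g = slope * ratio_percent + intercept + Normal(0, noise_sd)``
    where ``ratio_percent`` is the tile's achieved true ratio in percent.
    """
    ss = np.random.SeedSequence(field_cfg.seed)
    rng = np.random.default_rng(ss)
    children = ss.spawn(field_cfg.n_samples)
    lo, hi = field_cfg.ratio_range
    targets = rng.uniform(lo, hi, size=field_cfg.n_samples)
    noise = rng.normal(0.0, field_cfg.noise_sd, size=field_cfg.n_samples)

    samples = []
    for i in range(field_cfg.n_samples):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        cfg_i = SceneConfig(
            width=scene_cfg.width,
            height=scene_cfg.height,
            target_boll_ratio=float(targets[i]),
            boll_count_range=scene_cfg.boll_count_range,
            boll_radius_range=scene_cfg.boll_radius_range,
            film_glare_fraction=scene_cfg.film_glare_fraction,
            soil_texture_scale=scene_cfg.soil_texture_scale,
            branch_density=scene_cfg.branch_density,
            illumination_jitter=scene_cfg.illumination_jitter,
            seed=child_seed,
        )
        tile = generate_scene(cfg_i)
        ratio_pct = 100.0 * tile.true_ratio
        y = field_cfg.slope * ratio_pct + field_cfg.intercept + noise[i]
        samples.append(FieldSample(tile=tile, yield_g=float(y)))
    return FieldDataset(
        samples=tuple(samples),
        slope=field_cfg.slope,
        intercept=field_cfg.intercept,
        sample_area_m2=field_cfg.sample_area_m2,
    )
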