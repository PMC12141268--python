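"""Synthetic nadir field-image generator with exact ground truth.

Emulates UAV frames of row-planted maize at the three-leaf stage: parallel
plant rows with near-constant spacing (65 cm rows / 25 cm plants by
default), random emergence dropout, green weed clutter off the rows, an
illumination gradient, sensor noise and optional blur. Every image comes
with exact ground truth (emerged centroids and boxes, the planned planting
grid, dropped positions, row lines), so the whole counting chain is
testable without any field data.

The default pixel scale is 2.3 px/cm (about 57 px between plants). The
nominal survey scale of 0.44 in mixed literature units is exposed under
both readings as :data:`GSD_PRESETS`; neither is asserted correct.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "GSD_PRESETS",
    "generate_field",
    "split_dataset",
    "augment_image",
    "augmentation_bookkeeping",
    "AUGMENTATION_POOL",
]

#: Pixel-per-centimeter presets. "survey-low" takes the nominal 0.44 figure
#: literally as px/cm; "survey-high" reads it as cm/px and inverts.
GSD_PRESETS = {
    "default": 2.3,
    "survey-low": 0.44,
    "survey-high": 1.0 / 0.44,
}

_SOIL_RGB = np.array([118.0, 94.0, 72.0])


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and nuisance parameters of one synthetic field image.

    Lengths are centimeters on the ground; ``gsd_px_per_cm`` converts them
    to pixels. ``missing_prob`` is the i.i.d. emergence-dropout probability
    per planting position. ``illumination_gradient`` is the multiplicative
    brightness range across the frame. ``canvas_px`` (height, width) is
    normally left to the generator, which sizes the canvas to contain every
    row plus a margin.
    """

    n_rows: int = 3
    plants_per_row: int = 10
    row_spacing_cm: float = 65.0
    plant_spacing_cm: float = 25.0
    gsd_px_per_cm: float = GSD_PRESETS["default"]
    row_angle_deg: float = 0.0
    position_jitter_cm: float = 0.0
    missing_prob: float = 0.0
    weed_density: float = 0.0
    illumination_gradient: tuple[float, float] = (0.85, 1.15)
    noise_sigma: float = 0.0
    blur_sigma: float = 0.0
    seed: int = 0
    canvas_px: tuple[int, int] | None = None

    def validate(self) -> None:
        if self.n_rows < 1 or self.plants_per_row < 1:
            raise ValueError("n_rows and plants_per_row must be >= 1")
        for name in ("row_spacing_cm", "plant_spacing_cm", "gsd_px_per_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        if self.position_jitter_cm < 0 or self.weed_density < 0:
            raise ValueError("jitter and weed density must be >= 0")
        lo, hi = self.illumination_gradient
        if lo <= 0 or hi < lo:
            raise ValueError("illumination_gradient must be 0 < low <= high")

    @property
    def plant_spacing_px(self) -> float:
        return self.plant_spacing_cm * self.gsd_px_per_cm

    @property
    def row_spacing_px(self) -> float:
        return self.row_spacing_cm * self.gsd_px_per_cm

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Exact truth for one generated image.

    Positions are pixel coordinates (x rightward, y downward); boxes are
    half-open ``(x_min, y_min, x_max, y_max)``. ``planned_positions`` holds
    every grid slot (after placement jitter); ``emerged_index`` /
    ``missing_index`` partition its index set.
    """

    planned_positions: np.ndarray  # (P, 2)
    row_index: np.ndarray  # (P,) row of each planned slot
    slot_index: np.ndarray  # (P,) within-row position of each slot
    emerged_index: np.ndarray  # (E,)
    missing_index: np.ndarray  # (M,)
    emerged_boxes: np.ndarray  # (E, 4)
    row_lines: list[tuple[float, float]]  # (slope, intercept) per row

    @property
    def emerged_centroids(self) -> np.ndarray:
        return self.planned_positions[self.emerged_index]

    @property
    def missing_positions(self) -> np.ndarray:
        return self.planned_positions[self.missing_index]

    @property
    def n_missing(self) -> int:
        return int(self.missing_index.size)

    def interior_missing(self) -> int:
        """Missing slots strictly inside the emerged span of their row.

        A gap beyond the first or last emerged plant of a row does not
        change the row's projection span and is therefore unobservable to a
        span-based expected count; this is the portion of ``n_missing`` the
        counting chain can see.
        """
        count = 0
        for r in np.unique(self.row_index):
            in_row = self.row_index == r
            emerged = self.slot_index[in_row & np.isin(np.arange(self.row_index.size), self.emerged_index)]
            if emerged.size < 2:
                continue
            lo, hi = emerged.min(), emerged.max()
            missing = self.slot_index[in_row & np.isin(np.arange(self.row_index.size), self.missing_index)]
            count += int(((missing > lo) & (missing < hi)).sum())
        return count

    def to_json_dict(self) -> dict:
        return {
            "planned_positions": self.planned_positions.tolist(),
            "row_index": self.row_index.tolist(),
            "slot_index": self.slot_index.tolist(),
            "emerged_index": self.emerged_index.tolist(),
            "missing_index": self.missing_index.tolist(),
            "emerged_boxes": self.emerged_boxes.tolist(),
            "row_lines": [list(rl) for rl in self.row_lines],
            "n_missing": self.n_missing,
        }


def _plant_sprite_params(spec: FieldSpec) -> dict:
    s = spec.plant_spacing_px
    return {
        "lobe_len": 0.35 * s,  # semi-major axis scale of one leaf lobe
        "lobe_width_ratio": 0.32,
        "stem_radius": max(2.0, 0.06 * s),
    }


def _draw_lobes(
    canvas: np.ndarray,
    center_xy: np.ndarray,
    n_lobes: int,
    lobe_len: float,
    width_ratio: float,
    color_rgb: np.ndarray,
    rng: np.random.Generator,
    stem_radius: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint a multi-lobed green sprite; return the painted (rows, cols)."""
    h, w = canvas.shape[:2]
    painted_r: list[np.ndarray] = []
    painted_c: list[np.ndarray] = []
    base_angle = rng.uniform(0, 2 * np.pi)
    for k in range(n_lobes):
        ang = base_angle + 2 * np.pi * k / n_lobes + rng.normal(0, 0.25)
        u = rng.uniform(0.8, 1.2)
        a = 0.5 * lobe_len * u
        b = max(1.2, width_ratio * a)
        cx = center_xy[0] + 0.45 * lobe_len * u * np.cos(ang)
        cy = center_xy[1] + 0.45 * lobe_len * u * np.sin(ang)
        rr, cc = skdraw.ellipse(cy, cx, a, b, shape=(h, w), rotation=np.pi / 2 - ang)
        shade = rng.uniform(0.85, 1.1)
        canvas[rr, cc] = np.clip(color_rgb * shade, 0, 255)
        painted_r.append(rr)
        painted_c.append(cc)
    if stem_radius > 0:
        rr, cc = skdraw.disk((center_xy[1], center_xy[0]), stem_radius, shape=(h, w))
        canvas[rr, cc] = np.clip(color_rgb * 0.9, 0, 255)
        painted_r.append(rr)
        painted_c.append(cc)
    if painted_r:
        return np.concatenate(painted_r), np.concatenate(painted_c)
    return np.empty(0, int), np.empty(0, int)


def _green_rgb(rng: np.random.Generator) -> np.ndarray:
    """A random color in the HSV green band, as 0-255 RGB."""
    hsv = np.array([rng.uniform(0.24, 0.36), rng.uniform(0.55, 0.8), rng.uniform(0.45, 0.68)])
    return hsv2rgb(hsv.reshape(1, 1, 3)).reshape(3) * 255.0


def generate_field(spec: FieldSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one field image and its exact ground truth.

    Deterministic given ``spec.seed``. Raises ``ValueError`` naming the
    offending dimension when an explicit ``canvas_px`` cannot contain the
    planting grid plus margin.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    s_px = spec.plant_spacing_px
    r_px = spec.row_spacing_px
    jitter_px = spec.position_jitter_cm * spec.gsd_px_per_cm
    sprite = _plant_sprite_params(spec)

    # planned grid in field coordinates, rotated to the row angle
    ii, jj = np.meshgrid(np.arange(spec.plants_per_row), np.arange(spec.n_rows))
    slot_index = ii.ravel()
    row_index = jj.ravel()
    grid = np.column_stack([slot_index * s_px, row_index * r_px]).astype(float)
    theta = np.radians(spec.row_angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    grid = grid @ rot.T
    positions = grid + rng.normal(0.0, jitter_px, size=grid.shape)

    margin = sprite["lobe_len"] + 10.0
    offset = margin - positions.min(axis=0)
    positions = positions + offset
    extent = positions.max(axis=0) + margin
    need_w, need_h = int(np.ceil(extent[0])), int(np.ceil(extent[1]))
    if spec.canvas_px is not None:
        h, w = spec.canvas_px
        if h < need_h:
            raise ValueError(f"canvas height {h} px too small: the planting grid plus margin needs >= {need_h} px")
        if w < need_w:
            raise ValueError(f"canvas width {w} px too small: the planting grid plus margin needs >= {need_w} px")
    else:
        h, w = need_h, need_w

    # nominal row lines (pre-jitter geometry), y = m x + b in pixel coords
    row_lines = []
    for r in range(spec.n_rows):
        p0 = np.array([0.0, r * r_px]) @ rot.T + offset
        p1 = np.array([(spec.plants_per_row - 1) * s_px, r * r_px]) @ rot.T + offset
        dx, dy = p1 - p0
        if abs(dx) < 1e-12:
            slope = np.inf
            intercept = p0[0]
        else:
            slope = dy / dx
            intercept = p0[1] - slope * p0[0]
        row_lines.append((float(slope), float(intercept)))

    emerged_mask = rng.random(positions.shape[0]) >= spec.missing_prob
    emerged_index = np.where(emerged_mask)[0]
    missing_index = np.where(~emerged_mask)[0]

    # soil background with speckle
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _SOIL_RGB
    img += rng.normal(0, 5.0, size=(h, w, 1))
    img += rng.normal(0, 2.5, size=(h, w, 3))

    boxes = np.zeros((emerged_index.size, 4), dtype=int)
    for n, idx in enumerate(emerged_index):
        color = _green_rgb(rng)
        rr, cc = _draw_lobes(
            img,
            positions[idx],
            3,
            sprite["lobe_len"],
            sprite["lobe_width_ratio"],
            color,
            rng,
            stem_radius=sprite["stem_radius"],
        )
        if rr.size:
            boxes[n] = (cc.min(), rr.min(), cc.max() + 1, rr.max() + 1)
        else:  # sprite degenerated to nothing (should not happen at sane scales)
            x, y = positions[idx]
            boxes[n] = (int(x), int(y), int(x) + 1, int(y) + 1)

    _scatter_weeds(img, spec, positions, rng, sprite, rot, offset)

    # illumination ramp along a random direction
    lo, hi = spec.illumination_gradient
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    t = xx * np.cos(phi) + yy * np.sin(phi)
    t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
    img *= (lo + (hi - lo) * t)[..., None]

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        planned_positions=positions,
        row_index=row_index,
        slot_index=slot_index,
        emerged_index=emerged_index,
        missing_index=missing_index,
        emerged_boxes=boxes,
        row_lines=row_lines,
    )
    return img, truth


def _scatter_weeds(
    img: np.ndarray,
    spec: FieldSpec,
    positions: np.ndarray,
    rng: np.random.Generator,
    sprite: dict,
    rot: np.ndarray,
    offset: np.ndarray,
) -> None:
    """Drop green weed blobs off the plant rows (similar hue, smaller area).

    Weeds are rejected when closer than 0.2 x the row spacing to any row
    line (they sit between rows, like inter-row volunteers left by
    cultivation) or closer than 0.8 x the plant spacing to any plant.
    """
    n_weeds = int(rng.poisson(spec.weed_density))
    if n_weeds == 0:
        return
    h, w = img.shape[:2]
    min_plant_dist = 0.8 * spec.plant_spacing_px
    min_line_dist = 0.2 * spec.row_spacing_px
    row_y = np.arange(spec.n_rows) * spec.row_spacing_px
    for _ in range(n_weeds):
        for _try in range(50):
            p = rng.uniform([0, 0], [w, h])
            p_field = (p - offset) @ rot  # rot is orthonormal: inverse = transpose
            line_dist = np.min(np.abs(p_field[1] - row_y))
            if (
                line_dist > min_line_dist
                and np.min(np.linalg.norm(positions - p, axis=1)) > min_plant_dist
            ):
                break
        else:
            continue
        n_lobes = int(rng.integers(1, 3))
        area_frac = rng.uniform(0.3, 0.6)
        scale = np.sqrt(area_frac * 3.0 / n_lobes)
        _draw_lobes(
            img,
            p,
            n_lobes,
            sprite["lobe_len"] * scale,
            sprite["lobe_width_ratio"],
            _green_rgb(rng),
            rng,
        )


# ---------------------------------------------------------------------------
# dataset bookkeeping


def split_dataset(item_ids: list, ratio: tuple[float, float, float] = (7, 1, 2)) -> tuple[list, list, list]:
    """Split an ordered item list into train/val/test by proportional counts.

    Sizes are the exact proportional counts when divisible; otherwise the
    largest-remainder rule assigns leftover items (ties go to the earlier
    split). Items are assigned in order: the first block is train, then
    val, then test. Empty input yields three empty splits.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio components must be positive")
    items = list(item_ids)
    n = len(items)
    total = float(sum(ratio))
    quotas = [n * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    fracs = sorted(range(3), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in range(remainder):
        sizes[fracs[i]] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return items[:a], items[a:b], items[b:]


def augmentation_bookkeeping(
    n_items: int,
    ratio: tuple[float, float, float] = (7, 1, 2),
    variants_per_image: int = 4,
) -> dict:
    """Image counts after per-image augmentation of each split."""
    train, val, test = split_dataset(list(range(n_items)), ratio)
    return {
        "total_augmented": n_items * variants_per_image,
        "train": len(train) * variants_per_image,
        "val": len(val) * variants_per_image,
        "test": len(test) * variants_per_image,
    }


# ---------------------------------------------------------------------------
# augmentation


def _as_float(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float)


def _to_u8(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0, 255).astype(np.uint8)


def _aug_fill(img, rng):
    out = _as_float(img).copy()
    h, w = out.shape[:2]
    mean = out.reshape(-1, 3).mean(axis=0)
    for _ in range(int(rng.integers(1, 4))):
        rh, rw = int(rng.integers(h // 10 + 1, h // 3 + 2)), int(rng.integers(w // 10 + 1, w // 3 + 2))
        r0, c0 = int(rng.integers(0, max(h - rh, 1))), int(rng.integers(0, max(w - rw, 1)))
        out[r0 : r0 + rh, c0 : c0 + rw] = mean
    return _to_u8(out)


def _aug_rotate(img, rng):
    angle = float(rng.uniform(-25, 25))
    out = sktransform.rotate(_as_float(img) / 255.0, angle, resize=False, mode="edge")
    return _to_u8(out * 255.0)


def _aug_saturation(img, rng):
    hsv = rgb2hsv(_as_float(img) / 255.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.5, 1.5), 0, 1)
    return _to_u8(hsv2rgb(hsv) * 255.0)


def _aug_brightness(img, rng):
    return _to_u8(_as_float(img) * rng.uniform(0.6, 1.4))


def _aug_crop(img, rng):
    h, w = img.shape[:2]
    f = rng.uniform(0.7, 0.9)
    ch, cw = max(int(h * f), 1), max(int(w * f), 1)
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    crop = _as_float(img[r0 : r0 + ch, c0 : c0 + cw]) / 255.0
    out = sktransform.resize(crop, (h, w, 3), anti_aliasing=True)
    return _to_u8(out * 255.0)


def _aug_noise(img, rng):
    return _to_u8(_as_float(img) + rng.normal(0, rng.uniform(3, 10), size=img.shape))


def _aug_blur(img, rng):
    return _to_u8(ndimage.gaussian_filter(_as_float(img), sigma=(rng.uniform(0.5, 2.0),) * 2 + (0,)))


def _aug_resize(img, rng):
    # the original-preserving down/up resize used for cropping outputs
    h, w = img.shape[:2]
    f = rng.uniform(0.5, 0.8)
    small = sktransform.resize(_as_float(img) / 255.0, (max(int(h * f), 1), max(int(w * f), 1), 3), anti_aliasing=True)
    return _to_u8(sktransform.resize(small, (h, w, 3), anti_aliasing=True) * 255.0)


#: The fixed 8-method augmentation pool; 4 are drawn without replacement
#: per image.
AUGMENTATION_POOL = (
    ("fill", _aug_fill),
    ("rotate", _aug_rotate),
    ("saturation", _aug_saturation),
    ("brightness", _aug_brightness),
    ("crop", _aug_crop),
    ("noise", _aug_noise),
    ("blur", _aug_blur),
    ("resize", _aug_resize),
)


def augment_image(image: np.ndarray, seed: int) -> list[np.ndarray]:
    """Produce exactly 4 augmented variants of one image.

    The 4 methods are drawn without replacement from the 8-method pool;
    outputs keep the input raster dimensions, and the whole draw is
    deterministic given ``seed``.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(AUGMENTATION_POOL), size=4, replace=False)
    return [AUGMENTATION_POOL[i][1](image, rng) for i in picks]


def make_image_specs(base: FieldSpec, n_images: int, seed: int) -> list[FieldSpec]:
    """Per-image specs for a batch: the base spec re-seeded per frame."""
    return [replace(base, seed=int(seed) + i) for i in range(n_images)]
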