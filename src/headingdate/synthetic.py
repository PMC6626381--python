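"""Synthetic time-series paddy-field imagery with known flowering schedule.

The generator emulates the situation the detection pipeline is built for: a
fixed camera over a rice paddy, several photographs per day, and flowering
panicles that emerge over a window of days.  Rice is transplanted on a
regular grid of hills, so panicle sprites are placed on a planting-grid
lattice (one panicle per grid cell per day at most); each sprite is a
bright, elongated, randomly oriented blob on a darker green canopy-noise
background, mimicking the distinct luminance of anthesis without modelling
real rice morphology.

Because the emergence schedule is an explicit input, the true 50%-flowering
day of every generated series is known analytically
(:func:`true_heading_date`), which is what makes end-to-end recovery tests
possible without any field data.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .core import (AnnotatedImage, Box, ImageSeries, ValidationError,
                   write_annotations)

#: Default image times-of-day; one per image slot, chosen to fall inside the
#: three acquisition windows used for validation-set construction
#: (morning / midday / afternoon).
DEFAULT_IMAGE_TIMES = (dt.time(8, 30), dt.time(11, 30), dt.time(15, 30))


@dataclass
class PhenologyParams:
    """Parameters of one synthetic flowering season.

    The defaults define the package's standard synthetic study: a 640x480
    camera view over an 80 px planting-grid pitch (48 hills), a 10-day
    bell-shaped emergence schedule totalling 60 panicles around day 84 after
    a 2013-05-31 transplanting (the day range real acquisitions cover), and
    3 images per day.  Sprites span most of a grid cell, as field window
    sizes are chosen to match panicle size.
    """

    emergence_schedule: dict[int, int] = field(default_factory=lambda: {
        80: 2, 81: 4, 82: 6, 83: 8, 84: 10,
        85: 10, 86: 8, 87: 6, 88: 4, 89: 2})
    images_per_day: int = 3
    image_w: int = 640
    image_h: int = 480
    grid_pitch: int = 80          # planting-grid cell size, px
    panicle_size_range: tuple[int, int] = (56, 76)   # sprite major axis, px
    panicle_aspect_range: tuple[float, float] = (0.55, 0.85)
    flowering_duration_days: int = 1
    image_times: tuple[dt.time, ...] = DEFAULT_IMAGE_TIMES
    transplanting_date: dt.date = dt.date(2013, 5, 31)
    base_green: tuple[int, int, int] = (45, 95, 40)  # canopy mean RGB
    noise_amplitude: float = 28.0                    # canopy noise sd
    brightness_jitter: float = 8.0                   # per-image global shift
    sprite_luminance: tuple[int, int] = (205, 250)   # sprite channel band
    rng_seed: int = 0

    # margin kept between a sprite's tight box and its grid cell
    _CELL_MARGIN = 4

    @property
    def n_panicles_total(self) -> int:
        return sum(self.emergence_schedule.values())

    def validate(self) -> None:
        if any(c < 0 for c in self.emergence_schedule.values()):
            raise ValidationError("emergence_schedule counts must be >= 0")
        if self.images_per_day < 1:
            raise ValidationError("images_per_day must be >= 1")
        if self.images_per_day > len(self.image_times):
            raise ValidationError(
                f"images_per_day={self.images_per_day} needs at least that "
                f"many image_times (got {len(self.image_times)})")
        if self.flowering_duration_days < 1:
            raise ValidationError("flowering_duration_days must be >= 1")
        max_sprite = self.panicle_size_range[1]
        if max_sprite > self.grid_pitch - self._CELL_MARGIN:
            raise ValidationError(
                f"sprite major axis up to {max_sprite} px cannot fit in a "
                f"{self.grid_pitch} px grid cell with margin")
        n_cells = (self.image_w // self.grid_pitch) * (self.image_h // self.grid_pitch)
        if n_cells < 1:
            raise ValidationError("image smaller than one grid cell")
        peak = max(self.emergence_schedule.values(), default=0)
        active = peak * self.flowering_duration_days
        if active > n_cells:
            raise ValidationError(
                f"up to {active} simultaneously flowering panicles exceed "
                f"the {n_cells} grid cells available")


def true_heading_date(params: PhenologyParams) -> int:
    """Analytic 50%-flowering day: first day with cumulative emergence
    >= half the season total (ties resolved by the >= rule)."""
    total = params.n_panicles_total
    if not params.emergence_schedule:
        raise ValidationError("empty emergence schedule")
    if total <= 0:
        raise ValidationError("no panicles in the emergence schedule")
    cum = 0
    for day in sorted(params.emergence_schedule):
        cum += params.emergence_schedule[day]
        if cum * 2 >= total:
            return day
    raise AssertionError("unreachable: cumulative sum must reach total")


def _luminance(rgb: np.ndarray) -> np.ndarray:
    return (0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2])


def _render_background(rng: np.random.Generator,
                       params: PhenologyParams) -> np.ndarray:
    """Green canopy: blotchy low-frequency noise plus per-pixel grain."""
    h, w = params.image_h, params.image_w
    coarse_h, coarse_w = max(h // 16, 1), max(w // 16, 1)
    coarse = rng.normal(0.0, params.noise_amplitude, (coarse_h, coarse_w, 3))
    blotch = np.asarray(
        Image.fromarray(coarse.astype(np.float32)[..., 0], mode="F")
        .resize((w, h), Image.BILINEAR))
    img = np.empty((h, w, 3), dtype=np.float32)
    for c, base in enumerate(params.base_green):
        grain = rng.normal(0.0, params.noise_amplitude * 0.4, (h, w))
        img[..., c] = base + blotch * (0.4 + 0.3 * c % 1.0) + grain
    # keep canopy luminance well below the sprite band
    np.clip(img, 0, 165, out=img)
    return img


def _sprite_mask(rng: np.random.Generator, params: PhenologyParams
                 ) -> np.ndarray:
    """Boolean mask of one randomly oriented squarish-superellipse blob,
    tight to its own bounding box, guaranteed to fit a grid cell."""
    lo, hi = params.panicle_size_range
    major = rng.uniform(lo, hi)
    aspect = rng.uniform(*params.panicle_aspect_range)
    minor = major * aspect
    theta = rng.uniform(0, np.pi)
    avail = params.grid_pitch - params._CELL_MARGIN
    # rotated extent of the blob; shrink if rotation pushes it past the cell
    ext_x = major * abs(np.cos(theta)) + minor * abs(np.sin(theta))
    ext_y = major * abs(np.sin(theta)) + minor * abs(np.cos(theta))
    scale = min(1.0, avail / max(ext_x, ext_y))
    major *= scale
    minor *= scale

    size = avail
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    # exponent 4 superellipse: squarish, fills most of its tight box
    mask = (np.abs(2 * u / major) ** 4 + np.abs(2 * v / minor) ** 4) <= 1.0
    ys, xs = np.nonzero(mask)
    return mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]


def _day_sprites(day_rng: np.random.Generator, params: PhenologyParams,
                 count: int, occupied: set[int]) -> list[tuple[Box, np.ndarray, np.ndarray]]:
    """Place ``count`` sprites on free grid cells; returns (box, mask, rgb)."""
    cells_x = params.image_w // params.grid_pitch
    cells_y = params.image_h // params.grid_pitch
    free = [c for c in range(cells_x * cells_y) if c not in occupied]
    if count > len(free):
        raise ValidationError(
            f"{count} new panicles requested but only {len(free)} free "
            f"grid cells remain")
    chosen = day_rng.choice(len(free), size=count, replace=False) if count else []
    placed = []
    for idx in np.sort(np.asarray(chosen, dtype=int)):
        cell = free[int(idx)]
        gx, gy = cell % cells_x, cell // cells_x
        mask = _sprite_mask(day_rng, params)
        mh, mw = mask.shape
        max_dx = params.grid_pitch - mw
        max_dy = params.grid_pitch - mh
        dx = int(day_rng.integers(0, max_dx + 1))
        dy = int(day_rng.integers(0, max_dy + 1))
        x0 = gx * params.grid_pitch + dx
        y0 = gy * params.grid_pitch + dy
        lo, hi = params.sprite_luminance
        base = day_rng.uniform(lo + 15, hi - 5)
        rgb = np.clip(
            base + day_rng.normal(0, 6, (mh, mw, 3)) * np.array([1.0, 0.8, 1.2]),
            lo, 255).astype(np.float32)
        rgb[..., 2] *= 0.92  # slight warm cast, anthesis-like
        np.clip(rgb, lo, 255, out=rgb)
        placed.append((Box(x0, y0, x0 + mw, y0 + mh), mask, rgb))
        occupied.add(cell)
    return placed


def generate_field_series(params: PhenologyParams,
                          name: str = "synthetic") -> ImageSeries:
    """Render the full image series implied by ``params``.

    Deterministic: identical params and seed give bit-identical pixel
    arrays.  Sub-streams are derived per day (sprite placement, shared by
    all of that day's images because a panicle is a physical object) and per
    image (background texture, brightness jitter), so changing
    ``images_per_day`` never perturbs the imagery of earlier slots.
    """
    params.validate()
    days = sorted(params.emergence_schedule)
    active: dict[int, list[tuple[Box, np.ndarray, np.ndarray]]] = {}
    images: list[AnnotatedImage] = []
    all_days = range(days[0], days[-1] + params.flowering_duration_days) if days else []
    for day in all_days:
        new_count = params.emergence_schedule.get(day, 0)
        # withering: drop sprites whose flowering window has passed
        active = {d: s for d, s in active.items()
                  if d + params.flowering_duration_days > day}
        occupied: set[int] = set()
        for sprites in active.values():
            for box, _, _ in sprites:
                occupied.add(_cell_of(box, params))
        day_rng = np.random.default_rng(
            np.random.SeedSequence([params.rng_seed, 1, day]))
        active[day] = _day_sprites(day_rng, params, new_count, occupied)
        sprites_today = [s for d in sorted(active) for s in active[d]]

        date = params.transplanting_date + dt.timedelta(days=day)
        for slot in range(params.images_per_day):
            img_rng = np.random.default_rng(
                np.random.SeedSequence([params.rng_seed, 2, day, slot]))
            canvas = _render_background(img_rng, params)
            for box, mask, rgb in sprites_today:
                region = canvas[box.y_min:box.y_max, box.x_min:box.x_max]
                region[mask] = rgb[mask]
            jitter = img_rng.uniform(-params.brightness_jitter,
                                     params.brightness_jitter)
            canvas = np.clip(canvas + jitter, 0, 255)
            ts = dt.datetime.combine(date, params.image_times[slot])
            images.append(AnnotatedImage(
                image_id=f"{name}_d{day:03d}_t{slot}",
                pixels=canvas.astype(np.uint8),
                timestamp=ts,
                gt_boxes=[box for box, _, _ in sprites_today],
                day_index=day))
    return ImageSeries(name=name, images=images,
                       transplanting_date=params.transplanting_date)


def _cell_of(box: Box, params: PhenologyParams) -> int:
    cells_x = params.image_w // params.grid_pitch
    return (box.y_min // params.grid_pitch) * cells_x + box.x_min // params.grid_pitch


def random_schedule(rng: np.random.Generator, *, n_days: int = 10,
                    total: int = 60, start_day: int = 80) -> dict[int, int]:
    """Random bell-weighted emergence schedule totalling ``total`` panicles.

    Counts are multinomial draws around a triangular profile, the shape a
    flowering progress curve takes in the field.
    """
    days = np.arange(n_days)
    weights = np.minimum(days + 1, n_days - days).astype(float)
    weights /= weights.sum()
    counts = rng.multinomial(total, weights)
    return {start_day + int(d): int(c) for d, c in zip(days, counts)}


def save_series(series: ImageSeries, params: PhenologyParams,
                outdir: str | Path) -> Path:
    """Write images as PNG, ground truth as annotation CSV, and a JSON
    sidecar with the parameters and analytic 50%-flowering day.

    Returns the sidecar path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_paths = {}
    for img in series.images:
        rel = f"{img.image_id}.png"
        Image.fromarray(img.pixels).save(outdir / rel)
        image_paths[img.image_id] = rel
    write_annotations(series, outdir / "annotations.csv",
                      image_paths=image_paths)
    sidecar = {
        "name": series.name,
        "transplanting_date": series.transplanting_date.isoformat(),
        "n_panicles_total": params.n_panicles_total,
        "true_heading_day": true_heading_date(params),
        "true_heading_date": (series.transplanting_date +
                              dt.timedelta(days=true_heading_date(params))
                              ).isoformat(),
        "params": {
            "emergence_schedule": {str(k): v for k, v
                                   in sorted(params.emergence_schedule.items())},
            "images_per_day": params.images_per_day,
            "image_w": params.image_w,
            "image_h": params.image_h,
            "grid_pitch": params.grid_pitch,
            "panicle_size_range": list(params.panicle_size_range),
            "flowering_duration_days": params.flowering_duration_days,
            "rng_seed": params.rng_seed,
        },
    }
    sidecar_path = outdir / "series.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path
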