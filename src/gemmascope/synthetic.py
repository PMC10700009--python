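"""Synthetic gemmaling-image generator with channel-separable class effects.

Real gemmaling photographs show a single bilobed green plantlet centered on a
dark agar plate, growing over days 0-7 after gemma planting. This module
emulates that setting so every downstream stage (segmentation, ablation,
training, attribution, transfer) is testable at desk scale, with ground-truth
silhouette masks attached to every image.

The two classes ("male"/"female") can differ through four independent
channels, each injected as a standardized mean difference:

* ``area_effect``      -- log projected foreground area (multiplicative growth)
* ``color_effect``     -- mean foreground green intensity (linear scale)
* ``contour_effect``   -- amplitude of high contour harmonics (shape wiggliness)
* ``background_effect``-- background tint and scratch density (a deliberate
  confound, mimicking nuisance cues like scratches on the culture medium)

With all effects zero the two classes are draws from a single distribution.
Plant shape is a star-convex contour r(theta) = r0 (1 + sum_k a_k cos(k theta
+ phi_k)), k <= 8, with the bilobed k=2 component dominant; the radius is
renormalized so harmonics do not change expected area, which keeps the four
channels statistically independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from PIL import Image

from .types import ImageRecord, SilhouetteMask, LABELS

# ---------------------------------------------------------------------------
# growth schedule
# ---------------------------------------------------------------------------

#: imaging schedule (days after planting gemmae)
DAY_SCHEDULE = (0, 1, 2, 3, 4, 7)

# expected plant radius as a fraction of image side, strictly increasing in day
_RADIUS_FRACTION = {0: 0.08, 1: 0.10, 2: 0.12, 3: 0.15, 4: 0.18, 7: 0.24}
# number of contour lobes (the thallus bifurcates as it grows)
_LOBE_COUNT = {0: 2, 1: 2, 2: 2, 3: 4, 4: 4, 7: 8}


@dataclass(frozen=True)
class GrowthModel:
    """Day-indexed expected size and lobation of the plantlet."""

    day: int = 7

    def __post_init__(self) -> None:
        if self.day not in DAY_SCHEDULE:
            raise ValueError(f"day must be one of {DAY_SCHEDULE}, got {self.day}")

    def base_radius(self, image_size: int, day: Optional[int] = None) -> float:
        """Expected plant radius in pixels at the given day (monotone in day)."""
        d = self.day if day is None else day
        return _RADIUS_FRACTION[d] * image_size

    def lobe_count(self, day: Optional[int] = None) -> int:
        d = self.day if day is None else day
        return _LOBE_COUNT[d]


# ---------------------------------------------------------------------------
# class-effect configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelEffects:
    """Standardized between-class mean differences, one per channel.

    Each effect is a dimensionless standardized mean difference (Cohen's d
    convention, female minus male). Effects are independently settable; all
    zeros means the two classes share one distribution.
    """

    area_effect: float = 0.0
    color_effect: float = 0.0
    contour_effect: float = 0.0
    background_effect: float = 0.0


# within-class standard deviations of the latent channel parameters.
# These define what one "standardized unit" of each effect means.
SIGMA_LOG_AREA = 0.25      # sd of log projected area (biological CV ~25%)
SIGMA_GREEN = 0.08         # sd of mean foreground green intensity ([0,1] scale)
SIGMA_HUE = 0.08           # sd of the green<->brown tissue-hue latent
SIGMA_CONTOUR = 0.15       # sd of the contour spectral-centroid latent
SIGMA_TINT = 0.02          # sd of background tint level

# channel baselines
_BASE_GREEN = 0.55
# the contour channel redistributes a fixed total harmonic amplitude between
# a coarse-scallop harmonic and a fine-crenellation harmonic; coding the
# class difference as a spectral-centroid shift at constant energy keeps the
# expected area and radial variance identical across classes (the total
# amplitude is a within-class nuisance, not the signal)
_CONTOUR_KS = (5, 8)
_CONTOUR_AMP_MEAN = 0.24
_CONTOUR_AMP_SD = 0.015
_CONTOUR_AMP_RANGE = (0.05, 0.32)
_BASE_TINT = 0.10
_BASE_SCRATCH_RATE = 3.0
_GREEN_RANGE = (0.15, 0.95)
_TINT_RANGE = (0.02, 0.50)
_CONTOUR_RANGE = (0.0, 0.30)


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Full recipe for one synthetic dataset.

    ``n_per_class`` images per class per day; identical config + seed yields a
    bit-identical dataset.
    """

    n_per_class: int
    image_size: int = 256
    effects: ChannelEffects = field(default_factory=ChannelEffects)
    growth: GrowthModel = field(default_factory=GrowthModel)
    days: Tuple[int, ...] = ()
    scale_bar: bool = True
    line: str = "syn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 4:
            raise ValueError("n_per_class must be >= 4")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for d in self.days:
            if d not in DAY_SCHEDULE:
                raise ValueError(f"days must be drawn from {DAY_SCHEDULE}")

    @property
    def day_list(self) -> Tuple[int, ...]:
        return self.days if self.days else (self.growth.day,)


# ---------------------------------------------------------------------------
# low-level rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeParams:
    """Star-convex contour: radius plus (harmonic, amplitude, phase) triples."""

    radius: float
    harmonics: Tuple[Tuple[int, float, float], ...] = ()

    def amplitude_sum(self) -> float:
        return float(sum(abs(a) for _, a, _ in self.harmonics))


@dataclass(frozen=True)
class AppearanceParams:
    """Foreground color/texture: green level plus speckle texture."""

    green: float = _BASE_GREEN
    red: float = 0.20
    blue: float = 0.16
    texture_sd: float = 0.08


@dataclass(frozen=True)
class BackgroundParams:
    """Dark agar background: tint level, pixel noise and scratch segments."""

    tint: float = _BASE_TINT
    noise_sd: float = 0.012
    scratch_count: int = 3
    scratch_contrast: float = 0.10


def _contour_radius(shape: ShapeParams, theta: np.ndarray) -> np.ndarray:
    r = np.ones_like(theta)
    for k, amp, phase in shape.harmonics:
        r = r + amp * np.cos(k * theta + phase)
    return shape.radius * r


def _area_inflation(shape: ShapeParams) -> float:
    """Ratio of contour area to pi r0^2: 1 + 0.5 sum a_k^2."""
    return 1.0 + 0.5 * sum(a * a for _, a, _ in shape.harmonics)


def render_silhouette(shape: ShapeParams, image_size: int) -> np.ndarray:
    """Rasterize the star-convex contour into a centered boolean mask.

    Raises if the contour would self-intersect (radius non-positive somewhere)
    or poke out of frame.
    """
    if shape.amplitude_sum() >= 0.95:
        raise ValueError(
            "contour self-intersection: harmonic amplitudes sum to "
            f"{shape.amplitude_sum():.3f} >= 0.95"
        )
    r_max = shape.radius * (1.0 + shape.amplitude_sum())
    if r_max > image_size / 2.0 - 2.0:
        raise ValueError(
            f"out-of-frame radius: max contour radius {r_max:.1f} px does not fit "
            f"in a {image_size}-px frame"
        )
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dy, dx = yy - c, xx - c
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return rho <= _contour_radius(shape, theta)


def _paint_background(bg: BackgroundParams, image_size: int, rng: Generator) -> np.ndarray:
    """Agar plate: near-uniform dark tint, pixel noise, faint bright scratches."""
    img = np.full((image_size, image_size, 3), bg.tint, dtype=np.float64)
    # slight brown cast so the plate is not gray
    img[..., 0] *= 1.15
    img[..., 2] *= 0.85
    img += rng.normal(0.0, bg.noise_sd, size=img.shape)
    for _ in range(bg.scratch_count):
        y0, x0, y1, x1 = rng.integers(0, image_size, size=4)
        n = int(max(abs(int(y1) - int(y0)), abs(int(x1) - int(x0))) + 1)
        ys = np.linspace(y0, y1, n).round().astype(int)
        xs = np.linspace(x0, x1, n).round().astype(int)
        img[ys, xs, :] += bg.scratch_contrast
    return img


def _paint_foreground(
    img: np.ndarray, mask: np.ndarray, fg: AppearanceParams, rng: Generator
) -> np.ndarray:
    """Overwrite mask pixels with speckled green plant tissue."""
    size = img.shape[0]
    # texture drawn for the full frame so it is independent of the mask shape
    speckle = rng.normal(1.0, fg.texture_sd, size=(size, size))
    base = np.array([fg.red, fg.green, fg.blue])
    tissue = base[None, None, :] * speckle[:, :, None]
    out = img.copy()
    out[mask] = tissue[mask]
    return out


def scale_bar_box(image_size: int) -> Tuple[int, int, int, int]:
    """Fixed-position scale-bar bounding box as (row0, col0, row1, col1), exclusive ends."""
    length = max(8, image_size // 5)
    height = max(2, image_size // 100)
    margin = max(3, image_size // 40)
    r1 = image_size - margin
    c1 = image_size - margin
    return (r1 - height, c1 - length, r1, c1)


def draw_scale_bar(img: np.ndarray) -> np.ndarray:
    """Paint a white scale bar at the fixed position; returns a copy."""
    r0, c0, r1, c1 = scale_bar_box(img.shape[0])
    out = img.copy()
    out[r0:r1, c0:c1, :] = 0.95
    return out


def render_plant(
    shape: ShapeParams,
    appearance: AppearanceParams,
    background: BackgroundParams,
    image_size: int,
    seed: int | SeedSequence,
) -> Tuple[np.ndarray, SilhouetteMask]:
    """Render one plant image plus the exact mask used to paint it.

    Foreground and background draw from independent child RNG streams of
    ``seed``, so two calls differing only in background parameters produce
    pixel-identical foregrounds.
    """
    if image_size < 64:
        raise ValueError("image_size must be >= 64")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    fg_ss, bg_ss = ss.spawn(2)
    mask = render_silhouette(shape, image_size)
    img = _paint_background(background, image_size, default_rng(bg_ss))
    img = _paint_foreground(img, mask, appearance, default_rng(fg_ss))
    img = np.clip(img, 0.0, 1.0)
    rgb = (img * 255.0).round().astype(np.uint8)
    return rgb, SilhouetteMask(mask, provenance="ground_truth")


# ---------------------------------------------------------------------------
# per-class parameter sampling
# ---------------------------------------------------------------------------


def _check_reachable(effects: ChannelEffects) -> None:
    """Fail early if an effect would push a class mean outside its support."""
    if abs(effects.color_effect) * SIGMA_HUE / 2.0 > 0.40:
        raise ValueError("unreachable effect size for channel 'color'")
    half = abs(effects.background_effect) * SIGMA_TINT / 2.0
    if not (_TINT_RANGE[0] + 2 * SIGMA_TINT <= _BASE_TINT - half
            and _BASE_TINT + half <= _TINT_RANGE[1] - 2 * SIGMA_TINT):
        raise ValueError("unreachable effect size for channel 'background'")
    half = abs(effects.contour_effect) * SIGMA_CONTOUR / 2.0
    if half > 0.5:  # centroid mean would leave the [0, 1] allocation range
        raise ValueError("unreachable effect size for channel 'contour'")


def sample_plant_params(
    effects: ChannelEffects,
    growth: GrowthModel,
    day: int,
    class_idx: int,
    image_size: int,
    rng: Generator,
) -> Tuple[ShapeParams, AppearanceParams, BackgroundParams]:
    """Draw one plant's latent parameters for the given class.

    Class effects split symmetrically: male (index 0) at -d/2, female (index 1)
    at +d/2 standardized units from the channel baseline.
    """
    sgn = -1.0 if class_idx == 0 else 1.0

    # -- area channel: log projected area, centered on the day's expected size
    r_base = growth.base_radius(image_size, day)
    mu_log_area = np.log(np.pi * r_base**2) + sgn * effects.area_effect * SIGMA_LOG_AREA / 2.0
    log_area = rng.normal(mu_log_area, SIGMA_LOG_AREA)
    target_area = float(np.exp(log_area))

    # -- contour channel: bilobed base + centroid-coded high harmonics.
    # Total high-harmonic amplitude is a (tightly controlled) nuisance; the
    # class effect shifts how that amplitude is split between the coarse
    # scallop harmonic and the fine crenellation harmonic.
    lobes = growth.lobe_count(day)
    lobe_amp = float(np.clip(rng.normal(0.22, 0.03), 0.10, 0.30))
    lobe_phase = rng.uniform(0, 2 * np.pi)
    amp_total = float(np.clip(
        rng.normal(_CONTOUR_AMP_MEAN, _CONTOUR_AMP_SD), *_CONTOUR_AMP_RANGE
    ))
    centroid = rng.normal(
        sgn * effects.contour_effect * SIGMA_CONTOUR / 2.0, SIGMA_CONTOUR
    )
    u = float(np.clip(0.5 + centroid, 0.0, 1.0))
    k_lo, k_hi = _CONTOUR_KS
    harmonics = [
        (int(lobes), lobe_amp, float(lobe_phase)),
        (int(k_lo), float(amp_total * (1.0 - u)), float(rng.uniform(0, 2 * np.pi))),
        (int(k_hi), float(amp_total * u), float(rng.uniform(0, 2 * np.pi))),
    ]

    # renormalize radius so harmonics leave expected area unchanged
    inflation = 1.0 + 0.5 * sum(a * a for _, a, _ in harmonics)
    radius = float(np.sqrt(target_area / (np.pi * inflation)))
    shape = ShapeParams(radius=radius, harmonics=tuple(harmonics))

    # -- color channel: tissue hue along a green <-> brown (chlorotic) axis.
    # The latent m mixes a green tissue pole with a brown one, so either
    # class pole is a positive surface color, not just the absence of green.
    m = float(np.clip(
        rng.normal(0.55 + sgn * effects.color_effect * SIGMA_HUE / 2.0, SIGMA_HUE),
        0.05, 0.95,
    ))
    green = float(np.clip(rng.normal(0.40 + 0.25 * m, SIGMA_GREEN), *_GREEN_RANGE))
    appearance = AppearanceParams(
        green=green,
        red=float(np.clip(0.20 + 0.55 * (1.0 - m), 0.0, 1.0)),
        blue=0.14,
    )

    # -- background channel: a plate-tint shift (spatially broad) together
    # with a scratch-density shift (localized off-plant cues)
    tint = rng.normal(
        _BASE_TINT + sgn * effects.background_effect * SIGMA_TINT / 2.0, SIGMA_TINT
    )
    rate = _BASE_SCRATCH_RATE * np.exp(0.23 * sgn * effects.background_effect)
    background = BackgroundParams(
        tint=float(np.clip(tint, *_TINT_RANGE)),
        scratch_count=int(rng.poisson(rate)),
    )
    return shape, appearance, background


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    config: SyntheticDatasetConfig,
) -> List[Tuple[ImageRecord, SilhouetteMask]]:
    """Generate a balanced labeled dataset per the config.

    Returns ``2 * n_per_class * len(days)`` (record, mask) pairs; each record
    also carries its ground-truth mask. Deterministic: identical config (incl.
    seed) yields a bit-identical image set.
    """
    _check_reachable(config.effects)
    root = SeedSequence(config.seed)
    out: List[Tuple[ImageRecord, SilhouetteMask]] = []
    for day in config.day_list:
        for class_idx, label in enumerate(LABELS):
            for i in range(config.n_per_class):
                (param_ss, render_ss) = root.spawn(2)
                rng = default_rng(param_ss)
                shape, fg, bg = sample_plant_params(
                    config.effects, config.growth, day, class_idx, config.image_size, rng
                )
                # retry with shrunken harmonics if an extreme draw cannot be framed
                for _ in range(8):
                    try:
                        img, mask = render_plant(shape, fg, bg, config.image_size, render_ss)
                        break
                    except ValueError:
                        shape = replace(
                            shape,
                            radius=shape.radius * 0.9,
                            harmonics=tuple((k, a * 0.8, p) for k, a, p in shape.harmonics),
                        )
                else:  # pragma: no cover - parameters above make this unreachable
                    raise RuntimeError("could not render plant within frame")
                if config.scale_bar:
                    raw = img.astype(np.float64) / 255.0
                    img = (draw_scale_bar(raw) * 255.0).round().astype(np.uint8)
                rec = ImageRecord(
                    id=f"{config.line}-d{day}-{label}-{i:04d}",
                    pixels=img,
                    label=label,
                    line=config.line,
                    day=day,
                    mask=mask,
                )
                out.append((rec, mask))
    return out


def generate_pretext_dataset(
    n_lines: int = 10,
    n_per_line: int = 36,
    image_size: int = 64,
    seed: int = 1234,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Generic plant-variation pretext set for backbone pretraining.

    Draws ``n_lines`` pseudo-accessions, each a random bundle of line-level
    morphology (size, green level, contour crenellation, background tint,
    scratch rate, texture), and renders ``n_per_line`` images per line across
    the day schedule. The pretext labels are the line identities; learning to
    tell lines apart forces the features to encode all morphological
    channels. Images from this set never appear in downstream experiments
    (independent seed stream).

    Returns (raw uint8 images, integer line labels).
    """
    root = SeedSequence([seed, 0xBACB])
    line_rng = default_rng(root.spawn(1)[0])
    growth = GrowthModel(day=3)
    lines = []
    for _ in range(n_lines):
        lines.append(dict(
            radius_scale=line_rng.uniform(0.7, 1.3),
            green=line_rng.uniform(0.40, 0.70),
            contour=line_rng.uniform(0.0, 1.0),  # spectral-centroid level
            tint=line_rng.uniform(0.06, 0.16),
            scratch_rate=line_rng.uniform(1.0, 6.0),
            texture_sd=line_rng.uniform(0.04, 0.12),
        ))
    images, labels = [], []
    for li, line in enumerate(lines):
        for j in range(n_per_line):
            img_ss = root.spawn(1)[0]
            rng = default_rng(img_ss)
            day = DAY_SCHEDULE[rng.integers(0, len(DAY_SCHEDULE))]
            r_base = growth.base_radius(image_size, day) * line["radius_scale"]
            log_area = rng.normal(np.log(np.pi * r_base**2), SIGMA_LOG_AREA)
            lobes = growth.lobe_count(day)
            harmonics = [(lobes, float(np.clip(rng.normal(0.22, 0.03), 0.1, 0.3)),
                          float(rng.uniform(0, 2 * np.pi)))]
            amp = float(np.clip(rng.normal(0.24, 0.03), 0.05, 0.32))
            u = float(np.clip(rng.normal(line["contour"], SIGMA_CONTOUR), 0, 1))
            for k, frac in zip(_CONTOUR_KS, (1.0 - u, u)):
                harmonics.append((int(k), amp * frac,
                                  float(rng.uniform(0, 2 * np.pi))))
            inflation = 1.0 + 0.5 * sum(a * a for _, a, _ in harmonics)
            radius = float(np.sqrt(np.exp(log_area) / (np.pi * inflation)))
            radius = min(radius, (image_size / 2.0 - 3) / (1 + sum(a for _, a, _ in harmonics)))
            shape = ShapeParams(radius=radius, harmonics=tuple(harmonics))
            fg = AppearanceParams(
                green=float(np.clip(rng.normal(line["green"], SIGMA_GREEN), *_GREEN_RANGE)),
                texture_sd=line["texture_sd"],
            )
            bg = BackgroundParams(
                tint=float(np.clip(rng.normal(line["tint"], SIGMA_TINT), *_TINT_RANGE)),
                scratch_count=int(rng.poisson(line["scratch_rate"])),
            )
            img, _ = render_plant(shape, fg, bg, image_size, root.spawn(1)[0])
            img = (draw_scale_bar(img.astype(np.float64) / 255.0) * 255).round().astype(np.uint8)
            images.append(img)
            labels.append(li)
    return images, np.asarray(labels)


def dataset_sha256(dataset: Sequence[Tuple[ImageRecord, SilhouetteMask]]) -> str:
    """SHA-256 over all image and mask bytes, in generation order."""
    h = hashlib.sha256()
    for rec, mask in dataset:
        h.update(rec.id.encode())
        h.update(np.ascontiguousarray(rec.pixels).tobytes())
        h.update(np.packbits(mask.pixels).tobytes())
    return h.hexdigest()


def write_dataset(
    dataset: Sequence[Tuple[ImageRecord, SilhouetteMask]], outdir: str | Path
) -> pd.DataFrame:
    """Write images/masks as PNG plus a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, mask in dataset:
        ipath = outdir / "images" / f"{rec.id}.png"
        mpath = outdir / "masks" / f"{rec.id}.png"
        Image.fromarray(rec.pixels, mode="RGB").save(ipath)
        Image.fromarray((mask.pixels.astype(np.uint8) * 255), mode="L").save(mpath)
        rows.append(
            dict(id=rec.id, label=rec.label, line=rec.line, day=rec.day,
                 path=str(ipath), mask_path=str(mpath))
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> List[Tuple[ImageRecord, SilhouetteMask]]:
    """Load a dataset previously written by :func:`write_dataset`."""
    manifest = pd.read_csv(manifest_path)
    out = []
    for row in manifest.itertuples():
        img = np.asarray(Image.open(row.path).convert("RGB"))
        mpix = np.asarray(Image.open(row.mask_path).convert("L")) > 127
        mask = SilhouetteMask(mpix, provenance="ground_truth")
        rec = ImageRecord(
            id=str(row.id), pixels=img, label=str(row.label),
            line=str(row.line), day=int(row.day), mask=mask,
        )
        out.append((rec, mask))
    return out
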