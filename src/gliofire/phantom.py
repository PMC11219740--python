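"""Synthetic 2D MRI-like slice generator with ground truth.

Produces axial-slice phantoms that emulate the data the rest of the
pipeline is built for: a dark constant background, an elliptical brain
made of a few concentric tissue bands of distinct mean intensity, and
zero or more planted tumor blobs that are brighter than every tissue
band at least at their rim.  High-grade (HGG-like) tumors get a
heterogeneous, speckled core; low-grade (LGG-like) tumors a flat,
moderate-intensity core.  Every sample carries its ground-truth brain
mask, tumor mask, per-pixel tissue labels and the planted intensity
levels, so segmentation and classification can be scored exactly.

Intensities are generated on the 8-bit 0..255 scale and returned as a
float image in [0, 1].  Additive Gaussian noise is applied inside the
brain only; the background stays at a constant dark level below the
0.05 binarization threshold used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

HGG = "HGG"
LGG = "LGG"

__all__ = ["PhantomSpec", "PhantomSample", "generate_slice", "generate_dataset", "HGG", "LGG"]


class InvalidSpecError(ValueError):
    """Raised when a PhantomSpec violates its geometric or intensity invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``band_intensities`` are listed from the innermost elliptical band
    outwards.  ``background_level`` is an intensity fraction of full
    scale and must stay strictly below the 0.05 binarization threshold.
    """

    image_height: int = 200
    image_width: int = 200
    background_level: float = 0.02
    brain_center: tuple[float, float] | None = None   # (row, col); None = image center
    brain_semiaxes: tuple[float, float] | None = None  # (a_row, a_col); None = 0.38H, 0.32W
    band_intensities: tuple[float, ...] = (60.0, 110.0, 160.0)
    tumor_count: int = 1
    tumor_radius: float = 18.0
    tumor_rim_width: float = 2.0
    tumor_rim_intensity: float = 235.0
    tumor_core_intensity: float = 210.0
    core_heterogeneity_sd: float = 30.0
    noise_sd: float = 5.0
    class_label: str = HGG
    seed: int = 0

    @staticmethod
    def for_class(label: str, **overrides) -> "PhantomSpec":
        """Class-conditioned presets: HGG-like tumors are bright-rimmed and
        heterogeneous, LGG-like ones homogeneous and of moderate intensity."""
        if label == HGG:
            base = dict(tumor_core_intensity=210.0, core_heterogeneity_sd=30.0)
        elif label == LGG:
            base = dict(tumor_core_intensity=185.0, core_heterogeneity_sd=0.0)
        else:
            raise InvalidSpecError(f"unknown class label {label!r}")
        base.update(overrides)
        return PhantomSpec(class_label=label, **base)

    # -- derived geometry -------------------------------------------------
    def center(self) -> tuple[float, float]:
        if self.brain_center is not None:
            return self.brain_center
        return (self.image_height / 2.0, self.image_width / 2.0)

    def semiaxes(self) -> tuple[float, float]:
        if self.brain_semiaxes is not None:
            return self.brain_semiaxes
        return (0.38 * self.image_height, 0.32 * self.image_width)

    def validate(self) -> None:
        if self.image_height < 16 or self.image_width < 16:
            raise InvalidSpecError("image dimensions must be at least 16x16")
        if not 0.0 <= self.background_level:
            raise InvalidSpecError("background_level must be non-negative")
        if self.background_level >= 0.05:
            raise InvalidSpecError(
                "background_level must stay strictly below the 0.05 binarization threshold"
            )
        cr, cc = self.center()
        ar, ac = self.semiaxes()
        if ar <= 0 or ac <= 0:
            raise InvalidSpecError("brain semi-axes must be positive")
        if cr - ar < 0 or cr + ar > self.image_height or cc - ac < 0 or cc + ac > self.image_width:
            raise InvalidSpecError("brain ellipse exceeds image bounds")
        if len(self.band_intensities) < 1:
            raise InvalidSpecError("at least one tissue band is required")
        bands = np.sort(np.asarray(self.band_intensities, dtype=float))
        if bands[0] < 0 or bands[-1] > 255:
            raise InvalidSpecError("band intensities must lie in [0, 255]")
        if len(bands) > 1 and np.min(np.diff(bands)) < 4.0 * self.noise_sd:
            raise InvalidSpecError("band intensities must be separated by >= 4 x noise_sd")
        if self.tumor_count < 0:
            raise InvalidSpecError("tumor_count must be >= 0")
        if self.tumor_count > 0:
            if self.tumor_rim_intensity <= bands[-1]:
                raise InvalidSpecError("tumor rim must be strictly brighter than every band")
            if self.tumor_radius <= self.tumor_rim_width:
                raise InvalidSpecError("tumor radius must exceed its rim width")


@dataclass
class PhantomSample:
    """One rendered slice plus its ground truth."""

    image: np.ndarray          # float in [0, 1], shape (H, W)
    brain_mask: np.ndarray     # bool
    tumor_mask: np.ndarray     # bool, subset of brain_mask
    tissue_labels: np.ndarray  # int, 0 outside brain; 1..nb bands, nb+1 core, nb+2 rim
    planted_band_intensities: list[float]
    class_label: str
    spec: PhantomSpec = field(repr=False, default=None)


def _elliptic_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized elliptical radius rho; rho <= 1 is inside the brain."""
    cr, cc = spec.center()
    ar, ac = spec.semiaxes()
    rr, cc_grid = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
    return np.sqrt(((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2)


def _place_tumors(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Tumor centers inside the brain, pairwise non-overlapping, fully interior."""
    cr, cc = spec.center()
    ar, ac = spec.semiaxes()
    centers: list[tuple[float, float]] = []
    # keep the whole disk at elliptical radius < ~0.85 so it never leaves the brain
    max_rho = max(0.05, 0.85 - spec.tumor_radius / min(ar, ac))
    for _ in range(spec.tumor_count):
        for _attempt in range(200):
            rho = rng.uniform(0.15, max_rho)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            r0 = cr + rho * ar * np.sin(theta)
            c0 = cc + rho * ac * np.cos(theta)
            if all(
                np.hypot(r0 - r1, c0 - c1) > 2.0 * spec.tumor_radius + 2.0
                for r1, c1 in centers
            ):
                centers.append((r0, c0))
                break
        else:
            raise InvalidSpecError("could not place non-overlapping tumors; reduce count/radius")
    return centers


def generate_slice(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom slice deterministically from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    nb = len(spec.band_intensities)

    rho = _elliptic_radius(spec)
    brain = rho <= 1.0
    # concentric equal-width elliptical bands, innermost first
    band_idx = np.minimum((rho * nb).astype(int), nb - 1)
    labels = np.where(brain, band_idx + 1, 0)

    img = np.full((h, w), spec.background_level * 255.0, dtype=float)
    bands = np.asarray(spec.band_intensities, dtype=float)
    img[brain] = bands[band_idx[brain]]

    tumor_mask = np.zeros((h, w), dtype=bool)
    if spec.tumor_count > 0:
        rr, cc_grid = np.mgrid[0:h, 0:w]
        for r0, c0 in _place_tumors(spec, rng):
            dist = np.hypot(rr - r0, cc_grid - c0)
            disk = (dist <= spec.tumor_radius) & brain
            core = (dist <= spec.tumor_radius - spec.tumor_rim_width) & brain
            rim = disk & ~core
            img[core] = spec.tumor_core_intensity
            if spec.core_heterogeneity_sd > 0:
                # tissue-scale heterogeneity: a smoothed random field rather
                # than pixel-scale speckle, so the texture survives resampling
                # and is spatially structured (necrotic/cystic-like patches)
                field = rng.normal(0.0, 1.0, (h, w))
                field = gaussian_filter(field, sigma=1.5)
                field *= spec.core_heterogeneity_sd / field[core].std()
                img[core] += field[core]
            img[rim] = spec.tumor_rim_intensity
            labels[core] = nb + 1
            labels[rim] = nb + 2
            tumor_mask |= disk

    if spec.noise_sd > 0:
        img[brain] += rng.normal(0.0, spec.noise_sd, int(brain.sum()))
    img = np.clip(img, 0.0, 255.0) / 255.0

    planted = list(bands)
    if spec.tumor_count > 0:
        planted += [spec.tumor_core_intensity, spec.tumor_rim_intensity]
    return PhantomSample(
        image=img,
        brain_mask=brain,
        tumor_mask=tumor_mask,
        tissue_labels=labels,
        planted_band_intensities=planted,
        class_label=spec.class_label,
        spec=spec,
    )


def generate_dataset(
    n: int,
    class_balance: float = 0.51,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    jitter: bool = True,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms, ``floor(n * class_balance)`` of them HGG-like.

    Per-sample seeds and mild geometric/intensity jitter are derived
    reproducibly from the master seed, so two calls with the same
    arguments return element-wise identical datasets.  With the default
    balance of 0.51, n = 500 yields the 255/245 HGG/LGG split of a
    500-slice study.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie strictly inside (0, 1)")
    template = spec_template if spec_template is not None else PhantomSpec()
    n_hgg = int(np.floor(n * class_balance))
    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for i in range(n):
        label = HGG if i < n_hgg else LGG
        sub_seed = int(master.integers(0, 2**31 - 1))
        jrng = np.random.default_rng(sub_seed)
        spec = PhantomSpec.for_class(
            label,
            image_height=template.image_height,
            image_width=template.image_width,
            background_level=template.background_level,
            band_intensities=template.band_intensities,
            tumor_count=template.tumor_count,
            tumor_radius=template.tumor_radius,
            tumor_rim_width=template.tumor_rim_width,
            tumor_rim_intensity=template.tumor_rim_intensity,
            noise_sd=template.noise_sd,
            seed=sub_seed,
        )
        if jitter:
            ar, ac = spec.semiaxes()
            spec = replace(
                spec,
                brain_semiaxes=(ar * jrng.uniform(0.92, 1.0), ac * jrng.uniform(0.92, 1.0)),
                tumor_radius=spec.tumor_radius * jrng.uniform(0.85, 1.15),
            )
        samples.append(generate_slice(spec))
    return samples
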