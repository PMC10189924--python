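"""Synthetic multi-site, multi-class slide cohorts.

Real multi-hospital H&E cohorts carry two classes of signal: the morphology
that distinguishes cancer types, and acquisition-site fingerprints — each
hospital's stain chemistry shifts the color spectrum, and each scanner leaves
a characteristic low-amplitude noise texture.  The generator emulates both
with a single site-effect knob ``alpha``:

* stain: per-site 3×3 color-mixing matrix ``I + alpha·Δ`` with ``Δ`` entries
  drawn once per site in [−0.15, 0.15];
* noise: a fixed per-site band-limited Gaussian texture added at amplitude
  ``alpha · 0.05`` of the dynamic range.

At ``alpha = 0`` every site produces identically distributed patches, giving
an exact null for calibration; raising ``alpha`` strengthens the site
fingerprint without touching class morphology.  Cohorts can be produced as
rendered patch images (elliptical dark "nuclei" on a pale eosin background,
density and size set by the class) or directly in feature space (class mean +
``alpha``·site shift + isotropic noise), the fast path for probe and search
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import exposure, transform

from .features import SlideFeatures
from .metadata import MANIFEST_COLUMNS

# Stream tags for deriving independent RNG streams from the cohort seed.
_STREAM_MANIFEST = 0
_STREAM_SITE_EFFECTS = 1
_STREAM_FEATURE_MODEL = 2
_STREAM_SLIDE = 3

#: Per-site stain deviation range (entries of Δ).
STAIN_DELTA_RANGE = 0.15
#: Noise texture amplitude per unit alpha, as a fraction of dynamic range.
NOISE_AMPLITUDE_PER_ALPHA = 0.05
#: Feature-space isotropic noise norm (expected ||eps||); class means and
#: site shift directions are unit vectors, so alpha is expressed in units of
#: the class-separation scale.
FEATURE_NOISE_NORM = 0.5

_BACKGROUND = np.array([0.91, 0.83, 0.90])
_NUCLEUS = np.array([0.36, 0.27, 0.55])


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``site_shares`` defaults to equal shares and ``class_given_site`` to a
    uniform class distribution at every site; pass explicit tables to emulate
    the strongly imbalanced site × class composition of real consortium
    cohorts (see :func:`imbalanced_class_given_site`).
    """

    n_sites: int
    n_classes: int
    n_slides: int
    site_shares: Sequence[float] | None = None
    class_given_site: Sequence[Sequence[float]] | None = None
    patches_per_slide: int = 55
    patch_px: int = 128
    multi_slide_patient_frac: float = 0.07
    site_effect_alpha: float = 1.0
    feature_dim: int = 1024
    balanced_classes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_classes < 1 or self.n_slides < 1:
            raise ValueError("n_sites, n_classes and n_slides must be positive")
        if self.patches_per_slide < 1 or self.patch_px < 32:
            raise ValueError("patches_per_slide must be >= 1 and patch_px >= 32")
        if self.site_effect_alpha < 0:
            raise ValueError("site_effect_alpha must be nonnegative")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.site_shares is None:
            self.site_shares = [1.0 / self.n_sites] * self.n_sites
        self.site_shares = [float(s) for s in self.site_shares]
        if len(self.site_shares) != self.n_sites:
            raise ValueError(
                f"site_shares has length {len(self.site_shares)}, expected {self.n_sites}"
            )
        if abs(sum(self.site_shares) - 1.0) > 1e-9:
            raise ValueError("site_shares must sum to 1")
        if self.class_given_site is None:
            self.class_given_site = [
                [1.0 / self.n_classes] * self.n_classes for _ in range(self.n_sites)
            ]
        self.class_given_site = [[float(p) for p in row] for row in self.class_given_site]
        if len(self.class_given_site) != self.n_sites or any(
            len(row) != self.n_classes for row in self.class_given_site
        ):
            raise ValueError("class_given_site must be n_sites × n_classes")
        for row in self.class_given_site:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("each class_given_site row must sum to 1")
        if not 0.0 <= self.multi_slide_patient_frac < 1.0:
            raise ValueError("multi_slide_patient_frac must be in [0, 1)")


@dataclass(frozen=True)
class SiteEffect:
    """One site's acquisition fingerprint: stain mixing and noise texture."""

    stain_matrix: np.ndarray
    noise_texture_seed: int
    noise_amplitude: float


@dataclass
class SlidePatches:
    """Rendered patches of one slide, with grid coordinates and nucleus masks."""

    slide_id: str
    rasters: list[np.ndarray]
    coords: list[tuple[int, int, int]]
    masks: list[np.ndarray] | None = None


def site_code(i: int) -> str:
    """Two-character site code (base-36), mirroring a TSS code."""
    digits = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if not 0 <= i < 36 * 36:
        raise ValueError("at most 1296 sites supported")
    return digits[i // 36] + digits[i % 36]


def project_name(class_id: int) -> str:
    return f"SYN{class_id:02d}"


def project_class_index(project: str) -> int:
    if not project.startswith("SYN"):
        raise ValueError(f"not a synthetic project name: {project!r}")
    return int(project[3:])


def largest_remainder(shares: Sequence[float], total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``shares``.

    Largest-remainder rounding: every count differs from ``share·total`` by
    less than 1 and the counts sum exactly to ``total``.
    """
    shares = np.asarray(shares, dtype=float)
    quotas = shares / shares.sum() * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.lexsort((np.arange(len(shares)), -(quotas - counts)))
    counts[order[:remainder]] += 1
    return counts


def make_site_effects(config: CohortConfig) -> list[SiteEffect]:
    """Draw each site's stain deviation and noise seed once from the cohort seed."""
    rng = np.random.default_rng([config.seed, _STREAM_SITE_EFFECTS])
    effects = []
    for _ in range(config.n_sites):
        delta = rng.uniform(-STAIN_DELTA_RANGE, STAIN_DELTA_RANGE, size=(3, 3))
        tex_seed = int(rng.integers(0, 2**31 - 1))
        effects.append(
            SiteEffect(
                stain_matrix=np.eye(3) + config.site_effect_alpha * delta,
                noise_texture_seed=tex_seed,
                noise_amplitude=config.site_effect_alpha * NOISE_AMPLITUDE_PER_ALPHA,
            )
        )
    return effects


def generate_manifest(config: CohortConfig) -> pd.DataFrame:
    """Build the slide manifest: per-site counts, patients, classes.

    Both slides of a multi-slide patient share the site and the cancer
    project, as in real cohorts.  With ``balanced_classes`` each site's
    patient classes follow its ``class_given_site`` row deterministically
    (largest-remainder counts, randomly ordered) instead of independent
    draws, pinning the realized site × class composition to its expectation —
    the design needed for exact null calibration.
    """
    rng = np.random.default_rng([config.seed, _STREAM_MANIFEST])
    counts = largest_remainder(config.site_shares, config.n_slides)
    rows = []
    participant = 0
    f = config.multi_slide_patient_frac
    for s, c_s in enumerate(counts):
        code = site_code(s)
        institution = f"Hospital {code}"
        n_double = int(round(c_s * f / (1.0 + f)))
        n_double = min(n_double, c_s // 2)
        probs = np.asarray(config.class_given_site[s])
        patients = [2] * n_double + [1] * (c_s - 2 * n_double)
        if config.balanced_classes:
            class_counts = largest_remainder(probs, len(patients))
            class_pool = np.repeat(np.arange(config.n_classes), class_counts)
            class_pool = rng.permutation(class_pool)
        for p_idx, n_slides_patient in enumerate(patients):
            participant += 1
            patient_id = f"TCGA-{code}-{participant:04d}"
            if config.balanced_classes:
                cls = int(class_pool[p_idx])
            else:
                cls = int(rng.choice(config.n_classes, p=probs))
            for k in range(n_slides_patient):
                rows.append(
                    {
                        "slide_id": f"{patient_id}-{k + 1:02d}Z",
                        "patient_id": patient_id,
                        "site_code": code,
                        "institution": institution,
                        "project": project_name(cls),
                    }
                )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# image mode

def class_morphology(class_id: int | None) -> tuple[float, float]:
    """Nucleus density (expected count per 128×128 px) and radius for a class.

    ``class_id=None`` denotes the blank class: zero density, background only.
    """
    if class_id is None:
        return 0.0, 4.0
    density = 60.0 + 50.0 * class_id
    radius = 4.0 + 1.1 * (class_id % 3)
    return density, radius


@lru_cache(maxsize=256)
def _noise_texture(seed: int, patch_px: int) -> np.ndarray:
    """Fixed band-limited noise field for one site: unit-std, zero-mean, 3-channel."""
    rng = np.random.default_rng(seed)
    coarse_px = max(patch_px // 8, 2)
    coarse = rng.normal(size=(coarse_px, coarse_px, 3))
    field = transform.resize(
        coarse, (patch_px, patch_px, 3), order=3, mode="reflect", anti_aliasing=False
    )
    field -= field.mean(axis=(0, 1))
    field /= field.std(axis=(0, 1))
    return field


def render_patch(
    class_id: int | None,
    site_effect: SiteEffect,
    rng: np.random.Generator,
    patch_px: int = 128,
    density: float | None = None,
    radius: float | None = None,
    return_mask: bool = False,
):
    """Render one RGB patch: class morphology, then the site's stain and noise.

    Elliptical dark nuclei are placed uniformly at a class-dependent density
    and size on a pale background, the pixel colors are mixed through the
    site's stain matrix, the site's fixed noise texture is added, and the
    result is clipped to [0, 1].  With ``return_mask`` the ground-truth
    nucleus-pixel mask (pre-stain) is returned alongside.
    """
    if patch_px < 32:
        raise ValueError("patch_px must be >= 32")
    base_density, base_radius = class_morphology(class_id)
    if density is None:
        density = base_density
    if radius is None:
        radius = base_radius
    scale = patch_px / 128.0
    img = np.tile(_BACKGROUND, (patch_px, patch_px, 1)).astype(float)
    mask = np.zeros((patch_px, patch_px), dtype=bool)
    n_nuclei = rng.poisson(density * scale * scale)
    yy, xx = np.mgrid[0:patch_px, 0:patch_px]
    for _ in range(n_nuclei):
        cx, cy = rng.uniform(0, patch_px, size=2)
        a = radius * scale * rng.lognormal(0.0, 0.15)
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = np.clip(_NUCLEUS + rng.normal(0, 0.03, size=3), 0, 1)
        img[inside] = color
        mask |= inside
    img = np.clip(img @ site_effect.stain_matrix.T, 0.0, 1.0)
    if site_effect.noise_amplitude > 0:
        img = img + site_effect.noise_amplitude * _noise_texture(
            site_effect.noise_texture_seed, patch_px
        )
        img = np.clip(img, 0.0, 1.0)
    if return_mask:
        return img, mask
    return img


def amplify_noise(patch: np.ndarray) -> np.ndarray:
    """Histogram-equalize each channel to surface low-amplitude noise textures.

    A diagnostic, not a processing step: equalization stretches faint
    background structure to full contrast, making per-site noise fingerprints
    visible.  A constant-valued channel is returned unchanged (equalization
    of a degenerate histogram is undefined).
    """
    img = np.asarray(patch, dtype=float)
    out = img.copy()
    for c in range(img.shape[2]):
        chan = img[..., c]
        if np.ptp(chan) == 0:
            continue
        out[..., c] = exposure.equalize_hist(chan)
    return out


def generate_cohort(config: CohortConfig, mode: str = "images"):
    """Generate a full cohort: manifest plus a patch store or feature store.

    Returns ``(manifest, store)`` where the store maps ``slide_id`` to
    :class:`SlidePatches` (``mode="images"``) or :class:`SlideFeatures`
    (``mode="features"``).  A pure function of the config, including its seed.
    """
    if mode == "features":
        return generate_feature_cohort(config)
    if mode != "images":
        raise ValueError(f"unknown mode {mode!r}")
    manifest = generate_manifest(config)
    effects = make_site_effects(config)
    code_to_idx = {site_code(i): i for i in range(config.n_sites)}
    store: dict[str, SlidePatches] = {}
    for slide_idx, row in enumerate(manifest.itertuples(index=False)):
        rng = np.random.default_rng([config.seed, _STREAM_SLIDE, slide_idx])
        effect = effects[code_to_idx[row.site_code]]
        cls = project_class_index(row.project)
        rasters, coords, masks = [], [], []
        for p in range(config.patches_per_slide):
            raster, m = render_patch(
                cls, effect, rng, patch_px=config.patch_px, return_mask=True
            )
            rasters.append(raster)
            coords.append((p * config.patch_px, 0, 0))
            masks.append(m)
        store[row.slide_id] = SlidePatches(row.slide_id, rasters, coords, masks)
    return manifest, store


# ---------------------------------------------------------------------------
# feature mode

def _unit_rows(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    m = rng.normal(size=(n, d))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def generate_feature_cohort(config: CohortConfig):
    """Generate the cohort directly in feature space (fast path).

    Each patch vector is ``mu_class + alpha·u_site + eps`` with unit-norm
    class means and site shift directions drawn once per cohort and isotropic
    noise of expected norm ``FEATURE_NOISE_NORM``.  ``alpha`` therefore
    measures the site shift in units of the class-separation scale.
    """
    manifest = generate_manifest(config)
    d = config.feature_dim
    model_rng = np.random.default_rng([config.seed, _STREAM_FEATURE_MODEL])
    class_means = _unit_rows(model_rng, config.n_classes, d)
    site_shifts = _unit_rows(model_rng, config.n_sites, d)
    sigma = FEATURE_NOISE_NORM / math.sqrt(d)
    code_to_idx = {site_code(i): i for i in range(config.n_sites)}
    alpha = config.site_effect_alpha
    store: dict[str, SlideFeatures] = {}
    for slide_idx, row in enumerate(manifest.itertuples(index=False)):
        rng = np.random.default_rng([config.seed, _STREAM_SLIDE, slide_idx])
        mu = class_means[project_class_index(row.project)]
        shift = site_shifts[code_to_idx[row.site_code]]
        X = mu + alpha * shift + rng.normal(0, sigma, size=(config.patches_per_slide, d))
        store[row.slide_id] = SlideFeatures(
            row.slide_id, X, extractor="synthetic", version="v1"
        )
    return manifest, store


def imbalanced_class_given_site(
    n_sites: int, n_classes: int, n_single_class_sites: int, seed: int = 0
) -> list[list[float]]:
    """Site × class composition emulating a consortium cohort's imbalance.

    The first ``n_single_class_sites`` sites contribute a single class each
    (round-robin over classes); the rest get a Dirichlet-skewed mixture, so
    no two sites share a class profile.
    """
    if n_single_class_sites > n_sites:
        raise ValueError("n_single_class_sites cannot exceed n_sites")
    rng = np.random.default_rng([seed, 17])
    table: list[list[float]] = []
    for s in range(n_sites):
        if s < n_single_class_sites:
            row = [0.0] * n_classes
            row[s % n_classes] = 1.0
        else:
            row = list(rng.dirichlet(np.full(n_classes, 0.6)))
        table.append(row)
    return table
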