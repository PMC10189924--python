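"""Per-patch feature extraction behind a pluggable extractor contract.

An *extractor* is any callable mapping an RGB raster (H×W×3 float array in
[0, 1]) to a fixed-width real vector, deterministically for fixed parameters,
and exposing ``name``, ``version`` and ``dim`` attributes.  The shipped
:class:`BaselineExtractor` is a handcrafted, weight-free descriptor (color
histograms, gradient-orientation histogram, local-variance pyramid, fixed
seeded random projection to ``d`` dimensions), so the whole downstream
pipeline runs with no trained network.  Adapters wrapping pretrained CNNs can
be plugged in through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

#: Default feature width, matching the last-pooling width of the deep
#: networks commonly used as frozen pathology feature extractors.
DEFAULT_DIM = 1024

#: Seed of the shipped random-projection constant (version tag "v1").
_PROJECTION_SEED = 20230517


@dataclass
class SlideFeatures:
    """Feature matrix for one slide: one row per patch, ``d`` columns."""

    slide_id: str
    X: np.ndarray
    extractor: str = "unknown"
    version: str = "0"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D (n_patches × d)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"non-finite feature values for slide {self.slide_id}")

    @property
    def n_patches(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


@runtime_checkable
class Extractor(Protocol):
    name: str
    version: str
    dim: int

    def __call__(self, raster: np.ndarray) -> np.ndarray: ...


def _luminance(img: np.ndarray) -> np.ndarray:
    return img @ np.array([0.299, 0.587, 0.114])


class BaselineExtractor:
    """Deterministic handcrafted patch descriptor projected to ``dim``.

    Raw descriptor blocks:

    ``color``
        Per-channel intensity histograms (32 bins × 3 channels), L1-normalized.
        Invariant to any spatial permutation of pixels; sensitive to stain.
    ``gradient``
        Axial gradient-orientation histogram (18 bins over [0, π)), weighted
        by gradient magnitude on the luminance channel.  Sensitive to
        morphology (edge structure), nearly invariant to global color shifts.
    ``variance``
        Local-variance pyramid: mean and standard deviation of the luminance
        local variance at block scales 2, 4, 8 and 16 pixels (8 values),
        capturing texture/noise energy across frequencies.

    The concatenated descriptor is mapped to ``dim`` by a fixed Gaussian
    random projection generated once from a shipped seed, so features are
    bit-reproducible across runs and machines.
    """

    name = "baseline"
    version = "v1"

    _N_COLOR_BINS = 32
    _N_ORI_BINS = 18
    _PYRAMID_SCALES = (2, 4, 8, 16)

    def __init__(self, dim: int = DEFAULT_DIM):
        self.dim = dim
        raw_dim = 3 * self._N_COLOR_BINS + self._N_ORI_BINS + 2 * len(self._PYRAMID_SCALES)
        rng = np.random.default_rng(_PROJECTION_SEED)
        self._projection = rng.normal(size=(raw_dim, dim)) / np.sqrt(raw_dim)

    def raw_descriptor(self, raster: np.ndarray) -> dict[str, np.ndarray]:
        img = np.asarray(raster, dtype=float)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("expected an H×W×3 RGB raster")
        return {
            "color": self._color_block(img),
            "gradient": self._gradient_block(img),
            "variance": self._variance_block(img),
        }

    def __call__(self, raster: np.ndarray) -> np.ndarray:
        blocks = self.raw_descriptor(raster)
        raw = np.concatenate([blocks["color"], blocks["gradient"], blocks["variance"]])
        return raw @ self._projection

    def _color_block(self, img: np.ndarray) -> np.ndarray:
        hists = []
        for c in range(3):
            h, _ = np.histogram(img[..., c], bins=self._N_COLOR_BINS, range=(0.0, 1.0))
            hists.append(h / max(h.sum(), 1))
        return np.concatenate(hists)

    def _gradient_block(self, img: np.ndarray) -> np.ndarray:
        lum = _luminance(img)
        gy, gx = np.gradient(lum)
        mag = np.hypot(gx, gy)
        # axial orientation in [0, pi): invariant to 180-degree rotation
        ori = np.mod(np.arctan2(gy, gx), np.pi)
        h, _ = np.histogram(
            ori.ravel(), bins=self._N_ORI_BINS, range=(0.0, np.pi), weights=mag.ravel()
        )
        total = h.sum()
        return h / total if total > 0 else h

    def _variance_block(self, img: np.ndarray) -> np.ndarray:
        lum = _luminance(img)
        out = []
        for s in self._PYRAMID_SCALES:
            hh = (lum.shape[0] // s) * s
            ww = (lum.shape[1] // s) * s
            if hh == 0 or ww == 0:
                out.extend([0.0, 0.0])
                continue
            blocks = lum[:hh, :ww].reshape(hh // s, s, ww // s, s)
            local_var = blocks.var(axis=(1, 3))
            out.extend([float(local_var.mean()), float(local_var.std())])
        return np.asarray(out)


class SiteAwareExtractor:
    """Oracle extractor: baseline descriptor plus an explicit site-cue channel.

    Wraps a base extractor and injects a low-dimensional encoding of the true
    site effect (stain-matrix deviation and noise amplitude) into the last 10
    feature dimensions.  This emulates a feature extractor whose training has
    absorbed site-identifying signal, providing an upper-contrast reference
    against the plain baseline; it requires ground-truth site effects and is
    only meaningful on synthetic cohorts.
    """

    version = "v1"

    def __init__(self, base: Extractor, cue_scale: float = 1.0):
        self.base = base
        self.dim = base.dim
        self.name = f"{base.name}+site_cue"
        self.cue_scale = cue_scale
        self._cue: np.ndarray | None = None

    def bind_site(self, site_effect) -> "SiteAwareExtractor":
        """Set the site whose cue is appended to subsequently extracted patches.

        The cue is the *direction* of the site's stain deviation at unit norm
        (plus a normalized noise amplitude), so its magnitude is commensurate
        with the base features regardless of how weak the physical effect is;
        at zero site effect the cue vanishes and the oracle has no advantage.
        """
        dev = (np.asarray(site_effect.stain_matrix, dtype=float) - np.eye(3)).ravel()
        norm = np.linalg.norm(dev)
        dev_dir = dev / norm if norm > 0 else dev
        amp = site_effect.noise_amplitude
        self._cue = np.concatenate([dev_dir, [min(amp / 0.05, 1.0)]])
        return self

    def __call__(self, raster: np.ndarray) -> np.ndarray:
        if self._cue is None:
            raise RuntimeError("bind_site() must be called before extraction")
        v = np.array(self.base(raster), dtype=float)
        v[-10:] += self.cue_scale * self._cue
        return v


def extract_features(patch_set, extractor: Extractor) -> SlideFeatures:
    """Run ``extractor`` over every patch of a slide, preserving order.

    Raises a hard error if the patch set is empty or the extractor returns a
    wrong-width or non-finite vector — silent feature corruption must never
    reach the probe or the search index.
    """
    rasters = patch_set.rasters
    if rasters is None or len(rasters) == 0:
        raise ValueError(f"empty patch set for slide {patch_set.slide_id}")
    rows = []
    for i, raster in enumerate(rasters):
        v = np.asarray(extractor(raster), dtype=float)
        if v.shape != (extractor.dim,):
            raise ValueError(
                f"extractor {extractor.name} returned shape {v.shape}, "
                f"expected ({extractor.dim},) on patch {i} of {patch_set.slide_id}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(
                f"extractor {extractor.name} returned non-finite values "
                f"on patch {i} of {patch_set.slide_id}"
            )
        rows.append(v)
    return SlideFeatures(
        slide_id=patch_set.slide_id,
        X=np.vstack(rows),
        extractor=extractor.name,
        version=getattr(extractor, "version", "0"),
    )


def pool_features(sf: SlideFeatures, method: str = "mean") -> np.ndarray:
    """Pool a slide's patch features into one vector (column-wise mean)."""
    if sf.n_patches == 0:
        raise ValueError(f"cannot pool an empty feature matrix ({sf.slide_id})")
    if method != "mean":
        raise ValueError(f"unknown pooling method {method!r}")
    return sf.X.mean(axis=0)


def zscore_features(store: dict[str, SlideFeatures]) -> dict[str, SlideFeatures]:
    """Optional cohort-wide z-scoring of features (off by default downstream)."""
    stacked = np.vstack([sf.X for sf in store.values()])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    return {
        sid: SlideFeatures(sid, (sf.X - mu) / sd, sf.extractor, sf.version + "+z")
        for sid, sf in store.items()
    }
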