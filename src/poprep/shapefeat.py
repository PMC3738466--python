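"""Reduced hierarchical shape-feature model (S1 -> C1 -> S2 -> C2).

S1 is a bank of Gabor filters over orientations and spatial frequencies;
C1 takes local maxima over position and over frequency bands within an
orientation (an OR-like pooling); S2 units compute a Gaussian radial-basis
match between C1 patches and a dictionary of template patches sampled
(seeded) from the stimulus set itself; C2 takes the global maximum of each
template's match over positions and bands, yielding one
position/scale-tolerant activation vector per image.

The default scale is deliberately small (4 orientations x 4 frequencies,
200 templates); all counts are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel
from skimage.measure import block_reduce
from skimage.util import view_as_windows
from sklearn.cluster import KMeans

from .imgprops import CategoryScheme
from .stimgen import StimulusSet

__all__ = [
    "ShapeModelConfig",
    "FeatureMatrix",
    "extract_c2_features",
    "build_shape_categories",
]


@dataclass
class ShapeModelConfig:
    n_orientations: int = 4
    frequencies: tuple = (0.10, 0.15, 0.22, 0.30)
    c1_pool: int = 4                  # spatial pooling block (max)
    c1_band_size: int = 2             # frequencies pooled per C1 band
    n_templates: int = 200
    template_size: int = 6            # patch side length on the C1 grid
    rbf_sigma: float = 0.1            # width of the S2 match, per dimension
    seed: int = 0


@dataclass
class FeatureMatrix:
    """Objects x C2-unit activation matrix."""

    values: np.ndarray
    object_ids: list
    config: ShapeModelConfig = field(default_factory=ShapeModelConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("activations must be finite")


def _s1_kernels(cfg: ShapeModelConfig) -> list:
    kernels = []
    for freq in cfg.frequencies:
        for o in range(cfg.n_orientations):
            theta = np.pi * o / cfg.n_orientations
            ker = gabor_kernel(freq, theta=theta)
            # zero-DC: a uniform background must give no response
            kernels.append(ker - ker.mean())
    return kernels


def _c1_maps(img: np.ndarray, cfg: ShapeModelConfig,
             kernels: list) -> list[np.ndarray]:
    """One (orientations, H', W') stack per C1 band."""
    x = img.astype(np.float64) / 255.0 - 0.5  # fixed scale, mid-gray ~ 0
    n_f = len(cfg.frequencies)
    s1 = np.empty((n_f, cfg.n_orientations) + img.shape)
    k = 0
    for fi in range(n_f):
        for oi in range(cfg.n_orientations):
            ker = kernels[k]
            k += 1
            resp = fftconvolve(x, np.real(ker), mode="same")
            resp_i = fftconvolve(x, np.imag(ker), mode="same")
            s1[fi, oi] = np.hypot(resp, resp_i)
    bands = []
    for start in range(0, n_f, cfg.c1_band_size):
        band_s1 = s1[start:start + cfg.c1_band_size].max(axis=0)
        pooled = block_reduce(
            band_s1, (1, cfg.c1_pool, cfg.c1_pool), np.max
        )
        # suppress background filter noise: otherwise unit-normalizing
        # near-zero S2 patches amplifies it into random directions
        pooled[pooled < 0.02 * pooled.max()] = 0.0
        bands.append(pooled)
    return bands


def _sample_templates(
    c1_per_image: list[list[np.ndarray]],
    cfg: ShapeModelConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    t = cfg.template_size
    templates = []
    for _ in range(cfg.n_templates):
        img_idx = int(rng.integers(len(c1_per_image)))
        bands = c1_per_image[img_idx]
        band = bands[int(rng.integers(len(bands)))]
        _, h, w = band.shape
        if h < t or w < t:
            raise ValueError(
                f"template size {t} exceeds the C1 map ({h}x{w}); reduce "
                "template_size or c1_pool"
            )
        r = int(rng.integers(h - t + 1))
        c = int(rng.integers(w - t + 1))
        templates.append(band[:, r:r + t, c:c + t].ravel())
    return np.array(templates)


def _c2_vector(
    bands: list[np.ndarray], templates: np.ndarray, cfg: ShapeModelConfig
) -> np.ndarray:
    t = cfg.template_size
    dim = templates.shape[1]
    best = np.full(templates.shape[0], -np.inf)
    for band in bands:
        _, h, w = band.shape
        if h < t or w < t:
            raise ValueError("template size exceeds the C1 map")
        windows = view_as_windows(band, (band.shape[0], t, t))
        patches = windows.reshape(-1, dim)
        # squared Euclidean distances patch-template
        d2 = (
            (patches ** 2).sum(axis=1)[:, None]
            + (templates ** 2).sum(axis=1)[None, :]
            - 2.0 * patches @ templates.T
        )
        np.maximum(d2, 0.0, out=d2)
        act = np.exp(-d2 / (2.0 * cfg.rbf_sigma ** 2 * dim))
        best = np.maximum(best, act.max(axis=0))
    return best


def extract_c2_features(
    stimset: StimulusSet,
    config: ShapeModelConfig | None = None,
    seed: int | None = None,
) -> FeatureMatrix:
    """C2 activation vectors for every image in the set.

    Templates are sampled from the C1 representation of the stimulus set
    itself (seeded).  A template cut from an image guarantees that image an
    activation of 1.0 on that unit (RBF at distance zero).
    """
    cfg = config or ShapeModelConfig()
    if cfg.n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if len(stimset) == 0:
        raise ValueError("empty stimulus set")
    shapes = {img.shape for img in stimset.images}
    if len(shapes) != 1:
        raise ValueError("all images must share the same size")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    kernels = _s1_kernels(cfg)
    c1 = [_c1_maps(img, cfg, kernels) for img in stimset.images]
    templates = _sample_templates(c1, cfg, rng)
    values = np.array([_c2_vector(bands, templates, cfg) for bands in c1])
    return FeatureMatrix(
        values=values, object_ids=list(stimset.object_ids), config=cfg
    )


def build_shape_categories(
    fm: FeatureMatrix, k: int = 15, seed: int = 0
) -> CategoryScheme:
    """k-means over the C2 representation; categories named #1..#k."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(fm.object_ids):
        raise ValueError("k cannot exceed the number of objects")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(fm.values)
    categories: dict[str, set] = {f"#{i + 1}": set() for i in range(k)}
    for oid, lab in zip(fm.object_ids, km.labels_):
        categories[f"#{lab + 1}"].add(oid)
    return CategoryScheme(
        scheme_kind="shape_based",
        categories={n: frozenset(m) for n, m in categories.items()},
    )
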