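"""Low-level image properties and the extreme-value category scheme.

Four global properties are computed for each object image: luminance,
contrast, area and aspect ratio.  Object pixels are defined as pixels whose
intensity differs from the (uniform, synthetic) background value.  Eight
"low-level" categories are built by taking, for each property, the objects
with the highest and the lowest values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "PropertyVector",
    "CategoryScheme",
    "compute_properties",
    "compute_aspect_ratio",
    "property_table",
    "build_lowlevel_categories",
]

logger = logging.getLogger(__name__)

#: names of the four scalar properties, in canonical order
PROPERTY_NAMES = ("luminance", "contrast", "area", "aspect_ratio")


@dataclass(frozen=True)
class PropertyVector:
    """Scalar image properties of a single object-on-background frame.

    ``contrast`` and ``aspect_ratio`` are ``nan`` when undefined (e.g. on a
    blank frame, or when the object has no pixels on one side of the
    mid-gray reference level).
    """

    luminance: float
    contrast: float
    area: float
    aspect_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {
            "luminance": self.luminance,
            "contrast": self.contrast,
            "area": self.area,
            "aspect_ratio": self.aspect_ratio,
        }


@dataclass
class CategoryScheme:
    """A named family of object categories under one clustering hypothesis.

    ``scheme_kind`` is one of ``"semantic"``, ``"shape_based"`` or
    ``"low_level"``.  ``categories`` maps a category name to a frozenset of
    object ids.  For the semantic kind, ``superordinates`` maps
    ``"animate"``/``"inanimate"`` to the union of their subordinate
    categories.
    """

    scheme_kind: str
    categories: dict[str, frozenset]
    superordinates: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme_kind not in ("semantic", "shape_based", "low_level"):
            raise ValueError(f"unknown scheme kind: {self.scheme_kind!r}")
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        self.superordinates = {
            k: frozenset(v) for k, v in self.superordinates.items()
        }

    @property
    def universe(self) -> frozenset:
        out: frozenset = frozenset()
        for members in self.categories.values():
            out |= members
        return out


def _object_mask(img: np.ndarray, background_value: int) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    return img != background_value


def compute_properties(
    img: np.ndarray,
    background_value: int = 128,
    *,
    contrast_on_object_only: bool = True,
    angle_step: float = 1.0,
) -> PropertyVector:
    """Compute luminance, contrast, area and aspect ratio for one frame.

    Luminance is the mean intensity of the object pixels divided by 255;
    area is the fraction of frame pixels occupied by the object; contrast is
    ``(median(px > 128) - median(px < 128)) / (median(px > 128) + median(px < 128))``
    where ``px`` ranges over object pixels by default (set
    ``contrast_on_object_only=False`` to use the whole frame).  Medians use
    lower interpolation on even counts so that the result is always an
    observed intensity.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    mask = _object_mask(img, background_value)
    n_frame = img.size
    n_obj = int(mask.sum())
    area = n_obj / n_frame

    if n_obj == 0:
        return PropertyVector(
            luminance=float(background_value) / 255.0,
            contrast=float("nan"),
            area=0.0,
            aspect_ratio=float("nan"),
        )

    obj_px = img[mask].astype(np.float64)
    luminance = float(obj_px.mean()) / 255.0

    px = obj_px if contrast_on_object_only else img.astype(np.float64).ravel()
    hi = px[px > 128]
    lo = px[px < 128]
    if hi.size == 0 or lo.size == 0:
        contrast = float("nan")
    else:
        med_hi = _median_lower(hi)
        med_lo = _median_lower(lo)
        denom = med_hi + med_lo
        contrast = (med_hi - med_lo) / denom if denom != 0 else float("nan")

    aspect = compute_aspect_ratio(mask, angle_step=angle_step)
    return PropertyVector(
        luminance=luminance, contrast=float(contrast), area=area,
        aspect_ratio=aspect,
    )


def _median_lower(x: np.ndarray) -> float:
    """Median with lower interpolation: element at index (n-1)//2."""
    x = np.sort(np.asarray(x, dtype=np.float64))
    return float(x[(x.size - 1) // 2])


def compute_aspect_ratio(mask: np.ndarray, angle_step: float = 1.0) -> float:
    """Maximum of bounding-box height/width over rotations in [0, 180).

    The binary ``mask`` is rotated in ``angle_step`` degree increments
    (nearest-neighbour, expanded canvas) and the tight bounding box measured
    at each angle.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    best = 0.0
    fmask = mask.astype(np.float64)
    for angle in np.arange(0.0, 180.0, angle_step):
        if angle == 0.0:
            rot = mask
        else:
            rot = _sk_rotate(fmask, angle, resize=True, order=0) > 0.5
            if not rot.any():  # pragma: no cover - degenerate rotation
                continue
        rows = np.flatnonzero(rot.any(axis=1))
        cols = np.flatnonzero(rot.any(axis=0))
        h = rows[-1] - rows[0] + 1
        w = cols[-1] - cols[0] + 1
        best = max(best, h / w)
    return float(max(best, 1.0))


def property_table(
    images: dict | list,
    object_ids: list | None = None,
    background_value: int = 128,
    **kwargs,
) -> pd.DataFrame:
    """Property vectors for a collection of images, as a tidy table.

    ``images`` may be a mapping ``object_id -> raster`` or a list of rasters
    paired with ``object_ids``.
    """
    if isinstance(images, dict):
        items = list(images.items())
    else:
        if object_ids is None:
            object_ids = list(range(len(images)))
        items = list(zip(object_ids, images))
    rows = []
    for oid, img in items:
        pv = compute_properties(img, background_value, **kwargs)
        rows.append({"object_id": oid, **pv.as_dict()})
    return pd.DataFrame(rows).set_index("object_id")


def build_lowlevel_categories(
    props: pd.DataFrame, n: int = 15
) -> CategoryScheme:
    """Eight categories: the ``n`` highest / lowest objects per property.

    Objects with an undefined (nan) property are excluded from that
    property's pair of categories.  Ties at the cut are broken by object-id
    order (the stable sort key), which is logged.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    categories: dict[str, frozenset] = {}
    for prop in PROPERTY_NAMES:
        col = props[prop]
        defined = col[col.notna()]
        if n > len(defined):
            raise ValueError(
                f"n={n} exceeds the {len(defined)} objects with a defined "
                f"{prop}"
            )
        order = defined.sort_index().sort_values(kind="stable")
        if order.duplicated(keep=False).any():
            logger.info(
                "ties in %s broken by object-id order at the category cut",
                prop,
            )
        categories[f"low_{prop}"] = frozenset(order.index[:n])
        categories[f"high_{prop}"] = frozenset(order.index[-n:])
    return CategoryScheme(scheme_kind="low_level", categories=categories)
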