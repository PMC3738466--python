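"""Procedural generation of a synthetic object stimulus set.

The default composition emulates a 213-image battery: 94 twin pairs of
"real-world" objects (188 images), 5 cars, 5 faces, 5 abstract silhouettes,
5 texture patches, 1 blank frame, and 4 low-contrast variants of a single
object.  Objects are simple parametric shapes drawn on a uniform mid-gray
background; twins are jittered copies of a shared prototype, so that they
are highly similar at the pixel level.

Shape families span round / horizontally elongated / vertically elongated /
star-like / pointy / textured objects, and each family is compatible with
several semantic labels (and vice versa), so that semantic and shape
structure can be decoupled in downstream analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "StimulusConfig",
    "StimulusSet",
    "generate_stimulus_set",
    "build_semantic_categories",
    "load_config",
]

SHAPE_FAMILIES = (
    "round", "horizontal", "vertical", "star", "pointy", "textured",
)

ANIMATE_LABELS = (
    "four_limbed_animals", "birds", "faces", "fishes", "insects",
    "sea_invertebrates",
)
INANIMATE_LABELS = (
    "trees", "vehicles", "tools", "music_instruments", "buildings",
)
SEMANTIC_LABELS = ANIMATE_LABELS + INANIMATE_LABELS

# many-to-many compatibility between semantic labels and shape families,
# so neither hypothesis is a relabelling of the other
_LABEL_FAMILIES = {
    "four_limbed_animals": ("horizontal", "pointy"),
    "birds": ("horizontal", "round"),
    "faces": ("round",),
    "fishes": ("horizontal",),
    "insects": ("pointy", "star"),
    "sea_invertebrates": ("star", "round"),
    "trees": ("vertical", "star"),
    "vehicles": ("horizontal", "round"),
    "tools": ("vertical", "horizontal"),
    "music_instruments": ("vertical", "round"),
    "buildings": ("vertical",),
}


@dataclass
class StimulusConfig:
    """Composition and rendering parameters of the synthetic set."""

    frame_size: int = 64
    background: int = 128
    n_twin_pairs: int = 94
    n_cars: int = 5
    n_faces: int = 5
    n_silhouettes: int = 5
    n_textures: int = 5
    n_blank: int = 1
    n_low_contrast: int = 4
    #: contrast scaling of the low-contrast variant sequence
    low_contrast_levels: tuple = (0.10, 0.03, 0.02, 0.015)
    max_twin_rotation_deg: float = 5.0
    max_twin_contrast_jitter: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_twin_pairs", "n_cars", "n_faces", "n_silhouettes",
            "n_textures", "n_blank", "n_low_contrast",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count in composition: {name}")
        if self.frame_size < 32:
            raise ValueError("frame_size must be >= 32")
        if self.n_low_contrast > len(self.low_contrast_levels):
            raise ValueError(
                "not enough low_contrast_levels for n_low_contrast"
            )

    @property
    def n_images(self) -> int:
        return (
            2 * self.n_twin_pairs + self.n_cars + self.n_faces
            + self.n_silhouettes + self.n_textures + self.n_blank
            + self.n_low_contrast
        )


@dataclass
class StimulusSet:
    """Rendered images plus per-object metadata.

    ``objects`` is a list of dicts with keys ``object_id``, ``twin_set_id``,
    ``semantic_label``, ``is_animate``, ``shape_family`` and
    ``generator_params``.
    """

    images: list
    objects: list
    frame_size: int
    background: int = 128
    config: StimulusConfig = field(default_factory=StimulusConfig)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def object_ids(self) -> list:
        return [o["object_id"] for o in self.objects]

    def metadata(self) -> pd.DataFrame:
        rows = [
            {k: o[k] for k in (
                "object_id", "twin_set_id", "semantic_label", "is_animate",
                "shape_family",
            )}
            for o in self.objects
        ]
        return pd.DataFrame(rows).set_index("object_id")

    def twin_sets(self) -> dict[str, frozenset]:
        out: dict[str, set] = {}
        for o in self.objects:
            out.setdefault(o["twin_set_id"], set()).add(o["object_id"])
        return {k: frozenset(v) for k, v in out.items()}

    def image_by_id(self, object_id: str) -> np.ndarray:
        return self.images[self.object_ids.index(object_id)]

    def save(self, outdir: str | Path) -> None:
        """Write one PNG per image and a delimited metadata table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for img, obj in zip(self.images, self.objects):
            Image.fromarray(img, mode="L").save(
                outdir / f"{obj['object_id']}.png"
            )
        meta = self.metadata()
        meta.to_csv(outdir / "objects.tsv", sep="\t")


def load_config(path: str | Path) -> StimulusConfig:
    """Read a :class:`StimulusConfig` from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    known = {f for f in StimulusConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown stimulus config keys: {sorted(unknown)}")
    if "low_contrast_levels" in data:
        data["low_contrast_levels"] = tuple(data["low_contrast_levels"])
    return StimulusConfig(**data)


# ---------------------------------------------------------------------------
# rendering primitives

def _grid(frame_size: int):
    half = frame_size / 2.0
    y, x = np.mgrid[0:frame_size, 0:frame_size]
    return x - half + 0.5, y - half + 0.5


def _rotate_coords(x, y, angle_deg: float):
    a = np.deg2rad(angle_deg)
    return x * np.cos(a) + y * np.sin(a), -x * np.sin(a) + y * np.cos(a)


def _family_mask(family: str, params: dict, frame_size: int) -> np.ndarray:
    """Implicit-function mask for one shape family."""
    x, y = _grid(frame_size)
    x, y = _rotate_coords(x, y, params.get("angle", 0.0))
    r = params["radius"]
    if family == "round":
        a, b = r, r * params.get("squash", 0.9)
        return (x / a) ** 2 + (y / b) ** 2 <= 1.0
    if family == "horizontal":
        a, b = r * params.get("elong", 2.5), r * 0.45
        return (x / a) ** 2 + (y / b) ** 2 <= 1.0
    if family == "vertical":
        a, b = r * 0.45, r * params.get("elong", 2.5)
        return (np.abs(x) <= a) & (np.abs(y) <= b)
    if family == "star":
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        k = params.get("n_points", 5)
        amp = params.get("amp", 0.45)
        return rho <= r * (1.0 + amp * np.cos(k * theta))
    if family == "pointy":
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        k = params.get("n_points", 3)
        lobe = np.maximum(np.cos(k * theta), 0.0) ** params.get("sharp", 6)
        return rho <= r * (0.25 + 1.4 * lobe)
    if family == "textured":
        a = r * 1.1
        return (np.abs(x) <= a) & (np.abs(y) <= a)
    raise ValueError(f"unknown shape family: {family!r}")


def _render(
    family: str, params: dict, frame_size: int, background: int
) -> np.ndarray:
    """Render a two-tone object; no object pixel equals the background."""
    mask = _family_mask(family, params, frame_size)
    if not mask.any():
        raise ValueError(
            f"frame of size {frame_size} too small to render the requested "
            f"object (family={family!r}, radius={params['radius']})"
        )
    x, y = _grid(frame_size)
    x, y = _rotate_coords(x, y, params.get("angle", 0.0))
    canvas = np.full((frame_size, frame_size), float(background))

    dev_hi = params.get("dev_hi", 80.0)
    dev_lo = params.get("dev_lo", 80.0)
    if family == "textured":
        rng = np.random.default_rng(params["texture_seed"])
        kind = params.get("texture_kind", "dots")
        if kind == "dots":
            pattern = rng.random((frame_size, frame_size)) < 0.5
        else:  # oriented bars
            freq = params.get("bar_freq", 0.25)
            pattern = np.cos(2 * np.pi * freq * x) > 0
    else:
        freq = params.get("stripe_freq", 0.0)
        if freq > 0:
            pattern = np.cos(2 * np.pi * freq * (x + 0.3 * y)) > 0
        else:  # split object into a bright and a dark half
            pattern = x + 0.25 * y > params.get("split_offset", 0.0)

    hi = background + dev_hi
    lo = background - dev_lo
    canvas[mask & pattern] = hi
    canvas[mask & ~pattern] = lo
    out = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    # keep the background exactly representable: object pixels may never
    # collide with the background value
    collide = mask & (out == background)
    out[collide] = background + 1
    return out


def _camera_image(
    frame_size: int, background: int, contrast_scale: float, dev: float = 120.0
) -> np.ndarray:
    """The low-contrast reference object: a boxy body with a dark lens."""
    x, y = _grid(frame_size)
    r = frame_size * 0.28
    body = (np.abs(x) <= r * 1.3) & (np.abs(y) <= r * 0.8)
    lens = np.hypot(x, y) <= r * 0.45
    # integer deviations, floored, so the variant sequence has strictly
    # decreasing contrast even after 8-bit quantization
    d = max(1.0, np.floor(dev * contrast_scale))
    canvas = np.full((frame_size, frame_size), float(background))
    canvas[body] = background + d
    canvas[lens] = background - d
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# set assembly

def _prototype_params(family: str, rng: np.random.Generator,
                      frame_size: int) -> dict:
    scale = frame_size / 64.0
    params = {
        "radius": float(rng.uniform(7.0, 15.0) * scale),
        "angle": float(rng.uniform(0.0, 360.0)),
        "dev_hi": float(rng.uniform(30.0, 110.0)),
        "dev_lo": float(rng.uniform(30.0, 110.0)),
        "split_offset": float(rng.uniform(-2.0, 2.0)),
    }
    if family == "round":
        params["squash"] = float(rng.uniform(0.75, 1.0))
    elif family in ("horizontal", "vertical"):
        params["elong"] = float(rng.uniform(2.0, 3.2))
        params["radius"] = float(rng.uniform(6.0, 11.0) * scale)
    elif family == "star":
        params["n_points"] = int(rng.integers(5, 9))
        params["amp"] = float(rng.uniform(0.3, 0.55))
    elif family == "pointy":
        params["n_points"] = int(rng.integers(2, 5))
        params["sharp"] = int(rng.integers(4, 10))
    elif family == "textured":
        params["texture_seed"] = int(rng.integers(0, 2**31))
        params["texture_kind"] = str(
            rng.choice(["dots", "bars"])
        )
        params["bar_freq"] = float(rng.uniform(0.1, 0.35))
    if rng.random() < 0.4 and family != "textured":
        params["stripe_freq"] = float(rng.uniform(0.05, 0.2))
    return params


def _jitter(params: dict, cfg: StimulusConfig,
            rng: np.random.Generator) -> dict:
    out = dict(params)
    out["angle"] = params.get("angle", 0.0) + float(
        rng.uniform(-cfg.max_twin_rotation_deg, cfg.max_twin_rotation_deg)
    )
    cscale = 1.0 + float(rng.uniform(
        -cfg.max_twin_contrast_jitter, cfg.max_twin_contrast_jitter
    ))
    out["dev_hi"] = min(120.0, params["dev_hi"] * cscale)
    out["dev_lo"] = min(120.0, params["dev_lo"] * cscale)
    return out


def generate_stimulus_set(
    config: StimulusConfig | None = None, seed: int | None = None
) -> StimulusSet:
    """Generate the full synthetic stimulus set.

    Same config and seed give a bit-identical image set.
    """
    cfg = config or StimulusConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    images: list[np.ndarray] = []
    objects: list[dict] = []

    def add(img, object_id, twin_set_id, label, family, params):
        images.append(img)
        objects.append({
            "object_id": object_id,
            "twin_set_id": twin_set_id,
            "semantic_label": label,
            "is_animate": label in ANIMATE_LABELS,
            "shape_family": family,
            "generator_params": params,
        })

    # 94 twin pairs of "real-world" objects
    for i in range(cfg.n_twin_pairs):
        label = SEMANTIC_LABELS[i % len(SEMANTIC_LABELS)]
        family = str(rng.choice(_LABEL_FAMILIES[label]))
        proto = _prototype_params(family, rng, cfg.frame_size)
        twin_id = f"twin{i:03d}"
        for j in range(2):
            params = _jitter(proto, cfg, rng)
            img = _render(family, params, cfg.frame_size, cfg.background)
            add(img, f"{twin_id}_{j}", twin_id, label, family, params)

    # special groups: each group is one twin set of near-identical exemplars
    for group, count, label, family in (
        ("cars", cfg.n_cars, "vehicles", "horizontal"),
        ("faces", cfg.n_faces, "faces", "round"),
        ("silh", cfg.n_silhouettes, "silhouettes", "pointy"),
    ):
        if count == 0:
            continue
        proto = _prototype_params(family, rng, cfg.frame_size)
        for j in range(count):
            params = _jitter(proto, cfg, rng)
            img = _render(family, params, cfg.frame_size, cfg.background)
            add(img, f"{group}{j}", group, label, family, params)

    # texture patches: independent singletons
    for j in range(cfg.n_textures):
        params = _prototype_params("textured", rng, cfg.frame_size)
        img = _render("textured", params, cfg.frame_size, cfg.background)
        add(img, f"texture{j}", f"texture{j}", "textures", "textured", params)

    # blank frame
    for j in range(cfg.n_blank):
        img = np.full(
            (cfg.frame_size, cfg.frame_size), cfg.background, dtype=np.uint8
        )
        add(img, f"blank{j}", f"blank{j}", "blank", "blank", {})

    # low-contrast variant sequence of a single reference object
    for j in range(cfg.n_low_contrast):
        level = cfg.low_contrast_levels[j]
        img = _camera_image(cfg.frame_size, cfg.background, level)
        add(
            img, f"lowcontrast{j}", "lowcontrast", "tools", "horizontal",
            {"contrast_scale": level},
        )

    stimset = StimulusSet(
        images=images, objects=objects, frame_size=cfg.frame_size,
        background=cfg.background, config=cfg,
    )
    assert len(stimset) == cfg.n_images
    return stimset


def build_semantic_categories(stimset: StimulusSet):
    """Semantic category scheme (with animate/inanimate superordinates).

    Only the named semantic labels form categories; auxiliary objects
    (textures, blanks, silhouettes) stay outside the scheme.
    """
    from .imgprops import CategoryScheme

    meta = stimset.metadata()
    categories = {}
    for label in SEMANTIC_LABELS:
        members = frozenset(meta.index[meta["semantic_label"] == label])
        if members:
            categories[label] = members
    supers = {
        "animate": frozenset().union(*(
            categories.get(l, frozenset()) for l in ANIMATE_LABELS
        )),
        "inanimate": frozenset().union(*(
            categories.get(l, frozenset()) for l in INANIMATE_LABELS
        )),
    }
    return CategoryScheme(
        scheme_kind="semantic", categories=categories, superordinates=supers
    )
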