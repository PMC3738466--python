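"""Synthetic validation fixtures with planted, known structure.

These builders construct small stimulus/response configurations whose
ground truth is known by construction, for calibration and recovery checks
of the analysis stages (they are also used by the acceptance report).
"""

from __future__ import annotations

import numpy as np

from .imgprops import CategoryScheme
from .neurogen import ResponseDataset, TuningConfig, simulate_population
from .stimgen import StimulusSet, _prototype_params, _render

__all__ = [
    "twin_confound_stimulus_set",
    "twin_confound_schemes",
    "planted_gain_dataset",
]

_FAMILIES = ("round", "horizontal", "vertical", "star", "pointy", "textured")


def twin_confound_stimulus_set(
    seed: int,
    n_pairs_per_class: int = 6,
    frame_size: int = 64,
) -> StimulusSet:
    """Twin pairs whose semantic split is orthogonal to shape families.

    Two semantic classes ("target" / "other") of ``n_pairs_per_class`` twin
    pairs each; within each class the pairs cycle through the six shape
    families, so both classes span the same families and the only reliable
    image-level cue for the semantic split is the idiosyncratic appearance
    of each object - which its twin shares.
    """
    rng = np.random.default_rng(seed)
    images, objects = [], []
    pair = 0
    for label in ("target", "other"):
        for i in range(n_pairs_per_class):
            family = _FAMILIES[i % len(_FAMILIES)]
            proto = _prototype_params(family, rng, frame_size)
            twin_id = f"pair{pair:02d}"
            for j in range(2):
                params = dict(proto)
                params["angle"] = proto.get("angle", 0.0) + float(
                    rng.uniform(-5, 5)
                )
                img = _render(family, params, frame_size, 128)
                objects.append({
                    "object_id": f"{twin_id}_{j}",
                    "twin_set_id": twin_id,
                    "semantic_label": label,
                    "is_animate": label == "target",
                    "shape_family": family,
                    "generator_params": params,
                })
                images.append(img)
            pair += 1
    return StimulusSet(images=images, objects=objects,
                       frame_size=frame_size)


def twin_confound_schemes(
    stimset: StimulusSet,
) -> tuple[CategoryScheme, CategoryScheme]:
    """(semantic, family) schemes of a twin-confound stimulus set."""
    meta = stimset.metadata()
    semantic = CategoryScheme(
        scheme_kind="semantic",
        categories={
            label: frozenset(meta.index[meta["semantic_label"] == label])
            for label in ("target", "other")
        },
    )
    family = CategoryScheme(
        scheme_kind="shape_based",
        categories={
            fam: frozenset(meta.index[meta["shape_family"] == fam])
            for fam in meta["shape_family"].unique()
        },
    )
    return semantic, family


def planted_gain_dataset(
    stimset: StimulusSet,
    positive,
    gain_hz: float = 50.0,
    n_neurons: int = 16,
    seed: int = 0,
    repetitions: int = 7,
) -> ResponseDataset:
    """Responses with an additive rate gain on a planted object set."""
    rng = np.random.default_rng(seed)
    labels = [
        "pos" if oid in set(positive) else "neg"
        for oid in stimset.object_ids
    ]
    # per-object semantic labels are needed by the tuning path: wrap them
    stim = StimulusSet(
        images=stimset.images,
        objects=[
            {**o, "semantic_label": lab}
            for o, lab in zip(stimset.objects, labels)
        ],
        frame_size=stimset.frame_size,
        background=stimset.background,
    )
    tuning = TuningConfig(
        n_neurons=n_neurons,
        baseline_hz=10.0,
        semantic_gain={"pos": gain_hz},
        semantic_gain_weights=rng.uniform(0.5, 1.5, n_neurons),
        repetitions=repetitions,
    )
    return simulate_population(stim, tuning, seed=seed + 1)
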