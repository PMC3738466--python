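"""Synthetic spiking population with image-property-driven tuning.

Each simulated neuron has a baseline rate, a weight vector over image
property channels (area, luminance, contrast, aspect ratio and shape-family
indicators) and an optional additive rate gain per semantic label.  Trial
spike counts in a 100 ms response window are Poisson around the resulting
mean rate; an equal-duration background window provides the counts used for
responsiveness screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .imgprops import property_table
from .stimgen import SHAPE_FAMILIES, StimulusSet

__all__ = [
    "ResponseDataset",
    "TuningConfig",
    "default_property_channels",
    "simulate_population",
    "screen_responsive",
]

logger = logging.getLogger(__name__)

#: duration of the response window in seconds (100-200 ms post stimulus)
WINDOW_S = 0.1

PROPERTY_CHANNELS = (
    "area", "luminance", "contrast", "aspect_ratio",
) + tuple(f"family_{f}" for f in SHAPE_FAMILIES)


@dataclass
class ResponseDataset:
    """Trial-level spike counts for a population of neurons.

    ``counts`` has shape ``(n_neurons, n_objects, n_repetitions)`` and holds
    non-negative integer counts in the response window;
    ``background_counts`` has shape ``(n_neurons, n_background_trials)``.
    """

    counts: np.ndarray
    background_counts: np.ndarray
    object_ids: list
    neuron_ids: list
    window_ms: tuple = (100, 200)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.background_counts = np.asarray(self.background_counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (neurons, objects, trials)")
        if (self.counts < 0).any() or (self.background_counts < 0).any():
            raise ValueError("spike counts must be non-negative")
        if self.counts.shape[2] < 1:
            raise ValueError("every (neuron, object) pair needs >=1 trial")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_objects(self) -> int:
        return self.counts.shape[1]

    @property
    def n_repetitions(self) -> int:
        return self.counts.shape[2]

    def mean_rates(self) -> np.ndarray:
        """Mean firing rate (Hz) per (neuron, object) in the window."""
        return self.counts.mean(axis=2) / WINDOW_S

    def subset_neurons(self, idx) -> "ResponseDataset":
        idx = np.asarray(idx, dtype=int)
        return ResponseDataset(
            counts=self.counts[idx],
            background_counts=self.background_counts[idx],
            object_ids=list(self.object_ids),
            neuron_ids=[self.neuron_ids[i] for i in idx],
            window_ms=self.window_ms,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format trial table, including background trials."""
        rows = []
        for i, nid in enumerate(self.neuron_ids):
            for j, oid in enumerate(self.object_ids):
                for t, c in enumerate(self.counts[i, j]):
                    rows.append((nid, oid, t, int(c), 0))
            for t, c in enumerate(self.background_counts[i]):
                rows.append((nid, "", t, int(c), 1))
        return pd.DataFrame(
            rows,
            columns=["neuron_id", "object_id", "trial", "count",
                     "is_background"],
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   window_ms: tuple = (100, 200)) -> "ResponseDataset":
        bg = df[df["is_background"] == 1]
        fg = df[df["is_background"] == 0]
        neuron_ids = list(pd.unique(df["neuron_id"]))
        object_ids = list(pd.unique(fg["object_id"]))
        n_rep = fg.groupby(["neuron_id", "object_id"]).size()
        if n_rep.nunique() != 1:
            raise ValueError("trial table is ragged")
        counts = (
            fg.pivot_table(
                index=["neuron_id", "object_id"], columns="trial",
                values="count",
            )
            .reindex(
                pd.MultiIndex.from_product([neuron_ids, object_ids])
            )
            .to_numpy()
            .reshape(len(neuron_ids), len(object_ids), -1)
            .astype(int)
        )
        bg_counts = (
            bg.pivot_table(index="neuron_id", columns="trial",
                           values="count")
            .reindex(neuron_ids)
            .to_numpy()
            .astype(int)
        )
        return cls(counts, bg_counts, object_ids, neuron_ids, window_ms)

    @classmethod
    def load(cls, path: str | Path) -> "ResponseDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class TuningConfig:
    """Statistical tuning model of the simulated population.

    ``weights`` has shape ``(n_neurons, n_channels)`` in Hz per unit of the
    (z-scored) property channel; ``semantic_gain`` maps a semantic label to
    an additive rate (Hz) applied uniformly across neurons, optionally
    modulated per neuron via ``semantic_gain_weights``.
    """

    n_neurons: int = 94
    baseline_hz: float = 10.0
    background_hz: float | None = None
    weights: np.ndarray | None = None
    semantic_gain: dict = field(default_factory=dict)
    semantic_gain_weights: np.ndarray | None = None
    repetitions: int = 7
    n_background_trials: int = 50

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 1 <= self.repetitions <= 1000:
            raise ValueError("unreasonable repetition count")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_neurons,
                                      len(PROPERTY_CHANNELS)):
                raise ValueError(
                    "weights must be (n_neurons, n_channels) with channels "
                    f"{PROPERTY_CHANNELS}"
                )

    @classmethod
    def random(cls, n_neurons: int, seed: int, weight_scale: float = 4.0,
               **kwargs) -> "TuningConfig":
        """Heterogeneous random tuning over all property channels."""
        rng = np.random.default_rng(seed)
        w = rng.normal(0.0, weight_scale,
                       (n_neurons, len(PROPERTY_CHANNELS)))
        return cls(n_neurons=n_neurons, weights=w, **kwargs)


def default_property_channels(stimset: StimulusSet) -> pd.DataFrame:
    """Per-object channel matrix: z-scored properties + family indicators.

    Undefined properties (nan, e.g. contrast of the blank frame) contribute
    zero drive.
    """
    props = property_table(
        dict(zip(stimset.object_ids, stimset.images)),
        background_value=stimset.background,
        angle_step=6.0,
    )
    meta = stimset.metadata()
    out = pd.DataFrame(index=props.index)
    for col in ("area", "luminance", "contrast", "aspect_ratio"):
        v = props[col]
        z = (v - v.mean()) / v.std() if v.std() > 0 else v * 0.0
        out[col] = z.fillna(0.0)
    for fam in SHAPE_FAMILIES:
        out[f"family_{fam}"] = (
            (meta["shape_family"] == fam).astype(float)
        )
    return out


def simulate_population(
    stimset: StimulusSet,
    tuning: TuningConfig,
    seed: int = 0,
) -> ResponseDataset:
    """Draw Poisson trial counts around property-driven mean rates."""
    if len(stimset) == 0:
        raise ValueError("empty stimulus set")
    rng = np.random.default_rng(seed)
    channels = default_property_channels(stimset)
    X = channels.to_numpy()  # objects x channels
    n_obj = X.shape[0]
    n_neu = tuning.n_neurons

    rates = np.full((n_neu, n_obj), tuning.baseline_hz)
    if tuning.weights is not None:
        rates = rates + tuning.weights @ X.T
    if tuning.semantic_gain:
        meta = stimset.metadata()
        gain_obj = np.array([
            tuning.semantic_gain.get(lbl, 0.0)
            for lbl in meta["semantic_label"]
        ])
        gw = (
            np.ones(n_neu)
            if tuning.semantic_gain_weights is None
            else np.asarray(tuning.semantic_gain_weights, dtype=float)
        )
        rates = rates + np.outer(gw, gain_obj)
    rates = np.clip(rates, 0.0, None)

    lam = rates[:, :, None] * WINDOW_S
    counts = rng.poisson(
        np.broadcast_to(lam, (n_neu, n_obj, tuning.repetitions))
    )
    bg_hz = (
        tuning.baseline_hz if tuning.background_hz is None
        else tuning.background_hz
    )
    bg = rng.poisson(bg_hz * WINDOW_S, (n_neu, tuning.n_background_trials))
    return ResponseDataset(
        counts=counts,
        background_counts=bg,
        object_ids=list(stimset.object_ids),
        neuron_ids=[f"n{i:03d}" for i in range(n_neu)],
    )


def screen_responsive(
    ds: ResponseDataset, alpha: float = 0.005
) -> ResponseDataset:
    """Keep neurons responding to at least one object above background.

    A neuron is retained when, for at least one object, a one-sided Welch
    two-sample t-test of its response counts against its background counts
    gives p < ``alpha``.  Object tests with zero variance in both samples
    are skipped (logged).
    """
    if ds.background_counts.size == 0:
        raise ValueError("background counts required for screening")
    keep = []
    for i in range(ds.n_neurons):
        bg = ds.background_counts[i]
        responsive = False
        for j in range(ds.n_objects):
            fg = ds.counts[i, j]
            if fg.std() == 0 and bg.std() == 0:
                if fg[0] != bg[0]:
                    # degenerate but unambiguous difference
                    responsive = fg[0] > bg[0]
                    if responsive:
                        break
                logger.debug(
                    "zero-variance t-test skipped: neuron %s object %s",
                    ds.neuron_ids[i], ds.object_ids[j],
                )
                continue
            _, p = stats.ttest_ind(
                fg, bg, equal_var=False, alternative="greater"
            )
            if p < alpha:
                responsive = True
                break
        if responsive:
            keep.append(i)
    logger.info("screening retained %d/%d neurons", len(keep), ds.n_neurons)
    return ds.subset_neurons(keep)
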