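"""Walking/running classification of prints and trackways.

Fossil trackway comparisons are gait-matched: a fossil trackway is compared
only against reference prints made with the same gait.  The gait of a fossil
trackway is predicted with a bagged classification-tree ensemble trained on
the reference prints' five external measurements plus the 14 regional depths,
mirroring the bagging machinery of the mass model.  Trackway labels come from
a majority vote over the per-print predictions, with ties resolved toward
walking (the dominant reference activity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .schema import DEPTH_COLUMNS, MEASUREMENT_COLUMNS

__all__ = ["GaitLabel", "GaitClassifier", "fit_gait_classifier", "predict_gait"]

logger = logging.getLogger(__name__)

GAIT_FEATURES: tuple[str, ...] = MEASUREMENT_COLUMNS + DEPTH_COLUMNS
CLASSES = ("walking", "running")


@dataclass(frozen=True)
class GaitLabel:
    """Predicted gait of a trackway with its vote fraction."""

    value: str  # "walking" | "running"
    probability: float  # fraction of prints voting for the emitted label

    def __post_init__(self) -> None:
        if self.value not in CLASSES:
            raise ValueError(f"gait must be one of {CLASSES}")
        if not 0.5 <= self.probability <= 1.0:
            raise ValueError("emitted-label probability must lie in [0.5, 1.0]")


@dataclass
class GaitClassifier:
    """Bagged classification-tree ensemble over measurements + depth profile."""

    trees: list[DecisionTreeClassifier] = field(repr=False)
    oob_error: float
    n_train: int
    seed: int
    feature_names: tuple[str, ...] = GAIT_FEATURES

    def predict_prints(self, records: pd.DataFrame) -> np.ndarray:
        """Per-print labels: majority vote of the trees (ties -> walking)."""
        X = records[list(self.feature_names)].to_numpy(dtype=float)
        votes_running = np.zeros(len(X))
        for tree in self.trees:
            votes_running += tree.predict(X)
        frac = votes_running / len(self.trees)
        return np.where(frac > 0.5, "running", "walking")


def fit_gait_classifier(
    records: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    min_samples_leaf: int = 1,
) -> GaitClassifier:
    """Fit the bagged gait classifier on labelled reference prints.

    Requires both classes in the training labels.  Each tree is grown on a
    full-size bootstrap with ``ceil(sqrt(p))`` features tried per split; the
    out-of-bag majority vote gives the reported OOB error rate.
    """
    labels = records["gait"].to_numpy()
    present = set(labels)
    if not {"walking", "running"} <= present:
        raise ValueError(
            f"gait training data must contain both classes, found {sorted(present)}"
        )
    X = records[list(GAIT_FEATURES)].to_numpy(dtype=float)
    y = (labels == "running").astype(int)
    n, p = X.shape
    rng = np.random.default_rng([seed, 12])
    max_features = math.ceil(math.sqrt(p))
    trees = []
    oob_votes = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    all_idx = np.arange(n)
    for _ in range(n_trees):
        draw = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_idx, np.unique(draw), assume_unique=True)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[draw], y[draw])
        if oob.size:
            oob_votes[oob] += tree.predict(X[oob])
            oob_count[oob] += 1
        trees.append(tree)
    covered = oob_count > 0
    oob_pred = (oob_votes[covered] / oob_count[covered]) > 0.5
    oob_error = float(np.mean(oob_pred != y[covered].astype(bool)))
    return GaitClassifier(trees=trees, oob_error=oob_error, n_train=n, seed=seed)


def predict_gait(classifier: GaitClassifier, trackway: pd.DataFrame) -> GaitLabel:
    """Trackway gait: majority vote over per-print predictions.

    An exact tie is broken toward walking and logged.  The reported
    probability is the vote fraction of the emitted label (>= 0.5).
    """
    usable = trackway.dropna(subset=list(classifier.feature_names))
    if len(usable) == 0:
        raise ValueError("trackway has no prints with complete features")
    per_print = classifier.predict_prints(usable)
    frac_walking = float(np.mean(per_print == "walking"))
    if frac_walking == 0.5:
        logger.warning("gait vote tied for trackway; resolving toward walking")
    if frac_walking >= 0.5:
        return GaitLabel("walking", frac_walking)
    return GaitLabel("running", 1.0 - frac_walking)
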