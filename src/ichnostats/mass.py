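"""Body-mass estimation from footprint dimensions.

A bagged ensemble of regression trees predicts body mass (kg) from five
external print measurements: heel-to-hallux length, heel-to-2nd-toe length,
forefoot breadth, heel breadth, and average depth.  Each tree is grown on a
full-size bootstrap sample of the training rows; the rows not drawn form that
tree's out-of-bag (OOB) set, giving an internal error estimate.  A linear
regression of mass on heel-to-hallux length serves as the baseline that
ensemble predictions are benchmarked against.  Fossil trackways are predicted
from their average print dimensions.

Bookkeeping note: with full n-with-replacement bootstraps, a tree of n
training rows sees about n*(1 - (1-1/n)^n) ~ 0.632*n unique rows in-bag
(217 of 343) and the remaining ~0.368*n (126) out-of-bag, in expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .schema import MEASUREMENT_COLUMNS

__all__ = [
    "MassModel",
    "LengthRegression",
    "ModelEvaluation",
    "split_train_test",
    "fit_mass_model",
    "predict_mass",
    "predict_trackway_mass",
    "fit_length_regression",
    "evaluate",
]

MASS_COLUMN = "body_mass_kg"
LENGTH_COLUMN = "heel_to_hallux_length_cm"
SUBJECT_COLUMN = "subject_or_trackway_id"


def split_train_test(
    records: pd.DataFrame,
    fraction: float = 0.70,
    seed: int = 0,
    group_by_subject: bool = True,
) -> dict[str, pd.DataFrame]:
    """Seeded train/test partition of the reference footprint table.

    With ``group_by_subject`` (the default) all prints of a subject land on
    the same side of the split, avoiding leakage of a subject's repeated
    prints across the partition; subjects are accumulated into the training
    side until it holds at least ``round(fraction * n)`` rows.  With
    ``group_by_subject=False`` rows are partitioned individually and the
    training size is exactly ``round(fraction * n)`` (490 rows at the default
    fraction split 343 / 147).
    """
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records with known mass to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise ValueError("split fraction must lie strictly between 0 and 1 "
                         "(both partitions must be non-empty)")
    if records[MASS_COLUMN].isna().any():
        raise ValueError("every record in a training split must carry body_mass_kg")
    rng = np.random.default_rng([seed, 10])
    target = int(round(fraction * n))
    if group_by_subject:
        subjects = records[SUBJECT_COLUMN].unique()
        order = rng.permutation(subjects)
        counts = records[SUBJECT_COLUMN].value_counts()
        train_subjects, total = [], 0
        for s in order:
            if total >= target:
                break
            train_subjects.append(s)
            total += int(counts[s])
        in_train = records[SUBJECT_COLUMN].isin(train_subjects)
        train, test = records[in_train], records[~in_train]
    else:
        perm = rng.permutation(n)
        train = records.iloc[perm[:target]]
        test = records.iloc[perm[target:]]
    if len(train) == 0 or len(test) == 0:
        raise ValueError("degenerate split: one partition is empty")
    return {"train": train, "test": test}


@dataclass
class MassModel:
    """Bagged regression-tree ensemble with per-tree in-bag bookkeeping."""

    trees: list[DecisionTreeRegressor] = field(repr=False)
    inbag_indices: list[np.ndarray] = field(repr=False)  # unique in-bag rows per tree
    oob_indices: list[np.ndarray] = field(repr=False)
    training_response_range: tuple[float, float]
    rmse_oob: float
    n_train: int
    split_seed: int | None
    bootstrap_seed: int
    feature_names: tuple[str, ...] = MEASUREMENT_COLUMNS

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def mean_inbag_unique(self) -> float:
        """Average number of distinct training rows seen per tree."""
        return float(np.mean([len(ib) for ib in self.inbag_indices]))


def fit_mass_model(
    train: pd.DataFrame,
    n_trees: int = 500,
    bootstrap_seed: int = 0,
    split_seed: int | None = None,
    max_features: int | None = None,
    min_samples_leaf: int = 5,
) -> MassModel:
    """Fit the bagged regression-tree mass model.

    Per tree: draw a full-size bootstrap (n rows with replacement) from the
    training table; the unique sampled rows are that tree's in-bag set and the
    remainder its OOB set (in-bag and OOB partition the training rows).  Trees
    are grown without a depth limit, trying ``ceil(p/3)`` of the p = 5
    predictors at each split and stopping at leaves of ``min_samples_leaf``
    rows — conventional regression-forest settings.  OOB predictions are
    accumulated across trees into ``rmse_oob``.
    """
    X = train[list(MEASUREMENT_COLUMNS)].to_numpy(dtype=float)
    y = train[MASS_COLUMN].to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 training records")
    if np.ptp(X, axis=0).max() == 0 and np.ptp(y) != 0:
        raise ValueError("uninformative training data: every predictor is constant")
    if max_features is None:
        max_features = math.ceil(p / 3)
    rng = np.random.default_rng([bootstrap_seed, 11])
    trees, inbags, oobs = [], [], []
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    all_idx = np.arange(n)
    for _ in range(n_trees):
        draw = rng.integers(0, n, size=n)
        inbag = np.unique(draw)
        oob = np.setdiff1d(all_idx, inbag, assume_unique=True)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[draw], y[draw])
        if oob.size:
            oob_sum[oob] += tree.predict(X[oob])
            oob_count[oob] += 1
        trees.append(tree)
        inbags.append(inbag)
        oobs.append(oob)
    covered = oob_count > 0
    if covered.any():
        resid = y[covered] - oob_sum[covered] / oob_count[covered]
        rmse_oob = float(np.sqrt(np.mean(resid**2)))
    else:
        warnings.warn("no training row was ever out-of-bag; OOB RMSE undefined")
        rmse_oob = float("nan")
    return MassModel(
        trees=trees,
        inbag_indices=inbags,
        oob_indices=oobs,
        training_response_range=(float(y.min()), float(y.max())),
        rmse_oob=rmse_oob,
        n_train=n,
        split_seed=split_seed,
        bootstrap_seed=bootstrap_seed,
    )


def _as_feature_matrix(measurements, feature_names) -> np.ndarray:
    if isinstance(measurements, pd.DataFrame):
        return measurements[list(feature_names)].to_numpy(dtype=float)
    if isinstance(measurements, (pd.Series, dict)):
        return np.array([[float(measurements[c]) for c in feature_names]])
    arr = np.atleast_2d(np.asarray(measurements, dtype=float))
    if arr.shape[1] != len(feature_names):
        raise ValueError(f"expected {len(feature_names)} predictors, got {arr.shape[1]}")
    return arr


def predict_mass(model: MassModel, measurements) -> np.ndarray | float:
    """Ensemble prediction: the mean of the per-tree predictions.

    Accepts a DataFrame (one prediction per row), a Series/dict of the five
    measurements, or a bare array.  Predictions always lie within the training
    response range, since every tree predicts averages of training masses.
    """
    if not model.trees:
        raise ValueError("model has no trees; fit it first")
    X = _as_feature_matrix(measurements, model.feature_names)
    preds = np.mean([t.predict(X) for t in model.trees], axis=0)
    if isinstance(measurements, (pd.Series, dict)) or X.shape[0] == 1 and not isinstance(
        measurements, pd.DataFrame
    ):
        return float(preds[0])
    return preds


def predict_trackway_mass(model: MassModel, trackway: pd.DataFrame) -> float:
    """One mass prediction for a trackway from its average print dimensions."""
    cols = list(model.feature_names)
    complete = trackway.dropna(subset=cols)
    if len(complete) == 0:
        raise ValueError("trackway has no prints with complete measurements")
    mean_measurements = complete[cols].mean()
    return float(predict_mass(model, mean_measurements))


@dataclass(frozen=True)
class LengthRegression:
    """OLS of body mass on heel-to-hallux length: the single-predictor baseline."""

    slope: float
    intercept: float
    r_value: float
    n: int

    def predict(self, length) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(length, dtype=float)


def fit_length_regression(train: pd.DataFrame) -> LengthRegression:
    """Ordinary least squares of mass (kg) on print length (cm)."""
    x = train[LENGTH_COLUMN].to_numpy(dtype=float)
    y = train[MASS_COLUMN].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 records for a length regression")
    if np.ptp(x) == 0:
        raise ValueError("footprint length is constant; regression undefined")
    if len(x) == 2:
        warnings.warn("length regression fit to 2 points: zero residual degrees of freedom")
    res = stats.linregress(x, y)
    return LengthRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        n=len(x),
    )


@dataclass(frozen=True)
class ModelEvaluation:
    """Held-out accuracy of the ensemble and the length-only baseline."""

    rmse_oob: float
    rmse_test: float
    rmse_linear_test: float
    n_train: int
    n_test: int


def evaluate(
    model: MassModel, linear_model: LengthRegression, test: pd.DataFrame
) -> ModelEvaluation:
    """Test-set RMSEs of both models on identical rows."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    y = test[MASS_COLUMN].to_numpy(dtype=float)
    pred_ens = predict_mass(model, test)
    pred_lin = linear_model.predict(test[LENGTH_COLUMN])
    return ModelEvaluation(
        rmse_oob=model.rmse_oob,
        rmse_test=float(np.sqrt(np.mean((y - pred_ens) ** 2))),
        rmse_linear_test=float(np.sqrt(np.mean((y - pred_lin) ** 2))),
        n_train=model.n_train,
        n_test=len(test),
    )
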