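"""Trackway-vs-reference comparison via a subject-level resampling null.

The question: is a fossil trackway's mean 14-region depth topography within
the range of variation of modern human footprints made in comparable
substrate?  The test statistic is the Mahalanobis distance between the fossil
trackway's mean profile and the mean reference profile, under the reference
covariance.  Its null distribution is built by resampling: repeatedly pick one
reference subject, draw from that subject as many prints as the fossil
trackway has, average them, and measure the Mahalanobis distance of that
average from the mean and covariance of the *remaining* subjects' prints.
Sampling whole subjects (not pooled prints) respects the repeated-measures
structure of the reference data: prints of one individual are not independent.

The reported p-value is the probability of a resampled human distance at
least as large as the fossil one; with the default ``plus_one`` rule,
p = (1 + #{null >= d}) / (1 + n_iterations), so a finite null never yields
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from sklearn.covariance import LedoitWolf

from .gait import GaitClassifier, GaitLabel, predict_gait
from .schema import DEPTH_COLUMNS, DEPTH_LANDMARKS, DepthProfile, profiles_to_array

__all__ = [
    "ComparisonConfig",
    "ResamplingResult",
    "SingularCovarianceError",
    "mean_profile",
    "mahalanobis",
    "resample_null",
    "compare_trackway",
    "holdout_subject_pvalue",
]

SUBJECT_COLUMN = "subject_or_trackway_id"


class SingularCovarianceError(np.linalg.LinAlgError):
    """Covariance is singular and shrinkage is disabled."""


@dataclass(frozen=True)
class ComparisonConfig:
    """Knobs of the resampling comparison test."""

    n_iterations: int = 10_000
    gait_match: bool = True
    covariance_estimator: str = "sample"  # "sample" | "shrinkage" (Ledoit-Wolf)
    covariance_scope: str = "out_of_sample"  # "out_of_sample" | "full_pool" (fast, biased)
    within_subject_sampling: str = "without_replacement"  # | "with_replacement"
    mean_scope: str = "per_print"  # "per_print" | "per_subject"
    p_value_rule: str = "plus_one"  # "plus_one" | "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.covariance_estimator not in ("sample", "shrinkage"):
            raise ValueError("covariance_estimator must be 'sample' or 'shrinkage'")
        if self.covariance_scope not in ("out_of_sample", "full_pool"):
            raise ValueError("covariance_scope must be 'out_of_sample' or 'full_pool'")
        if self.within_subject_sampling not in ("without_replacement", "with_replacement"):
            raise ValueError("unknown within-subject sampling mode")
        if self.mean_scope not in ("per_print", "per_subject"):
            raise ValueError("mean_scope must be 'per_print' or 'per_subject'")
        if self.p_value_rule not in ("plus_one", "raw"):
            raise ValueError("p_value_rule must be 'plus_one' or 'raw'")


@dataclass(frozen=True)
class ResamplingResult:
    """Outcome of one fossil-trackway comparison."""

    fossil_distance: float
    null_distances: np.ndarray = field(repr=False)
    p_value: float
    n_prints_matched: int  # reference prints in the gait-matched pool
    n_prints_fossil: int
    gait_used: GaitLabel
    seed: int


def mean_profile(profiles) -> DepthProfile:
    """Element-wise mean of depth profiles over the 14 regions.

    Accepts a list of :class:`DepthProfile`, an (n, 14) array, or a DataFrame
    carrying the canonical depth columns.
    """
    if isinstance(profiles, pd.DataFrame):
        arr = profiles[list(DEPTH_COLUMNS)].to_numpy(dtype=float)
    elif isinstance(profiles, np.ndarray):
        arr = np.atleast_2d(profiles)
    else:
        arr = profiles_to_array(profiles)
    if arr.shape[0] == 0:
        raise ValueError("empty list of depth profiles")
    return DepthProfile(arr.mean(axis=0))


def _deficient_directions(cov: np.ndarray) -> list[str]:
    """Landmarks dominating the null-space directions of a singular covariance."""
    eigvals, eigvecs = np.linalg.eigh(cov)
    tol = max(cov.shape[0] * np.finfo(float).eps * max(eigvals.max(), 0.0), 1e-300)
    names = []
    for k in np.nonzero(eigvals <= tol)[0]:
        loading = int(np.argmax(np.abs(eigvecs[:, k])))
        names.append(DEPTH_LANDMARKS[loading])
    return sorted(set(names))


def _negligible(diff: np.ndarray, *operands: np.ndarray) -> bool:
    """True when the difference is zero up to rounding of its operands' scale."""
    scale = max(1.0, *(float(np.abs(op).max()) for op in operands if op.size))
    return bool(np.abs(diff).max() <= 1e-12 * scale)


def _cholesky_or_raise(cov: np.ndarray):
    try:
        return cho_factor(np.asarray(cov, dtype=float), lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "covariance is singular (deficient directions dominated by "
            f"{_deficient_directions(np.asarray(cov, dtype=float))}); "
            "enable shrinkage or enlarge the pool"
        ) from exc


def mahalanobis(x, mu, cov: np.ndarray) -> float:
    """sqrt((x - mu)^T cov^{-1} (x - mu)).

    ``x`` and ``mu`` may be :class:`DepthProfile` or plain vectors.  A zero
    difference returns 0 for any covariance (including a singular one: the
    zero vector has zero norm in every metric).  A singular covariance with a
    nonzero difference raises :class:`SingularCovarianceError` naming the
    deficient directions.
    """
    xv = x.values if isinstance(x, DepthProfile) else np.asarray(x, dtype=float)
    mv = mu.values if isinstance(mu, DepthProfile) else np.asarray(mu, dtype=float)
    diff = xv - mv
    if _negligible(diff, xv, mv):
        return 0.0
    factor = _cholesky_or_raise(cov)
    return float(np.sqrt(diff @ cho_solve(factor, diff)))


def _pool_arrays(pool: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = pool[list(DEPTH_COLUMNS)].to_numpy(dtype=float)
    subjects = pool[SUBJECT_COLUMN].to_numpy()
    return X, subjects


def _estimate_cov(rows: np.ndarray, estimator: str) -> np.ndarray:
    if estimator == "shrinkage":
        return LedoitWolf(assume_centered=False).fit(rows).covariance_
    return np.cov(rows, rowvar=False)


def _reference_stats(
    X: np.ndarray,
    subjects: np.ndarray,
    exclude,
    config: ComparisonConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the reference pool with one subject held out.

    The mean always excludes the held-out subject ("the rest of the human
    subjects"); with ``covariance_scope="full_pool"`` the covariance reuses
    the whole pool (faster, slightly biased toward the held-out subject).
    """
    keep = subjects != exclude
    rest = X[keep]
    if config.mean_scope == "per_subject":
        labels = subjects[keep]
        mu = np.mean(
            [rest[labels == s].mean(axis=0) for s in pd.unique(labels)], axis=0
        )
    else:
        mu = rest.mean(axis=0)
    cov_rows = X if config.covariance_scope == "full_pool" else rest
    return mu, _estimate_cov(cov_rows, config.covariance_estimator)


def resample_null(
    pool: pd.DataFrame, n_prints: int, config: ComparisonConfig
) -> np.ndarray:
    """Null distribution of trackway-sized human mean-profile distances.

    Per iteration: (1) draw one subject uniformly among eligible subjects,
    (2) sample ``n_prints`` of that subject's prints (without replacement by
    default; subjects with fewer prints are ineligible in that mode),
    (3) average them, (4) measure the Mahalanobis distance of the average from
    the mean/covariance of the remaining subjects' prints.  Returns
    ``config.n_iterations`` distances; fully determined by ``config.seed``.

    Iterations that share a held-out subject share its out-of-sample mean and
    covariance, so those statistics are computed once per subject.
    """
    X, subjects = _pool_arrays(pool)
    unique_subjects = pd.unique(subjects)
    if len(unique_subjects) < 3:
        raise ValueError("resampling needs at least 3 reference subjects")
    groups = {s: np.nonzero(subjects == s)[0] for s in unique_subjects}
    without = config.within_subject_sampling == "without_replacement"
    eligible = [
        s for s in unique_subjects if (len(groups[s]) >= n_prints or not without)
    ]
    if not eligible:
        raise ValueError(
            f"no subject has >= {n_prints} prints for without-replacement sampling"
        )
    rng = np.random.default_rng([config.seed, 13])
    draws = rng.integers(0, len(eligible), size=config.n_iterations)
    out = np.empty(config.n_iterations)
    for k, s in enumerate(eligible):
        positions = np.nonzero(draws == k)[0]
        if positions.size == 0:
            continue
        idx_s = groups[s]
        mu, cov = _reference_stats(X, subjects, s, config)
        m = positions.size
        if without:
            order = np.argsort(rng.random((m, len(idx_s))), axis=1)[:, :n_prints]
        else:
            order = rng.integers(0, len(idx_s), size=(m, n_prints))
        means = X[idx_s][order].mean(axis=1)
        diffs = means - mu
        if _negligible(diffs, means, mu):  # zero norm in any metric
            out[positions] = 0.0
            continue
        factor = _cholesky_or_raise(cov)
        z = solve_triangular(factor[0], diffs.T, lower=True)
        out[positions] = np.sqrt(np.sum(z**2, axis=0))
    return out


def _p_value(fossil_distance: float, null: np.ndarray, rule: str) -> float:
    exceed = int(np.sum(null >= fossil_distance))
    if rule == "plus_one":
        return (1 + exceed) / (1 + len(null))
    return exceed / len(null)


def _resolve_gait(
    fossil: pd.DataFrame,
    classifier: GaitClassifier | None,
    gait: str | GaitLabel | None,
) -> GaitLabel:
    if isinstance(gait, GaitLabel):
        return gait
    if gait is not None:
        return GaitLabel(gait, 1.0)
    if classifier is not None:
        return predict_gait(classifier, fossil)
    if "gait" in fossil.columns:
        values = set(fossil["gait"].dropna()) - {"unknown"}
        if len(values) == 1:
            return GaitLabel(values.pop(), 1.0)
    raise ValueError(
        "cannot determine fossil gait: provide a classifier, an explicit gait, "
        "or a uniform gait column"
    )


def compare_trackway(
    fossil: pd.DataFrame,
    pool: pd.DataFrame,
    classifier: GaitClassifier | None = None,
    config: ComparisonConfig = ComparisonConfig(),
    gait: str | GaitLabel | None = None,
) -> ResamplingResult:
    """Compare one fossil trackway's mean topography against the human pool.

    The reference pool is first restricted to prints of the trackway's
    (predicted or supplied) gait; the null is resampled with trackway-sized
    subject draws; the fossil distance is measured from the matched pool's
    grand mean under its covariance; and the p-value is the probability of a
    human distance at least that large.
    """
    fossil_profiles = fossil.dropna(subset=list(DEPTH_COLUMNS))
    if len(fossil_profiles) == 0:
        raise ValueError("fossil trackway has no prints with depth profiles")
    gait_label = _resolve_gait(fossil_profiles, classifier, gait)
    matched = pool
    if config.gait_match and "gait" in pool.columns:
        matched = pool[pool["gait"] == gait_label.value]
        if len(matched) == 0:
            raise ValueError(
                f"reference pool has no prints with gait {gait_label.value!r}"
            )
    n_prints = len(fossil_profiles)
    null = resample_null(matched, n_prints, config)
    X, _ = _pool_arrays(matched)
    if config.mean_scope == "per_subject":
        labels = matched[SUBJECT_COLUMN].to_numpy()
        grand_mean = np.mean(
            [X[labels == s].mean(axis=0) for s in pd.unique(labels)], axis=0
        )
    else:
        grand_mean = X.mean(axis=0)
    cov = _estimate_cov(X, config.covariance_estimator)
    fossil_distance = mahalanobis(
        mean_profile(fossil_profiles).values, grand_mean, cov
    )
    return ResamplingResult(
        fossil_distance=fossil_distance,
        null_distances=null,
        p_value=_p_value(fossil_distance, null, config.p_value_rule),
        n_prints_matched=len(matched),
        n_prints_fossil=n_prints,
        gait_used=gait_label,
        seed=config.seed,
    )


def holdout_subject_pvalue(
    pool: pd.DataFrame,
    subject,
    config: ComparisonConfig,
    n_prints: int | None = None,
) -> float:
    """Self-consistency probe: treat one pool subject's prints as the fossil.

    The held-out subject's prints (all of them, or the first ``n_prints``)
    become a pseudo-fossil trackway and are compared against the remaining
    subjects.  Over many held-out subjects and seeds the resulting p-values
    should be approximately uniform — the calibration check behind the test's
    type-I error rate.
    """
    mask = pool[SUBJECT_COLUMN] == subject
    fossil = pool[mask]
    if n_prints is not None:
        fossil = fossil.iloc[:n_prints]
    rest = pool[~mask]
    result = compare_trackway(
        fossil, rest, config=config, gait=None if "gait" in fossil.columns else "walking"
    )
    return result.p_value
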