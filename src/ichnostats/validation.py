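"""Simulation experiments that validate the pipeline against known truth.

Each function runs one self-contained experiment on synthetic data and
returns the summary quantity a methods reader would ask for: the numerical
agreement of the Mahalanobis implementation with a brute-force inverse, the
type-I error and power of the resampling comparison test, the accuracy
ordering of the mass models, the bagging bookkeeping, the geometry round
trip, and the recovery rate of mean-method sexing.  The package's tests and
the acceptance script both drive these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compare, geometry, mass, sexing, synthetic
from .schema import DEPTH_COLUMNS

__all__ = [
    "mahalanobis_oracle_gap",
    "resampling_type1_error",
    "resampling_power",
    "mass_model_ordering",
    "bagging_inbag_count",
    "geometry_round_trip",
    "mean_method_recovery",
    "pipeline_determinism",
]


def _gauss_jordan_inverse(a: np.ndarray) -> np.ndarray:
    """Explicit matrix inverse by Gauss-Jordan elimination with partial pivoting.

    Deliberately naive: the independent route against which the Cholesky-based
    Mahalanobis implementation is checked.
    """
    n = a.shape[0]
    aug = np.hstack([a.astype(float).copy(), np.eye(n)])
    for col in range(n):
        pivot = col + int(np.argmax(np.abs(aug[col:, col])))
        if aug[pivot, col] == 0:
            raise np.linalg.LinAlgError("singular matrix")
        aug[[col, pivot]] = aug[[pivot, col]]
        aug[col] = aug[col] / aug[col, col]
        for row in range(n):
            if row != col:
                aug[row] = aug[row] - aug[row, col] * aug[col]
    return aug[:, n:]


def mahalanobis_oracle_gap(n_instances: int = 100, seed: int = 0) -> float:
    """Worst absolute disagreement with the explicit-inverse oracle.

    Random SPD covariances of dimension 2-14; returns max |implementation -
    oracle| over all instances.
    """
    rng = np.random.default_rng([seed, 20])
    worst = 0.0
    for _ in range(n_instances):
        dim = int(rng.integers(2, 15))
        a = rng.normal(size=(dim, dim))
        cov = a @ a.T + 1e-3 * dim * np.eye(dim)
        x, mu = rng.normal(size=dim), rng.normal(size=dim)
        ours = compare.mahalanobis(x, mu, cov)
        diff = x - mu
        oracle = float(np.sqrt(diff @ _gauss_jordan_inverse(cov) @ diff))
        worst = max(worst, abs(ours - oracle))
    return worst


def resampling_type1_error(
    n_replicates: int = 500,
    n_iterations: int = 2000,
    alpha: float = 0.05,
    n_subjects: int = 41,
    prints_per_subject: int = 12,
    n_prints: int = 5,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the comparison test on a null human pool.

    A multivariate-normal pool of exchangeable subjects; each replicate holds
    one subject out, treats ``n_prints`` of its prints as a pseudo-fossil
    trackway, and records whether p < alpha.  A calibrated test rejects at
    close to the nominal rate.
    """
    rejections = 0
    for r in range(n_replicates):
        pool = synthetic.generate_profile_pool(
            n_subjects=n_subjects, prints_per_subject=prints_per_subject,
            seed=seed * 100_003 + r,
        )
        subjects = pool["subject_or_trackway_id"].unique()
        held_out = subjects[r % len(subjects)]
        config = compare.ComparisonConfig(
            n_iterations=n_iterations, seed=seed * 100_003 + 50_000 + r
        )
        p = compare.holdout_subject_pvalue(pool, held_out, config, n_prints=n_prints)
        rejections += p < alpha
    return rejections / n_replicates


def resampling_power(
    n_runs: int = 100,
    shift_sd: float = 3.0,
    n_iterations: int = 2000,
    n_prints: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate against a divergent ("Laetoli-like") forefoot template.

    The pseudo-fossil trackway is drawn from the human walking template with
    its forefoot depth gradient shifted laterally by ``shift_sd`` pooled SDs
    of per-print depth slope.
    """
    rejections = 0
    for r in range(n_runs):
        pool = synthetic.generate_profile_pool(seed=seed * 4999 + r)
        fossil = synthetic.generate_divergent_trackway_profiles(
            n_prints=n_prints, shift_sd=shift_sd, seed=seed * 4999 + r
        )
        config = compare.ComparisonConfig(
            n_iterations=n_iterations, seed=seed * 4999 + 70_000 + r
        )
        result = compare.compare_trackway(fossil, pool, config=config)
        rejections += result.p_value < alpha
    return rejections / n_runs


def mass_model_ordering(
    n_replicates: int = 50, n_trees: int = 500, seed: int = 0
) -> dict[str, float]:
    """Ensemble vs length-only baseline over seeded replicates of the study.

    Each replicate generates a fresh default population (~490 prints), splits
    rows 70/30, fits both models on the training side and scores both on the
    identical test rows.  Returns the fraction of replicates where the
    ensemble wins and the mean test RMSEs (kg).
    """
    wins = 0
    rmse_ens, rmse_lin = [], []
    for r in range(n_replicates):
        rep_seed = seed * 20_011 + r
        cfg = synthetic.PopulationConfig(seed=rep_seed)
        table = synthetic.generate_footprints(
            synthetic.generate_population(cfg), cfg
        )
        split = mass.split_train_test(
            table, seed=rep_seed, group_by_subject=False
        )
        model = mass.fit_mass_model(
            split["train"], n_trees=n_trees, bootstrap_seed=rep_seed
        )
        baseline = mass.fit_length_regression(split["train"])
        ev = mass.evaluate(model, baseline, split["test"])
        wins += ev.rmse_test < ev.rmse_linear_test
        rmse_ens.append(ev.rmse_test)
        rmse_lin.append(ev.rmse_linear_test)
    return {
        "ensemble_win_fraction": wins / n_replicates,
        "rmse_ensemble_kg": float(np.mean(rmse_ens)),
        "rmse_linear_kg": float(np.mean(rmse_lin)),
    }


def bagging_inbag_count(
    n_train: int = 343, n_trees: int = 500, n_seeds: int = 5, seed: int = 0
) -> float:
    """Mean unique in-bag count per tree for full-size bootstraps of n rows.

    For n = 343 the theoretical expectation n(1 - (1 - 1/n)^n) is 217.0, with
    126.0 rows out-of-bag.
    """
    rng = np.random.default_rng([seed, 21])
    counts = []
    for s in range(n_seeds):
        table = pd.DataFrame(
            {c: rng.uniform(5, 30, n_train) for c in mass.MEASUREMENT_COLUMNS}
        )
        table["body_mass_kg"] = rng.uniform(20, 70, n_train)
        table["subject_or_trackway_id"] = [f"s{i}" for i in range(n_train)]
        model = mass.fit_mass_model(
            table, n_trees=n_trees, bootstrap_seed=seed * 7919 + s
        )
        counts.append(model.mean_inbag_unique())
    return float(np.mean(counts))


def geometry_round_trip(
    n_surfaces: int = 5, tilt: tuple = (0.05, -0.03, 0.4), seed: int = 0
) -> dict[str, float]:
    """Depth and plane-coefficient recovery on tilted noiseless surfaces.

    Returns the worst landmark-depth error (cm) and worst plane-coefficient
    error over the generated surfaces.
    """
    cfg = synthetic.PopulationConfig(seed=seed)
    table = synthetic.generate_footprints(synthetic.generate_population(cfg), cfg)
    surface_cfg = synthetic.SurfaceConfig(tilt=tilt)
    worst_depth = 0.0
    worst_coef = 0.0
    for i in range(n_surfaces):
        record = table.iloc[i]
        surface = synthetic.generate_surface(record, surface_cfg)
        plane = geometry.fit_reference_plane(surface)
        worst_coef = max(
            worst_coef, float(np.abs(np.array(plane.coefficients) - tilt).max())
        )
        oriented = geometry.orient_surface(surface, plane)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # template noise can dip below 0
            measured = geometry.measure_depths(oriented)
        truth = np.array([record[c] for c in DEPTH_COLUMNS])
        worst_depth = max(worst_depth, float(np.abs(measured.values - truth).max()))
    return {"max_depth_error_cm": worst_depth, "max_plane_coef_error": worst_coef}


def mean_method_recovery(
    n_assemblages: int = 1000,
    n_trackways: int = 16,
    dimorphism_sd: float = 1.5,
    seed: int = 0,
) -> dict[str, float]:
    """Accuracy and count-conservation of mean-method sexing under dimorphism.

    Assemblages of ``n_trackways`` adults, half male, with sex-specific mass
    means separated by ``dimorphism_sd`` pooled standard deviations; the mean
    method is applied to the true masses and scored against the generating
    sexes.
    """
    sd = 5.0
    gap = dimorphism_sd * sd
    population = synthetic.PopulationConfig(
        mass_mean_male=51.0 + gap / 2, mass_mean_female=51.0 - gap / 2, mass_sd=sd
    )
    accs = []
    conserved = 0
    for r in range(n_assemblages):
        scenario = synthetic.generate_fossil_scenario(
            synthetic.FossilScenarioConfig(
                n_trackways=n_trackways, prints_per_trackway=1,
                population=population, seed=seed * 49_999 + r,
            )
        )
        truth = scenario["truth"]
        predictions = truth.rename(columns={"body_mass_kg": "predicted_mass_kg"})[
            ["trackway_id", "predicted_mass_kg", "site_id"]
        ]
        out = sexing.attribute_sex(predictions)
        acc = np.mean(
            [a.predicted_sex == s for a, s in zip(out, truth["sex"])]
        )
        accs.append(acc)
        comp = sexing.site_composition(out)
        totals = comp[["males", "females", "excluded"]].sum(axis=1)
        conserved += bool((totals == comp["trackways"]).all())
    return {
        "accuracy": float(np.mean(accs)),
        "conservation_rate": conserved / n_assemblages,
    }


def pipeline_determinism(tmp_dir, seed: int = 0) -> bool:
    """True when two pipeline runs from one config give byte-identical tables."""
    from pathlib import Path

    from . import pipeline

    config = {
        "seed": seed,
        "mass": {"n_trees": 100},
        "compare": {"n_iterations": 500},
        "fossil_scenario": {"n_trackways": 6, "prints_per_trackway": 4},
    }
    tmp_dir = Path(tmp_dir)
    pipeline.run_pipeline(config, output_dir=tmp_dir / "run_a")
    pipeline.run_pipeline(config, output_dir=tmp_dir / "run_b")
    names = sorted(p.name for p in (tmp_dir / "run_a").glob("*.csv"))
    if not names:
        return False
    return all(
        (tmp_dir / "run_a" / n).read_bytes() == (tmp_dir / "run_b" / n).read_bytes()
        for n in names
    )
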