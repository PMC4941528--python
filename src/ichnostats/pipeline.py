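"""End-to-end analysis pipeline: measure -> mass -> gait -> compare -> sex.

Driven by one configuration mapping (typically loaded from YAML).  Every run
writes its report tables and a manifest (config snapshot, seeds, package
version, input digests, timestamp) into a run directory; all stochastic
stages derive their randomness from the single configured seed, so two runs
with the same configuration produce byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, compare, gait, io, mass, sexing, synthetic
from .schema import DEPTH_COLUMNS

__all__ = ["PipelineStageError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_reference(config: dict, seed: int) -> pd.DataFrame:
    pop_kwargs = dict(config.get("simulate", {}))
    pop_kwargs.setdefault("seed", seed)
    pop = synthetic.PopulationConfig(**pop_kwargs)
    subjects = synthetic.generate_population(pop)
    return synthetic.generate_footprints(subjects, pop)


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the full analysis and write reports plus a manifest.

    Config keys: ``seed``; ``reference_table`` (path) or ``simulate``
    (:class:`~ichnostats.synthetic.PopulationConfig` keyword overrides);
    ``fossil_table`` (path) or ``fossil_frame`` (DataFrame, programmatic use);
    ``output_dir``; optional ``mass``, ``compare`` and ``sexing`` sections with
    the corresponding module options.

    Stages, in order: mass estimation (ensemble fit, baseline, evaluation,
    per-trackway predictions), gait classification, morphological comparison
    (skipped with a logged reason when the fossil table lacks depth profiles),
    and sex attribution.  Returns the report tables keyed by name.
    """
    out = Path(output_dir or config.get("output_dir", "ichnostats_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    digests = {}
    stages: list[str] = []

    # --- inputs ---------------------------------------------------------
    if "reference_table" in config:
        ref_path = Path(config["reference_table"])
        reference = io.read_footprint_table(ref_path)
        digests[str(ref_path)] = _sha256(ref_path)
    else:
        reference = _simulate_reference(config, seed)
        stages.append("simulate")
    if "fossil_table" in config:
        fossil_path = Path(config["fossil_table"])
        fossil = io.read_footprint_table(fossil_path)
        digests[str(fossil_path)] = _sha256(fossil_path)
    elif "fossil_frame" in config:
        fossil = config["fossil_frame"]
    else:
        scenario = synthetic.FossilScenarioConfig(
            seed=seed, **config.get("fossil_scenario", {})
        )
        fossil = synthetic.generate_fossil_scenario(scenario)["trackways"]
    reports: dict[str, pd.DataFrame] = {}

    # --- mass estimation ------------------------------------------------
    mass_opts = config.get("mass", {})
    try:
        split = mass.split_train_test(
            reference,
            fraction=mass_opts.get("split_fraction", 0.70),
            seed=seed,
            group_by_subject=mass_opts.get("group_by_subject", True),
        )
        model = mass.fit_mass_model(
            split["train"],
            n_trees=mass_opts.get("n_trees", 500),
            bootstrap_seed=seed,
            split_seed=seed,
        )
        baseline = mass.fit_length_regression(split["train"])
        evaluation = mass.evaluate(model, baseline, split["test"])
        rows = []
        for trackway_id, group in fossil.groupby("subject_or_trackway_id", sort=True):
            rows.append(
                {
                    "trackway_id": trackway_id,
                    "site_id": group["site_id"].iloc[0] if "site_id" in group else "",
                    "n_prints": len(group),
                    "predicted_mass_kg": mass.predict_trackway_mass(model, group),
                }
            )
        predictions = pd.DataFrame(rows)
        reports["mass_predictions"] = predictions
        reports["mass_evaluation"] = pd.DataFrame([vars(evaluation)])
        stages.append("mass_estimation")
    except Exception as exc:  # noqa: BLE001 - stage label added
        raise PipelineStageError("mass_estimation", exc) from exc

    # gait prediction and the comparison both need the fossil depth profiles
    has_depths = all(c in fossil.columns for c in DEPTH_COLUMNS) and bool(
        fossil[list(DEPTH_COLUMNS)].notna().all(axis=1).any()
    )

    # --- gait classification --------------------------------------------
    if has_depths:
        try:
            classifier = gait.fit_gait_classifier(
                reference, n_trees=mass_opts.get("n_trees", 500), seed=seed
            )
            gait_rows = []
            for trackway_id, group in fossil.groupby(
                "subject_or_trackway_id", sort=True
            ):
                label = gait.predict_gait(classifier, group)
                gait_rows.append(
                    {
                        "trackway_id": trackway_id,
                        "gait": label.value,
                        "probability": label.probability,
                    }
                )
            reports["gait_labels"] = pd.DataFrame(gait_rows)
            stages.append("gait")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("gait", exc) from exc

    # --- morphological comparison ---------------------------------------
    if has_depths:
        try:
            cmp_opts = dict(config.get("compare", {}))
            cmp_opts.setdefault("seed", seed)
            cmp_config = compare.ComparisonConfig(**cmp_opts)
            cmp_rows = []
            for trackway_id, group in fossil.groupby(
                "subject_or_trackway_id", sort=True
            ):
                result = compare.compare_trackway(
                    group, reference, classifier=classifier, config=cmp_config
                )
                cmp_rows.append(
                    {
                        "trackway_id": trackway_id,
                        "gait_used": result.gait_used.value,
                        "n_prints_fossil": result.n_prints_fossil,
                        "n_prints_matched": result.n_prints_matched,
                        "fossil_distance": result.fossil_distance,
                        "p_value": result.p_value,
                    }
                )
            reports["comparison_results"] = pd.DataFrame(cmp_rows)
            stages.append("morpho_compare")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("morpho_compare", exc) from exc
    else:
        logger.warning(
            "fossil table lacks complete depth profiles; skipping the gait "
            "and morphological comparison stages"
        )

    # --- sex attribution -------------------------------------------------
    try:
        sex_opts = config.get("sexing", {})
        attributions = sexing.attribute_sex(
            reports["mass_predictions"],
            manual_flags=sex_opts.get("manual_exclusions", ()),
            automatic_outliers=sex_opts.get("automatic_outliers", False),
        )
        reports["sex_attributions"] = pd.DataFrame(
            [
                {
                    "trackway_id": a.trackway_id,
                    "site_id": a.site_id,
                    "predicted_mass_kg": a.predicted_mass,
                    "predicted_sex": a.predicted_sex or "",
                    "threshold_mean_kg": a.threshold_mean,
                    "excluded": a.excluded,
                    "exclusion_reason": a.exclusion_reason,
                    "tie": a.tie,
                }
                for a in attributions
            ]
        )
        reports["site_composition"] = sexing.site_composition(attributions)
        stages.append("sex_attribution")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("sex_attribution", exc) from exc

    # --- reports + manifest ---------------------------------------------
    for name, frame in reports.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "package": "ichnostats",
        "version": __version__,
        "seed": seed,
        "config": {
            k: v for k, v in config.items() if k != "fossil_frame"
        },
        "input_digests": digests,
        "stages": stages,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str), encoding="utf-8"
    )
    return reports
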