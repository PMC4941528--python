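"""Sex attribution from trackway body-mass predictions: the mean method.

In a size-dimorphic species, individuals whose estimated mass exceeds the
assemblage mean are classified male and those below it female.  The method
tends to *under*-count males when true dimorphism exceeds that of the sample
used to frame the threshold, so male counts read as conservative lower
bounds.  Extreme small outliers (e.g. a probable child) can be excluded from
the threshold calculation, manually or by a modified z-score rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SexAttribution",
    "detect_outliers",
    "attribute_sex",
    "site_composition",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SexAttribution:
    """Predicted sex of one trackway under the mean method."""

    trackway_id: str
    predicted_mass: float
    predicted_sex: str | None  # None iff excluded
    threshold_mean: float | None
    excluded: bool
    exclusion_reason: str = ""
    site_id: str = ""
    tie: bool = False


def detect_outliers(
    masses,
    manual_flags=(),
    automatic: bool = False,
    z_threshold: float = 3.5,
    ids=None,
) -> list[tuple[bool, str]]:
    """Exclusion flags for the threshold-mean calculation.

    ``manual_flags`` names trackway ids (or indices when ``ids`` is omitted)
    to exclude outright.  With ``automatic=True`` a low-side modified z-score
    rule is added: masses with 0.6745 * (x - median) / MAD < -z_threshold are
    flagged (small outliers such as a probable child; large individuals are
    never auto-excluded).  Returns one ``(excluded, reason)`` pair per mass.
    """
    masses = np.asarray(masses, dtype=float)
    n = len(masses)
    if ids is None:
        ids = list(range(n))
    manual = set(manual_flags)
    flags: list[tuple[bool, str]] = []
    auto_flags = np.zeros(n, dtype=bool)
    if automatic:
        if n < 3:
            raise ValueError("automatic outlier detection needs at least 3 masses")
        med = np.median(masses)
        mad = np.median(np.abs(masses - med))
        if mad > 0:
            mz = 0.6745 * (masses - med) / mad
            auto_flags = mz < -z_threshold
    for i, (mass, label) in enumerate(zip(masses, ids)):
        if label in manual:
            flags.append((True, "manually flagged"))
        elif auto_flags[i]:
            flags.append((True, f"low-side modified z-score outlier ({mass:.1f} kg)"))
        else:
            flags.append((False, ""))
    if all(f for f, _ in flags):
        raise ValueError("every mass was excluded; no threshold can be formed")
    for (excluded, reason), label in zip(flags, ids):
        if excluded:
            logger.warning("excluding trackway %s from mean: %s", label, reason)
    return flags


def attribute_sex(
    predictions: pd.DataFrame,
    manual_flags=(),
    automatic_outliers: bool = False,
    threshold_scope: str = "assemblage",  # "assemblage" | "per_site"
) -> list[SexAttribution]:
    """Mean-method sex attribution for a table of trackway mass predictions.

    ``predictions`` needs columns ``trackway_id`` and ``predicted_mass_kg``
    (``site_id`` optional).  The threshold is the mean of the non-excluded
    masses — assemblage-wide by default, or per site.  Masses strictly above
    the threshold are male, strictly below female; a mass exactly at the
    threshold is classified female with a logged tie note (conservative toward
    fewer males).  Excluded trackways carry no sex.
    """
    df = predictions.reset_index(drop=True)
    ids = df["trackway_id"].tolist()
    masses = df["predicted_mass_kg"].to_numpy(dtype=float)
    sites = df["site_id"].tolist() if "site_id" in df.columns else [""] * len(df)
    flags = detect_outliers(
        masses, manual_flags=manual_flags, automatic=automatic_outliers, ids=ids
    )
    excluded = np.array([f for f, _ in flags])
    usable = ~excluded
    if usable.sum() < 2:
        raise ValueError("need at least 2 non-excluded masses for the mean method")

    def threshold_for(site: str) -> float:
        if threshold_scope == "per_site":
            in_scope = usable & (np.asarray(sites) == site)
            if in_scope.sum() < 2:
                raise ValueError(f"site {site!r} has fewer than 2 usable masses")
            return float(masses[in_scope].mean())
        return float(masses[usable].mean())

    if len(set(masses[usable])) == 1:
        logger.warning(
            "all usable masses identical (%.2f kg): every trackway ties at the mean",
            masses[usable][0],
        )

    out: list[SexAttribution] = []
    for i, (label, mass, site) in enumerate(zip(ids, masses, sites)):
        if excluded[i]:
            out.append(
                SexAttribution(
                    trackway_id=label,
                    predicted_mass=float(mass),
                    predicted_sex=None,
                    threshold_mean=None,
                    excluded=True,
                    exclusion_reason=flags[i][1],
                    site_id=site,
                )
            )
            continue
        thr = threshold_for(site)
        tie = mass == thr
        if tie:
            logger.warning(
                "trackway %s mass equals the threshold mean (%.3f kg); "
                "classifying female (tie rule)", label, thr,
            )
        sex = "male" if mass > thr else "female"
        out.append(
            SexAttribution(
                trackway_id=label,
                predicted_mass=float(mass),
                predicted_sex=sex,
                threshold_mean=thr,
                excluded=False,
                site_id=site,
                tie=bool(tie),
            )
        )
    return out


def site_composition(attributions: list[SexAttribution]) -> pd.DataFrame:
    """Per-site counts of predicted males, females and exclusions.

    Counts conserve totals: males + females + excluded equals the number of
    trackways, per site.  Individual-identity linking across trackways is not
    attempted — counts are of trackways, an upper bound on individuals.
    """
    rows = {}
    for a in attributions:
        row = rows.setdefault(
            a.site_id, {"site_id": a.site_id, "males": 0, "females": 0,
                        "excluded": 0, "trackways": 0}
        )
        row["trackways"] += 1
        if a.excluded:
            row["excluded"] += 1
        elif a.predicted_sex == "male":
            row["males"] += 1
        else:
            row["females"] += 1
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["site_id"]))
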