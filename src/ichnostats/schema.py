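"""Canonical footprint-table schema and depth-profile container.

One delimited-text schema is shared by every stage of the pipeline.  Units are
embedded in the column names (all linear measurements in cm, mass in kg) so
that tables cannot silently drift between unit conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: The 14 functionally relevant footprint regions, in canonical order:
#: medial/lateral heel, medial/lateral midfoot, the five metatarsal heads
#: (medial mt1 to lateral mt5) and the five toes (hallux toe1 to toe5).
DEPTH_LANDMARKS: tuple[str, ...] = (
    "heel_medial",
    "heel_lateral",
    "midfoot_medial",
    "midfoot_lateral",
    "mt1",
    "mt2",
    "mt3",
    "mt4",
    "mt5",
    "toe1",
    "toe2",
    "toe3",
    "toe4",
    "toe5",
)

N_REGIONS = len(DEPTH_LANDMARKS)

#: Column names of the 14 regional depths in the footprint table.
DEPTH_COLUMNS: tuple[str, ...] = tuple(f"depth_{name}_cm" for name in DEPTH_LANDMARKS)

#: The five external-dimension predictors used by the mass model.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "heel_to_hallux_length_cm",
    "heel_to_t2_length_cm",
    "forefoot_breadth_cm",
    "heel_breadth_cm",
    "mean_depth_cm",
)

#: Label / bookkeeping columns.
ID_COLUMNS: tuple[str, ...] = (
    "footprint_id",
    "subject_or_trackway_id",
    "site_id",
    "role",
    "gait",
    "sex",
    "substrate",
)

#: Columns a footprint table must always carry.  ``body_mass_kg`` and the 14
#: depth columns are optional (fossil tables may lack either).
REQUIRED_COLUMNS: tuple[str, ...] = ID_COLUMNS + MEASUREMENT_COLUMNS

OPTIONAL_COLUMNS: tuple[str, ...] = ("body_mass_kg",) + DEPTH_COLUMNS

ROLES = ("reference", "fossil")
GAITS = ("walking", "running", "unknown")
SEXES = ("male", "female", "unknown")

# index weights of a least-squares slope over positions 1..5 (centered)
_SLOPE_WEIGHTS = (np.arange(1, 6) - 3.0) / 10.0

MT_REGIONS = DEPTH_LANDMARKS[4:9]
TOE_REGIONS = DEPTH_LANDMARKS[9:14]


@dataclass(frozen=True)
class DepthProfile:
    """Depths (cm, positive downward from the reference plane) at the 14 regions.

    Values follow the canonical :data:`DEPTH_LANDMARKS` order.  Negative values
    are permitted (a displacement rim at a nominal landmark) but are unusual.
    """

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_REGIONS,):
            raise ValueError(
                f"a depth profile has exactly {N_REGIONS} values, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("depth profile values must be finite")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "DepthProfile":
        """Build from a ``{landmark: depth}`` mapping (all 14 keys required)."""
        missing = [name for name in DEPTH_LANDMARKS if name not in mapping]
        if missing:
            raise KeyError(f"depth profile mapping missing regions: {missing}")
        return cls(np.array([mapping[name] for name in DEPTH_LANDMARKS], dtype=float))

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(DEPTH_LANDMARKS, self.values)}

    def __getitem__(self, landmark: str) -> float:
        return float(self.values[DEPTH_LANDMARKS.index(landmark)])

    @property
    def mt(self) -> np.ndarray:
        """Depths at the five metatarsal heads, medial to lateral."""
        return self.values[4:9]

    @property
    def toes(self) -> np.ndarray:
        """Depths at the five toes, hallux to fifth."""
        return self.values[9:14]


def profiles_to_array(profiles: Iterable[DepthProfile]) -> np.ndarray:
    """Stack profiles into an (n, 14) array in canonical region order."""
    arr = np.array([p.values for p in profiles], dtype=float)
    if arr.size == 0:
        raise ValueError("empty list of depth profiles")
    return arr
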