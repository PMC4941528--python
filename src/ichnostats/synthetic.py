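"""Synthetic footprint populations, surfaces and fossil-site scenarios.

The generator emulates the structure of a habitually-barefoot experimental
footprint dataset: ~41 subjects of known sex, age class and body mass, each
leaving repeated prints under varied substrate hydration/compaction, with
external print dimensions scaling allometrically with body mass and a
14-region depth topography drawn from gait-specific multivariate-normal
templates.  Every emitted record carries the parameters that generated it, so
parameter-recovery tests can score the downstream estimators against truth.

Depth templates are expressed in *relative* units (the template mean is
normalised to 1) and scaled per print by a substrate- and mass-dependent mean
depth.  The walking template encodes the human medial-to-lateral gradient of
decreasing forefoot depth; the running template deepens the forefoot and
lightens the heel.  A "Laetoli-like" divergent template is obtained by adding
a medial-to-lateral ramp to the forefoot regions, parameterised in pooled
standard deviations of the per-print forefoot depth slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .schema import DEPTH_COLUMNS, DEPTH_LANDMARKS, N_REGIONS

__all__ = [
    "SubjectSpec",
    "DepthTemplate",
    "PopulationConfig",
    "SurfaceConfig",
    "default_template_library",
    "shift_forefoot_template",
    "generate_population",
    "generate_footprints",
    "generate_surface",
    "generate_profile_pool",
    "generate_fossil_scenario",
]


class EmptyPopulationError(ValueError):
    """All subject counts are zero."""


@dataclass(frozen=True)
class SubjectSpec:
    """One simulated print-maker."""

    subject_id: str
    sex: str  # "male" | "female"
    age_class: str  # "adult" | "juvenile"
    body_mass: float  # kg
    n_prints: int

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")
        if self.n_prints < 1:
            raise ValueError("a subject produces at least one print")


@dataclass(frozen=True)
class DepthTemplate:
    """Mean 14-region depth shape (relative units) and its covariance."""

    mean: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mu.shape != (N_REGIONS,) or cov.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("template must be a 14-vector mean and 14x14 covariance")
        if not np.allclose(cov, cov.T):
            raise ValueError("template covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("template covariance must be positive semi-definite")
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "cov", cov)

    def normalised(self) -> "DepthTemplate":
        """Rescale so that the mean of the template mean vector is 1."""
        scale = float(np.mean(self.mean))
        if scale <= 0:
            raise ValueError("template mean must have positive average depth")
        return DepthTemplate(self.mean / scale, self.cov / scale**2)


# Relative region depths.  Walking: deep medial forefoot with a strictly
# decreasing medial-to-lateral gradient over mt1..mt5 and toe1..toe5, deep
# heel, shallow medial midfoot (longitudinal arch).  Running: forefoot
# uniformly deepened, heel relatively lightened, arch slightly filled.
_WALK_MEAN = np.array(
    [1.00, 0.92,  # heel medial / lateral
     0.25, 0.55,  # midfoot medial / lateral (arch)
     1.10, 1.00, 0.85, 0.70, 0.55,  # mt1..mt5
     0.95, 0.85, 0.60, 0.48, 0.38]  # toe1..toe5
)
_RUN_MEAN = np.array(
    [0.72, 0.68,
     0.38, 0.55,
     1.28, 1.24, 1.18, 1.12, 1.06,
     1.10, 1.05, 0.97, 0.90, 0.84]
)


def _compound_symmetry_cov(sd: float, rho: float) -> np.ndarray:
    corr = np.full((N_REGIONS, N_REGIONS), rho)
    np.fill_diagonal(corr, 1.0)
    return sd**2 * corr


def default_template_library(
    sd: float = 0.12, rho: float = 0.3
) -> dict[str, DepthTemplate]:
    """Walking and running templates with compound-symmetric covariance.

    ``sd`` is the per-region standard deviation in relative depth units and
    ``rho`` the common inter-region correlation (prints that sink deeper
    overall do so at every region).
    """
    cov = _compound_symmetry_cov(sd, rho)
    return {
        "walking": DepthTemplate(_WALK_MEAN, cov).normalised(),
        "running": DepthTemplate(_RUN_MEAN, cov).normalised(),
    }


_SLOPE_W = (np.arange(1, 6) - 3.0) / 10.0  # least-squares slope weights, idx 1..5


def forefoot_slope_sd(template: DepthTemplate) -> float:
    """SD of the per-print metatarsal depth slope implied by the template."""
    block = template.cov[4:9, 4:9]
    return float(np.sqrt(_SLOPE_W @ block @ _SLOPE_W))


def shift_forefoot_template(template: DepthTemplate, shift_sd: float) -> DepthTemplate:
    """Add a lateral-deepening ramp across the forefoot regions.

    The ramp is scaled so the template's mean forefoot depth slope moves by
    ``shift_sd`` pooled per-print standard deviations of that slope (computed
    from the template covariance).  ``shift_sd = 0`` returns the template
    unchanged; large positive shifts flip the human medial-deeper gradient
    into the lateral-deeper / flat pattern seen in non-human trackmakers.
    """
    if shift_sd == 0:
        return template
    a = shift_sd * forefoot_slope_sd(template)
    ramp = a * (np.arange(1, 6) - 3.0)
    mean = template.mean.copy()
    mean[4:9] = mean[4:9] + ramp
    mean[9:14] = mean[9:14] + ramp
    return DepthTemplate(mean, template.cov)


@dataclass(frozen=True)
class PopulationConfig:
    """Study-design knobs for the synthetic experimental population.

    Defaults emulate an experimental sample of 41 habitually-barefoot subjects
    (15 adult males, 14 adult females, 12 juveniles) producing ~490 prints
    overall, with adult sex-specific mass means straddling ~52.6 kg and a
    whole-sample spread reaching down toward ~18 kg via the juveniles.
    """

    n_male: int = 15
    n_female: int = 14
    n_juvenile: int = 12
    mass_mean_male: float = 57.0  # kg
    mass_mean_female: float = 48.0  # kg
    mass_sd: float = 5.0  # kg, adults
    mass_mean_juvenile: float = 35.0  # kg
    mass_sd_juvenile: float = 8.0  # kg
    juvenile_male_fraction: float = 10.0 / 12.0
    mass_truncation: float = 15.0  # kg, lower bound of the truncated normals
    prints_per_subject: tuple[int, int] = (10, 14)
    allometry_exponent: float = 1.0 / 3.0  # isometric length-mass scaling
    length_coefficient: float = 6.8  # cm * kg^-exponent: ~26 cm print at 56 kg
    t2_ratio: float = 0.98
    forefoot_breadth_ratio: float = 0.38
    heel_breadth_ratio: float = 0.25
    dimension_noise_cv: float = 0.04
    depth_scale_cm: float = 2.0  # mean print depth at the reference mass, neutral substrate
    depth_reference_mass: float = 50.0  # kg
    depth_noise_sd: float = 0.15  # cm
    substrate_levels: tuple[tuple[str, float], ...] = (
        ("dry_compact", 0.5),
        ("moist", 1.0),
        ("wet_soft", 1.5),
    )
    gait_mix: float = 0.8  # fraction of walking prints
    template_library: dict[str, DepthTemplate] = field(
        default_factory=default_template_library
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_male, self.n_female, self.n_juvenile) < 0:
            raise ValueError("subject counts must be non-negative")
        if min(self.mass_mean_male, self.mass_mean_female, self.mass_sd) <= 0:
            raise ValueError("mass means and SDs must be positive")
        if not 0.0 <= self.gait_mix <= 1.0:
            raise ValueError("gait_mix must lie in [0, 1]")
        lo, hi = self.prints_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("prints_per_subject must be a valid range with lo >= 1")
        if not self.substrate_levels:
            raise ValueError("at least one substrate level is required")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    a = (lower - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.ppf(rng.random(size))


def generate_population(config: PopulationConfig) -> list[SubjectSpec]:
    """Draw the subject roster: ids, sexes, age classes, masses, print counts.

    Masses come from sex-/age-specific normals truncated below at
    ``config.mass_truncation`` kg.  Deterministic given ``config.seed``.
    """
    total = config.n_male + config.n_female + config.n_juvenile
    if total == 0:
        raise EmptyPopulationError("population config has zero subjects in every class")
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.prints_per_subject
    subjects: list[SubjectSpec] = []

    def add(prefix: str, n: int, sex_of, age_class: str, mean: float, sd: float) -> None:
        masses = _truncated_normal(rng, mean, sd, config.mass_truncation, n)
        counts = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            subjects.append(
                SubjectSpec(
                    subject_id=f"{prefix}{i + 1:02d}",
                    sex=sex_of(i),
                    age_class=age_class,
                    body_mass=float(masses[i]),
                    n_prints=int(counts[i]),
                )
            )

    add("M", config.n_male, lambda i: "male", "adult",
        config.mass_mean_male, config.mass_sd)
    add("F", config.n_female, lambda i: "female", "adult",
        config.mass_mean_female, config.mass_sd)
    if config.n_juvenile:
        juv_sex = np.where(
            rng.random(config.n_juvenile) < config.juvenile_male_fraction,
            "male", "female",
        )
        add("J", config.n_juvenile, lambda i: str(juv_sex[i]), "juvenile",
            config.mass_mean_juvenile, config.mass_sd_juvenile)
    return subjects


def _draw_print(
    rng: np.random.Generator,
    subject: SubjectSpec,
    config: PopulationConfig,
    gait: str,
    substrate: tuple[str, float],
    template: DepthTemplate,
) -> dict:
    m = subject.body_mass
    cv = config.dimension_noise_cv
    eps = rng.normal(0.0, cv, size=4) if cv > 0 else np.zeros(4)
    # each dimension scales the underlying allometric length with its own
    # independent noise: four noisy views of the same size signal
    base = config.length_coefficient * m**config.allometry_exponent
    length = base * (1 + eps[0])
    t2 = config.t2_ratio * base * (1 + eps[1])
    fb = config.forefoot_breadth_ratio * base * (1 + eps[2])
    hb = config.heel_breadth_ratio * base * (1 + eps[3])
    tag, mult = substrate
    base = config.depth_scale_cm * m / config.depth_reference_mass
    depth_scale = mult * base + rng.normal(0.0, config.depth_noise_sd)
    depth_scale = max(depth_scale, 0.05)
    t = template.normalised()
    profile = depth_scale * rng.multivariate_normal(t.mean, t.cov, method="cholesky")
    row = {
        "subject_or_trackway_id": subject.subject_id,
        "site_id": "experimental",
        "role": "reference",
        "gait": gait,
        "sex": subject.sex,
        "substrate": tag,
        "body_mass_kg": m,
        "heel_to_hallux_length_cm": length,
        "heel_to_t2_length_cm": t2,
        "forefoot_breadth_cm": fb,
        "heel_breadth_cm": hb,
        "mean_depth_cm": max(float(profile.mean()), 0.0),
        # ground truth of the generating process
        "true_substrate_multiplier": mult,
        "true_depth_scale_cm": depth_scale,
        "age_class": subject.age_class,
    }
    row.update(dict(zip(DEPTH_COLUMNS, profile)))
    return row


def generate_footprints(
    subjects: list[SubjectSpec], config: PopulationConfig
) -> pd.DataFrame:
    """Emit the footprint table for a subject roster.

    Per print: heel-to-hallux length L = c * mass^exponent * (1 + eps) with
    eps ~ N(0, cv); the other three dimensions are fixed ratios of L with
    independent multiplicative noise; mean depth is a substrate multiplier
    times a mass-proportional base plus noise; the 14-region profile is the
    gait template's multivariate normal scaled by the print's mean depth.
    Substrate and gait vary print-to-print within each subject.  Ground-truth
    columns (mass, sex, substrate multiplier, depth scale) ride along.
    """
    if not subjects:
        raise ValueError("subject list is empty")
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    counter = 0
    for subject in subjects:
        for _ in range(subject.n_prints):
            gait = "walking" if rng.random() < config.gait_mix else "running"
            if gait not in config.template_library:
                raise KeyError(f"gait {gait!r} missing from template library")
            substrate = config.substrate_levels[
                rng.integers(len(config.substrate_levels))
            ]
            row = _draw_print(rng, subject, config, gait,
                              substrate, config.template_library[gait])
            counter += 1
            row["footprint_id"] = f"fp{counter:04d}"
            rows.append(row)
    df = pd.DataFrame(rows)
    front = ["footprint_id"] + [c for c in df.columns if c != "footprint_id"]
    return df[front]


@dataclass(frozen=True)
class SurfaceConfig:
    """Geometry of synthetic 3-D print surfaces."""

    spacing: float = 0.25  # cm between grid nodes
    pit_sigma: float = 0.8  # cm, width of each landmark depression
    tilt: tuple[float, float, float] = (0.0, 0.0, 0.0)  # plane z = a*x + b*y + c
    noise_sd: float = 0.0  # cm of white measurement noise
    margin_band: float = 1.0  # cm-wide undisturbed annulus at the grid edge

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.pit_sigma <= 0:
            raise ValueError("pit sigma must be > 0")


def landmark_layout(
    length: float, forefoot_breadth: float, heel_breadth: float
) -> dict[str, tuple[float, float]]:
    """Anatomically arranged landmark coordinates for a print of given size.

    Foot axis along +y from the heel (y=0) toward the toes; medial side at
    negative x (a right foot seen from above).
    """
    L, Bf, Bh = length, forefoot_breadth, heel_breadth
    return {
        "heel_medial": (-0.25 * Bh, 0.10 * L),
        "heel_lateral": (0.25 * Bh, 0.10 * L),
        "midfoot_medial": (-0.30 * Bf, 0.40 * L),
        "midfoot_lateral": (0.30 * Bf, 0.42 * L),
        "mt1": (-0.45 * Bf, 0.72 * L),
        "mt2": (-0.22 * Bf, 0.73 * L),
        "mt3": (0.00 * Bf, 0.72 * L),
        "mt4": (0.22 * Bf, 0.70 * L),
        "mt5": (0.45 * Bf, 0.68 * L),
        "toe1": (-0.38 * Bf, 0.93 * L),
        "toe2": (-0.15 * Bf, 0.92 * L),
        "toe3": (0.05 * Bf, 0.90 * L),
        "toe4": (0.25 * Bf, 0.88 * L),
        "toe5": (0.42 * Bf, 0.86 * L),
    }


_CUTOFF_SIGMAS = 7.0  # truncate pits here; the shifted kernel is exactly 0 beyond


def _pit_kernel(r2: np.ndarray, sigma: float) -> np.ndarray:
    """Truncated, level-shifted Gaussian: exactly zero at and beyond 7 sigma."""
    cut = _CUTOFF_SIGMAS**2 * sigma**2
    level = np.exp(-0.5 * _CUTOFF_SIGMAS**2)
    val = np.exp(-0.5 * r2 / sigma**2) - level
    return np.where(r2 < cut, np.maximum(val, 0.0), 0.0)


def generate_surface(
    record: pd.Series | dict,
    surface_config: SurfaceConfig = SurfaceConfig(),
    rng: np.random.Generator | None = None,
) -> geometry.FootprintSurface:
    """Render one footprint record as a gridded surface.

    The surface is a tilted plane minus 14 truncated-Gaussian pits whose
    amplitudes are solved (small kernel system) so the summed field equals the
    record's depth profile *exactly* at the landmark nodes; landmark
    coordinates are snapped to grid nodes so bilinear sampling is exact there.
    The margin annulus lies beyond the pits' truncation radius and is exactly
    planar (before optional white noise).
    """
    rec = dict(record)
    profile = np.array([rec[c] for c in DEPTH_COLUMNS], dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("record lacks a finite 14-region depth profile")
    cfg = surface_config
    marks = landmark_layout(
        rec["heel_to_hallux_length_cm"],
        rec["forefoot_breadth_cm"],
        rec["heel_breadth_cm"],
    )
    pad = _CUTOFF_SIGMAS * cfg.pit_sigma + cfg.margin_band + 2 * cfg.spacing
    xs = np.array([p[0] for p in marks.values()])
    ys = np.array([p[1] for p in marks.values()])
    x0, x1 = xs.min() - pad, xs.max() + pad
    y0, y1 = ys.min() - pad, ys.max() + pad
    nx = int(np.ceil((x1 - x0) / cfg.spacing)) + 1
    ny = int(np.ceil((y1 - y0) / cfg.spacing)) + 1
    gx = x0 + cfg.spacing * np.arange(nx)
    gy = y0 + cfg.spacing * np.arange(ny)

    # snap landmarks to grid nodes: bilinear interpolation is exact at nodes
    snapped: dict[str, tuple[float, float]] = {}
    for name, (px, py) in marks.items():
        j = int(np.clip(np.rint((px - x0) / cfg.spacing), 0, nx - 1))
        i = int(np.clip(np.rint((py - y0) / cfg.spacing), 0, ny - 1))
        snapped[name] = (float(gx[j]), float(gy[i]))

    centers = np.array([snapped[name] for name in DEPTH_LANDMARKS])
    d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    G = _pit_kernel(d2, cfg.pit_sigma)
    amplitudes = np.linalg.solve(G, profile)

    xx, yy = np.meshgrid(gx, gy)
    a, b, c = cfg.tilt
    z = a * xx + b * yy + c
    for amp, (cx, cy) in zip(amplitudes, centers):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        z = z - amp * _pit_kernel(r2, cfg.pit_sigma)
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        z = z + rng.normal(0.0, cfg.noise_sd, size=z.shape)

    w = max(int(np.floor(cfg.margin_band / cfg.spacing)), 1)
    mask = np.zeros_like(z, dtype=bool)
    mask[:w, :] = mask[-w:, :] = True
    mask[:, :w] = mask[:, -w:] = True

    return geometry.FootprintSurface(
        origin=(float(x0), float(y0)),
        spacing=cfg.spacing,
        elevations=z,
        margin_mask=mask,
        landmarks=snapped,
    )


def generate_profile_pool(
    n_subjects: int = 41,
    prints_per_subject: int = 12,
    template: DepthTemplate | None = None,
    depth_scale: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pure multivariate-normal 14-region profile pool, grouped by subject.

    Prints are i.i.d. draws from the (normalised) template scaled to
    ``depth_scale`` cm mean depth — no mass or substrate structure — so
    subjects are exchangeable.  This is the null world for calibration
    experiments on the resampling comparison test.
    """
    if template is None:
        template = default_template_library()["walking"]
    t = template.normalised()
    rng = np.random.default_rng([seed, 2])
    n = n_subjects * prints_per_subject
    profiles = depth_scale * rng.multivariate_normal(
        t.mean, t.cov, size=n, method="cholesky"
    )
    subjects = np.repeat([f"S{i + 1:02d}" for i in range(n_subjects)], prints_per_subject)
    df = pd.DataFrame(profiles, columns=list(DEPTH_COLUMNS))
    df.insert(0, "subject_or_trackway_id", subjects)
    df.insert(1, "footprint_id", [f"fp{i + 1:04d}" for i in range(n)])
    df["gait"] = "walking"
    return df


def generate_divergent_trackway_profiles(
    n_prints: int = 5,
    shift_sd: float = 3.0,
    template: DepthTemplate | None = None,
    depth_scale: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pure-MVN pseudo-fossil trackway with a shifted forefoot gradient.

    Draws ``n_prints`` profiles from the (normalised) template after shifting
    its forefoot regions by ``shift_sd`` pooled SDs of depth slope — the
    divergent counterpart to :func:`generate_profile_pool`, on the same
    relative scale.
    """
    if template is None:
        template = default_template_library()["walking"]
    shifted = shift_forefoot_template(template.normalised(), shift_sd)
    rng = np.random.default_rng([seed, 4])
    profiles = depth_scale * rng.multivariate_normal(
        shifted.mean, shifted.cov, size=n_prints, method="cholesky"
    )
    df = pd.DataFrame(profiles, columns=list(DEPTH_COLUMNS))
    df.insert(0, "subject_or_trackway_id", "DIVERGENT")
    df["gait"] = "walking"
    return df


@dataclass(frozen=True)
class FossilScenarioConfig:
    """Layout of a synthetic multi-trackway fossil site."""

    n_trackways: int = 16
    prints_per_trackway: int = 5
    male_fraction: float = 0.5
    gait: str = "walking"
    site_id: str = "synthetic_site"
    divergent_trackways: tuple[int, ...] = ()  # indices with the shifted template
    divergent_shift: float = 0.0  # pooled SDs of forefoot-slope shift
    population: PopulationConfig = field(default_factory=PopulationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trackways < 1:
            raise ValueError("a fossil scenario needs at least one trackway")
        if self.prints_per_trackway < 1:
            raise ValueError("each trackway needs at least one print")
        if any(i < 0 or i >= self.n_trackways for i in self.divergent_trackways):
            raise ValueError("divergent trackway index out of range")


def generate_fossil_scenario(config: FossilScenarioConfig) -> dict:
    """Emit a fossil-site footprint table plus its ground-truth composition.

    Trackways are adults with sex counts fixed at ``round(male_fraction *
    n_trackways)`` males; masses and dimensions follow the population config's
    allometric model.  Trackways listed in ``divergent_trackways`` use the
    human template shifted laterally by ``divergent_shift`` pooled SDs of
    forefoot depth slope ("Laetoli-like"); a shift of 0 leaves the template
    equal to the human one.

    Returns ``{"trackways": DataFrame, "truth": DataFrame}``; the trackway
    table uses the canonical schema with role="fossil" and masses omitted.
    """
    pop = config.population
    rng = np.random.default_rng([config.seed, 3])
    n_male = int(round(config.male_fraction * config.n_trackways))
    sexes = ["male"] * n_male + ["female"] * (config.n_trackways - n_male)
    base_template = pop.template_library[config.gait]
    divergent_template = shift_forefoot_template(base_template, config.divergent_shift)

    rows, truth_rows = [], []
    counter = 0
    for t_idx, sex in enumerate(sexes):
        mean = pop.mass_mean_male if sex == "male" else pop.mass_mean_female
        mass = float(_truncated_normal(rng, mean, pop.mass_sd, pop.mass_truncation, 1)[0])
        divergent = t_idx in config.divergent_trackways
        template = divergent_template if divergent else base_template
        trackway_id = f"T{t_idx + 1:02d}"
        subject = SubjectSpec(trackway_id, sex, "adult", mass,
                              config.prints_per_trackway)
        substrate = pop.substrate_levels[rng.integers(len(pop.substrate_levels))]
        for _ in range(config.prints_per_trackway):
            row = _draw_print(rng, subject, pop, config.gait, substrate, template)
            counter += 1
            row["footprint_id"] = f"ft{counter:04d}"
            row["site_id"] = config.site_id
            row["role"] = "fossil"
            del row["body_mass_kg"]  # unknown for fossils; truth table keeps it
            rows.append(row)
        truth_rows.append(
            {
                "trackway_id": trackway_id,
                "site_id": config.site_id,
                "sex": sex,
                "body_mass_kg": mass,
                "gait": config.gait,
                "template": "divergent" if divergent else config.gait,
                "divergent_shift": config.divergent_shift if divergent else 0.0,
                "n_prints": config.prints_per_trackway,
            }
        )
    trackways = pd.DataFrame(rows)
    front = ["footprint_id"] + [c for c in trackways.columns if c != "footprint_id"]
    return {"trackways": trackways[front], "truth": pd.DataFrame(truth_rows)}
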