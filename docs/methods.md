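# Methods

`ichnostats` implements a statistical pipeline for analysing assemblages of
footprints — typically fossil hominin trackways measured against a reference
sample of prints made by living, habitually barefoot people in comparable
substrate. This note records the models, their assumptions, the defaults, and
the choices made where the design was genuinely open.

## The measurement model

A footprint is summarised two ways:

* **External dimensions** (cm): heel-to-hallux length, heel-to-second-toe
  length, forefoot breadth, heel breadth, and average depth.
* **Depth topography**: impression depths at 14 functionally relevant
  regions — medial/lateral heel, medial/lateral midfoot, the five metatarsal
  heads, and the five toes — measured perpendicular to a reference plane.

The reference plane is the least-squares plane through the *undisturbed
margin* of the print (sediment the foot did not deform). `fit_reference_plane`
solves the ordinary least-squares problem over the margin cells and reports
the residual RMS; `orient_surface` replaces elevations by residuals so the
margin plane becomes z = 0; `measure_depths` then reads depths (positive
downward) at annotated landmark coordinates by bilinear interpolation, or
optionally as the local maximum depth within a radius r of the landmark.
Landmark identification is treated as input: the landmarks of real prints are
annotated by a human analyst, and automating that judgement is out of scope.

"Average depth" is ambiguous for a surface, so two estimators are exposed and
the one used is recorded: the mean of (−elevation) over an outline mask
(default for surfaces) or the mean of the 14 regional depths (used for
tabular data). On synthetic prints the two differ by a template-consistent
proportional offset because the outline mean includes undeformed floor.

The **forefoot depth gradient** summarises the medial-to-lateral pattern: the
least-squares slope of depth against position 1..5 across the metatarsal
heads and, separately, across the toes (cm per position). Human walking —
medial pressure transfer and toe-off through the first two digits — produces
negative slopes (deeper medially).

## Body-mass estimation

Mass (kg) is predicted from the five external dimensions by a bagged
ensemble of regression trees. Each of the 500 trees (default) is grown on a
full-size bootstrap of the training rows; the rows a tree never sampled form
its out-of-bag (OOB) set, and pooled OOB predictions give an internal RMSE.
With full n-with-replacement bootstraps the expected unique in-bag count is
n·(1 − (1 − 1/n)ⁿ) ≈ 0.632·n: for 343 training rows, ≈ 217 in-bag and 126
out-of-bag per tree. Tree settings follow regression-forest convention:
⌈p/3⌉ = 2 of the 5 features tried per split, terminal nodes of ≥ 5 rows, no
depth limit. Predictions are means over trees and therefore always lie within
the training response range — the estimator cannot extrapolate beyond the
masses it has seen, which matters when a fossil print is larger than every
reference print.

The benchmark is an OLS regression of mass on heel-to-hallux length alone,
evaluated on the identical held-out rows. Train/test splitting is 70/30,
seeded; by default all prints of one subject stay on the same side of the
split (repeated prints of one person are not independent, and row-wise
splitting leaks subject identity into the test set). Row-wise splitting is
available for protocols defined in terms of print counts (490 prints split
343/147). Fossil trackways are predicted from their average print
dimensions, one prediction per trackway.

## Gait classification

Trackway comparisons are gait-matched, so fossil trackways need a
walking/running label. A bagged classification-tree ensemble (same bagging
machinery; ⌈√p⌉ features per split) is trained on the reference prints'
5 dimensions + 14 depths. Trackway labels are majority votes over per-print
predictions; exact ties resolve toward walking — the dominant activity in
reference datasets and the gait of interest in fossil interpretation — and
are logged. The classifier family and feature set are a design choice, made
for coherence with the mass model rather than fidelity to any particular
prior implementation.

## The resampling comparison test

The core question: is a fossil trackway's mean 14-region topography within
the range of modern human variation? The test statistic is the Mahalanobis
distance D = √((x−μ)ᵀ Σ⁻¹ (x−μ)) between the fossil trackway's mean profile
x and the reference mean μ under the reference print covariance Σ. Σ is the
sample covariance by default, with optional Ledoit–Wolf shrinkage for small
gait-matched pools (14 dimensions can approach the usable sample size).

The null distribution respects the repeated-measures structure of the
reference data. Per iteration (default 10,000):

1. draw one reference subject uniformly among subjects with at least as many
   prints as the fossil trackway;
2. sample that many of the subject's prints without replacement (with-
   replacement sampling is available, and admits smaller subjects);
3. average them into a trackway-sized mean profile;
4. measure its Mahalanobis distance from the mean and covariance of the
   *remaining* subjects' prints.

The p-value is the probability of a resampled distance at least as large as
the fossil one, estimated with the +1 correction
p = (1 + #{null ≥ D}) / (1 + N) so a finite null never reports exactly zero.
Subject selection is uniform over subjects, not prints, so prolific subjects
are not over-weighted. The out-of-sample mean/covariance depends only on
which subject was held out, so it is computed once per subject and shared by
that subject's iterations (an exact cache, not an approximation); iterations
are vectorised per held-out subject. A fast mode reuses the full-pool
covariance, which is slightly anti-conservative because the held-out
subject's own spread then inflates Σ.

Degenerate cases: a zero difference vector returns distance 0 under any
covariance (a zero vector has zero norm in every metric — this also covers a
pool of identical prints, whose covariance is singular); a singular
covariance with a nonzero difference raises an error naming the landmark
directions with no variance. The reference mean can be taken per-print
(default) or per-subject-then-averaged; both are exposed because either
reading is defensible.

Calibration and power are established by simulation (`validation` module):
held-out reference subjects treated as pseudo-fossils yield approximately
uniform p-values and a type-I error near the nominal 5%; a "Laetoli-like"
template whose forefoot gradient is shifted 3 pooled SDs laterally is
rejected at p < 0.05 in essentially every run.

## Sex attribution (mean method)

Trackways with predicted mass strictly above the mean of all (non-excluded)
predictions are classified male, below female. A mass exactly at the mean is
classified female with a logged tie note — the conservative direction,
consistent with the method's framing as a lower bound on male counts.
Exclusions (e.g. a probable child) are manual flags or an optional low-side
modified z-score rule (0.6745·(x−median)/MAD < −3.5; large individuals are
never auto-excluded). The threshold is assemblage-wide by default, per-site
optionally. When true dimorphism exceeds that of the calibrating population
and the assemblage is male-biased, smaller males fall below the threshold, so
the male count is a conservative underestimate; the simulation in
`mean_method_recovery` reproduces this behaviour. Counts are of trackways:
linking trackways to unique individuals is out of scope, so male counts per
site are upper bounds on distinct trackmakers and lower bounds per the
dimorphism argument.

## The synthetic-data generator

The generator produces populations with the structure the analysis assumes,
with every record joinable to its generating parameters:

* **Population** (defaults): 15 adult males, 14 adult females, 12 juveniles
  (10:2 male-biased), each leaving 10–14 prints (~490 total). Masses are
  normal, truncated below at 15 kg: adults 57/48 ± 5 kg by sex, juveniles
  35 ± 8 kg. These defaults give a whole-sample mean near 48 kg, SD near
  10–11 kg and a range reaching down toward 20 kg, with an adult subset
  around 52–53 kg — the spread expected of a habitually barefoot reference
  population with a juvenile contingent.
* **Dimensions**: heel-to-hallux length L = c·m^(1/3) (isometry; c = 6.8
  cm·kg^(−1/3), ≈26 cm at 56 kg), with the other three dimensions fixed
  ratios (0.98, 0.38, 0.25) of the *underlying* allometric length. Each
  dimension carries its own independent multiplicative Gaussian noise
  (CV 4%): four noisy views of one size signal, which is what makes a
  multi-predictor estimator genuinely better than length alone.
* **Depths**: per print, a substrate multiplier (0.5 / 1.0 / 1.5 for
  dry-compact / moist / wet-soft) times a mass-proportional base (2 cm at
  50 kg) plus noise (SD 0.15 cm) sets the mean depth; the 14-region profile
  is a multivariate-normal draw from a gait template (relative units,
  compound-symmetric covariance, per-region SD 0.12, inter-region
  correlation 0.3) scaled by that mean depth. The walking template encodes a
  strictly decreasing medial-to-lateral forefoot gradient and a shallow
  medial midfoot (the longitudinal arch); the running template deepens the
  forefoot uniformly and lightens the heel. Substrate multipliers are
  placeholders: the real substrate–depth relationship of any particular
  sediment is not modelled.
* **Divergent templates**: a "Laetoli-like" trackmaker is emulated by adding
  a lateral-deepening ramp across the forefoot regions, scaled in pooled SDs
  of the per-print forefoot depth slope implied by the template covariance.
  0 SD is exactly the human template; ~4.3 SD flattens the default walking
  gradient; larger shifts reverse it.
* **Surfaces**: a tilted plane minus 14 truncated-Gaussian pits at
  anatomically arranged landmark positions. Pit amplitudes are obtained by
  solving a 14×14 kernel system so the summed field equals the depth profile
  *exactly* at the landmarks, landmark coordinates are snapped to grid nodes
  (bilinear sampling is exact at nodes), and the kernel is level-shifted to
  reach exactly zero at 7σ so the margin annulus is exactly planar. These
  three constructions are what make the round-trip identity (depths
  recovered to 1e-6 cm, plane coefficients to 1e-10 after fit + orient) an
  exact property rather than an approximation.
* **Fossil scenarios**: multi-trackway sites with fixed sex counts
  (round(male_fraction·n)), adult masses, a chosen gait, and optional
  divergent trackways, emitted with a ground-truth composition table.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: photogrammetric reconstruction error, erosion and
taphonomic overprinting, preservation bias ("Goldilocks" substrate
selection), correlated substrate variation along a trackway, foot-shape
differences beyond depth templates (juveniles are scaled-down adults),
actual substrate mechanics, and any non-Gaussian tail behaviour of real
depth distributions.

## Numerical choices

* Plane fits use `numpy.linalg.lstsq`; margin masks with < 3 cells or
  collinear cells raise a degenerate-fit error (rank check on centred
  coordinates, tolerance 1e-9 of the coordinate scale).
* Mahalanobis distances use a Cholesky factorisation with triangular solves;
  the test suite checks agreement with a naive Gauss–Jordan explicit inverse
  to 1e-10 on random SPD matrices of dimension 2–14.
* Differences at or below 1e-12 of the data scale are treated as exactly
  zero before factorisation (so machine-rounding residue from column means
  cannot turn a degenerate all-identical pool into a spurious singularity
  error).
* Negative measured depths (displacement rim at a nominal landmark) are
  allowed and warned about, never clipped.
* All randomness flows from named integer seeds through
  `numpy.random.default_rng` seed sequences; sub-streams use distinct
  (seed, stream) pairs so population, print, surface and resampling draws
  are independent but jointly reproducible. Report tables are byte-identical
  across runs with the same configuration.

## Problem sizes used in the validation experiments

The shipped experiments (`ichnostats.validation`, driven by the test suite
and `scripts/acceptance.py`) use: 100 random SPD instances for the oracle
check; 500 held-out replicates at 2,000 resampling iterations for type-I
error; 100 runs at 2,000 iterations for power; 50 seeded replicates of the
~490-print population with 500-tree ensembles for the model ordering; 5 seeds
of 343-row bootstraps for the in-bag count; 5 surfaces for the geometry round
trip; and 1,000 16-trackway assemblages for mean-method recovery. These sizes
give stable Monte-Carlo estimates (binomial SE ≤ ~1–2 percentage points on
the rates) at desk-scale runtime; the full 10,000-iteration default remains
the recommendation for real analyses.

## Known limitations

* The mass model cannot extrapolate above the largest training mass; fossil
  individuals larger than every reference subject are systematically
  underestimated.
* The comparison test assumes the reference pool's covariance is estimable
  (n prints ≫ 14 after gait matching); shrinkage mitigates but does not
  remove small-pool bias.
* Gait classification transfers from reference to fossil prints only insofar
  as depth topography, not substrate, drives the class difference.
* The mean method is a coarse instrument: it assumes a roughly balanced,
  two-class mixture and degrades toward chance as dimorphism shrinks.
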