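# Methods

## The measurement chain

A transmission ultrasound scan of a breast in a water bath yields a 3D
speed-of-sound (SoS) map, in m/s, on a voxel grid with millimetre-scale
spacing.  Within soft breast tissue the SoS ordering is stable: adipose
tissue is slowest, glandular tissue faster, ductal tissue faster still;
skin is also fast and sits directly against the bath.  The pipeline
turns one such map into tissue volumes and a longitudinal cohort of
volumes into hypothesis decisions:

SoS volume → breast mask → skin peel → fat vs. fibroglandular (FCM) →
gland vs. duct (FCM) → volumes in cc → per-breast CoV and pooled
variances → F / t / Spearman battery.

## Segmentation

**Bath separation.**  Water voxels lie in a band around the bath speed
(default 1500 ± 10 m/s).  The breast is the largest 26-connected
component of out-of-band voxels, with interior holes filled.  When
measurement noise is present (its SD is estimated robustly, via
1.4826·MAD, from the eight corner blocks of the grid, which the scan
geometry leaves as pure water), the band is widened to ±4 estimated SDs
and a one-step binary closing repairs noise pits in the component's
surface before hole-filling.  An all-water volume raises an empty-scan
error that the cleaning stage records rather than aborting a cohort run.

**Skin peel.**  Skin and fibroglandular tissue have similar SoS, so skin
is identified by geometry: voxels within a peel depth (default 4.5 mm,
Euclidean distance with anisotropic voxel spacing) of the water-facing
border *and* with SoS above the fat/fibroglandular decision boundary.
The SoS condition keeps fatty voxels at the border in the interior; the
boundary is the midpoint of a k = 2 FCM on the masked voxels (a plain
"above the fat center" rule would flip half of the fatty border voxels,
since they sit at the fat center).  The default peel depth exceeds the
default phantom's 2 mm skin so the whole shell is captured; the phantom
keeps a subcutaneous fat margin (default 6 mm) between skin and any
fibroglandular tissue, mirroring real anatomy, so the peel cannot eat
into glands.

**Tissue classification.**  Fuzzy C-means on the scalar SoS values of
the interior: memberships u_ij minimize Σ u_ijᵐ (x_i − c_j)², with
fuzzifier m = 2, tolerance 1e-5 on the center shift, ≤ 300 iterations,
and deterministic quantile initialization; centers are reported in
ascending order so cluster 0 is always the slower class.  The interior
is first split fat vs. fibroglandular (k = 2); the fibroglandular
compartment is then split gland vs. duct by a second k = 2 FCM (the
faster cluster is duct), or by a fixed threshold if configured.  Because
the first split's upper center is a gland/duct mixture mean, final
thresholds are refined to the symmetric midpoints (fat|gland and
gland|duct) once the second-stage centers are known — without this the
fat boundary sits closer to the gland distribution and gland volume is
biased low under noise.  A compartment whose values show no two-class
structure (fewer than two distinct values, or centers closer than
2 m/s) is left whole, so a breast without fibroglandular tissue
segments cleanly as fat.

**Label cleanup under noise.**  Classification always runs on the raw
voxel values — intensity smoothing was deliberately rejected because it
blends values across tissue interfaces and systematically dilates
high-SoS structures (ducts gained ~20% volume in trials).  Instead,
when noise is detected, a conservative 3×3×3 label filter relabels a
voxel to its neighbourhood mode only if fewer than 6 of its 26
neighbours share its current class (two passes).  This removes
salt-and-pepper misclassification without eroding the curved surfaces
of genuine structures; a plain mode filter shaved several percent off
convex lobules.  On noiseless input neither the widened band nor the
filter activates and segmentation is exact.

On default phantoms with noise SD up to 20% of the fat–gland contrast
(15 m/s), gland, duct, fat and total-breast volumes are recovered to
within 2%; without noise, exactly.

## Volumetrics and cleaning

Volumes are voxel counts × voxel volume, reported in cc; FGV = gland +
duct, TBV = skin + fat + FGV, QBD = FGV/TBV.  Cleaning excludes (a)
empty scans, (b) scans whose segmentation found no fibroglandular
tissue despite a non-zero TBV, and (c) per-breast glandular outliers
with modified z-score above 5, where the robust scale is
max(MAD, 0.10 × median).  The floor matters: in an 8-visit series with
a narrow luteal peak the raw MAD collapses to the noise scale and the
physiological peak itself would be flagged; the floored rule still
catches order-of-magnitude reconstruction failures, which is what the
exclusion step exists for.  Cleaning is idempotent, never raises, and
series left with fewer than two retained observations are dropped with
a recorded reason.

## The statistical battery

Per breast and tissue: n, mean, SD (n−1), and CoV = SD/mean.  Group
variances pool squared deviations of each scan from its own breast's
mean; the degrees of freedom are (retained scans − breasts), so 30
pre-menopausal breasts × 8 visits give df = 210.  The four null
hypotheses, all one-tailed:

| H   | statistic | default α |
|-----|-----------|-----------|
| I   | F = (pooled SD pre gland / post gland)² | 0.01 |
| II  | F, ductal analogue                      | 0.05 |
| III | t on per-breast glandular CoVs          | 0.01 |
| IV  | t on per-breast ductal CoVs             | 0.01 (plus a 0.10 sensitivity note) |

plus within-group gland-vs-duct variance contrasts at α = 0.001 and a
per-group Spearman rank correlation (rank–rank Pearson with average
ranks for ties) of per-breast mean duct vs. gland volume.

The t-test uses the approximate degrees of freedom with (n+1)
denominators and a −2 correction; in the equal-s, equal-n case this
evaluates to 2n (not the pooled 2n − 2), and it is implemented exactly
as stated.  Note that this makes the test slightly anti-conservative
relative to Welch–Satterthwaite: with groups of 40 and 8 the realized
one-sided size is ~2% at nominal α = 1%.  The d.f. is rounded to the
nearest integer for the critical-value lookup; the critical value at
the unrounded d.f. is logged as a cross-check.  Critical values always
come from the continuous F and t distributions (inverse regularized
incomplete beta), never from tables; where historical table lookups
disagree with exact quantiles, the exact quantiles govern.

Degenerate inputs (constant series, zero pooled variance) produce
explicit "degenerate" outcomes with fail-to-reject decisions and notes,
never crashes.

## The synthetic cohort generator

The generator encodes the study conditions the battery is meant to
detect.  Defaults:

- **Cohort**: 24 subjects — 15 pre-, 5 peri-, 4 post-menopausal — two
  breasts each, eight weekly visits (days 0–49, two 28-day cycles).
  The peri group is generated and summarized but the four hypotheses
  compare pre vs. post only.
- **Cycle model**: volume(t) = baseline × (1 + A·bump(t)) × ε, with
  bump a raised-cosine window of half-width 4 days peaking at day 24 —
  a late-luteal rise that is zero at menses onset.  Amplitudes A:
  gland 0.25 pre / 0.04 post; duct 0.06 pre / 0.03 post (ducts change
  little in either group; that stability is itself one of the
  conclusions the battery reproduces).
- **Baselines**: gland 21.6 cc pre / 17.7 cc post (glandular
  involution), duct 9.0 cc in both groups, TBV 500/450 cc.  With the
  CoV targets below these give group SD scales of ~4.3 cc (pre gland),
  ~2.2 cc (post gland) and ~1.8 cc (duct).
- **CoV targets**: gland 0.20 pre / 0.125 post; duct 0.20 in both
  groups.  The per-observation noise CV is solved analytically from
  the target after subtracting the cyclic contribution (the expected
  noise-free series CoV, averaged over a uniform grid of cycle-phase
  offsets): noise² = target² − cyclic².
- **Between-breast structure**: each breast draws a size factor
  (truncated-normal, SD 0.20) shared by its gland and duct baselines,
  plus small tissue-specific (SD 0.05) and subject-level (SD 0.05)
  factors.  The shared factor is what produces the high cross-breast
  rank correlation (~0.85) between mean gland and duct volumes.
- **Noise law**: a symmetric unit-mean multiplicative factor
  (1 + cv·z, truncated at 0.05).  A lognormal factor was tried first
  and rejected: its excess kurtosis (~0.6 at CV 0.2) roughly doubles
  the realized size of the one-tailed variance tests, i.e. the
  generator itself would break the battery's reference distributions.
- **Noise scale vs. size**: noise SD ∝ baseline^γ with γ = 0.5 for
  gland and γ = 0 for duct.  Ducts are at the scanner's resolution
  limit, so their error is absolute (a fixed floor in cc); glandular
  error grows partly with bulk.  γ < 1 keeps the pooled per-scan
  deviations near-homoscedastic within a group — with fully
  proportional noise (γ = 1) the variance F-tests rejected a true null
  several times their nominal α, because deviation SDs then inherit
  the spread of the size factor.

The generator reproduces: the luteal-phase rise of glandular (and
weakly ductal) volume; scale invariance of the CoV (doubling baselines
leaves it unchanged, bit-for-bit under a fixed seed); group mean CoVs
converging to their targets (law-of-large-numbers check at 100
subjects; the sample CoV of an 8-point series is biased low by ~3.5%,
the usual c₄-type effect, which is inside the 10% check tolerance);
Spearman coupling ≈ 0.85; and the reject/accept/reject/accept decision
pattern in ≥ 90% of seeded 20-pre + 4-post replicates.  That pattern
rate sits near its theoretical ceiling: even a perfectly calibrated
battery fails H-II in 5% of replicates by construction (α = 0.05 under
a true null) and loses a few more percent to H-III/H-IV finite-power
and finite-size effects.

What the generator does **not** emulate: reconstruction physics and
artifacts (attenuation, reflection, aliasing), partial-volume mixing at
tissue interfaces (phantom voxels are pure, so noiseless segmentation
is exact in a way real scans never are), anatomically validated duct
topology, hormone dynamics (the luteal bump is a fixed window, not a
hormone model), irregular cycle lengths, and visit-to-visit
registration error.  Passing tests therefore demonstrate the
correctness and calibration of the measurement-and-inference chain, not
the clinical accuracy of the imaging modality.

## Imaging phantom details

Grid 96³ at 1.5 mm isotropic (the transmission-mode resolution scale);
breast = sphere of radius 55 mm (interior) plus a 2 mm skin shell,
centred in the bath.  SoS means (m/s): water 1500, fat 1440, gland
1515, duct 1560, skin 1580 — literature-typical values chosen to
preserve the physiological orderings (only the orderings are
constrained by the science; the exact values are configurable).
Additive Gaussian voxel noise with configurable SD.

Gland and duct compartments are carved to an exact voxel count from
shape potentials: ducts by distance to a recursive binary tree of
segments grown inward from a nipple point (depth 5, tapering radius),
glands by normalized distance to a set of random ellipsoid lobules
(default 12, semi-axes 8–16 mm).  Selecting the n smallest-potential
voxels (ties broken by voxel index, so output is deterministic) gives
ground-truth fractions accurate to one voxel, and lets a volume series
be rendered by growing/shrinking the same frozen geometry to each
timepoint's target volume — the round trip through rendering,
segmentation and volumetry recovers series values to within one voxel
volume per structure.

## Reproducibility

Every stochastic component takes an explicit integer seed
(`numpy.random.Generator`); identical (spec, seed) pairs give
bit-identical phantoms, cohorts, and reports.  CSV outputs carry
provenance headers (package version, seed, config hash); display
splines in figures are never fed back into statistics.
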