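"""Synthetic speed-of-sound breast phantoms and longitudinal cohorts.

The imaging phantom is a breast immersed in a water bath: a spherical
breast with a thin skin shell, an adipose interior, glandular lobules
(random ellipsoid blobs) and a branching ductal tree (capsules around a
recursive binary tree of segments).  Ducts are acoustically faster than
glands, and both are faster than fat; skin is the high-speed confounder
next to the water border.  Gland and duct compartments are carved to an
*exact* voxel count from smooth shape potentials, so the emitted
ground-truth label volume reproduces the requested tissue fractions (or
an explicit target volume) to within one voxel.

The longitudinal generator produces per-breast volume series with a
luteal-phase raised-cosine bump (zero at menses onset, peaking late in
the cycle) on top of a per-breast baseline, with multiplicative lognormal
measurement noise.  Cohort-level defaults encode the study conditions:
pre-menopausal glandular series targeting a CoV of 0.20 vs. 0.125
post-menopausally, ductal CoV 0.20 in both groups, weekly visits over two
cycles, and gland/duct baselines coupled through a per-breast size factor
so that mean ductal and glandular volumes are strongly rank-correlated
across a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .segmentation import SoSVolume, Tissue, TissueLabelVolume
from .volumetry import BreastVolumetrics, VolumeSeries, MM3_PER_CC

__all__ = [
    "PhantomSpec",
    "CycleModel",
    "GroupParams",
    "CohortSpec",
    "build_phantom",
    "simulate_breast_series",
    "simulate_cohort",
    "render_series_to_volumes",
    "luteal_bump",
    "cyclic_cov",
    "measurement_cv_for_target",
]


# ---------------------------------------------------------------------------
# imaging phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acoustics of one synthetic breast volume.

    ``breast_radius_mm`` is the radius of the breast proper (fat +
    fibroglandular interior); the skin shell sits outside it, so the
    grid must contain ``breast_radius_mm + skin_thickness_mm``.
    ``gland_fraction`` / ``duct_fraction`` are target shares of the whole
    breast (skin included).  ``fg_margin_mm`` keeps a subcutaneous fat
    layer between the skin and any fibroglandular tissue.
    Speed-of-sound defaults (m/s) preserve the physiological ordering
    fat < gland < duct and fat < skin; only the orderings are
    anatomically constrained, the values are literature-typical.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    sos_water: float = 1500.0
    sos_fat: float = 1440.0
    sos_gland: float = 1515.0
    sos_duct: float = 1560.0
    sos_skin: float = 1580.0
    sos_noise_sd: float = 0.0
    breast_radius_mm: float = 55.0
    skin_thickness_mm: float = 2.0
    n_lobules: int = 12
    duct_tree_depth: int = 5
    duct_branch_length_mm: float = 9.0
    duct_branch_radius_mm: float = 2.5
    gland_fraction: float = 0.15
    duct_fraction: float = 0.04
    fg_margin_mm: float = 6.0

    def __post_init__(self) -> None:
        if not (self.sos_fat < self.sos_gland < self.sos_duct):
            raise ValueError("tissue ordering requires sos_fat < sos_gland < sos_duct")
        if not self.sos_skin > self.sos_fat:
            raise ValueError("skin must be faster than fat (sos_skin > sos_fat)")
        for name in ("gland_fraction", "duct_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.gland_fraction + self.duct_fraction >= 1.0:
            raise ValueError("gland_fraction + duct_fraction must be < 1")
        if self.sos_noise_sd < 0:
            raise ValueError("sos_noise_sd must be >= 0")
        if self.breast_radius_mm < 0 or self.skin_thickness_mm < 0:
            raise ValueError("radii must be >= 0")
        extent = [n * s for n, s in zip(self.grid_shape, self.voxel_size)]
        outer = self.breast_radius_mm + self.skin_thickness_mm
        if any(2.0 * outer > e for e in extent) and self.breast_radius_mm > 0:
            raise ConfigurationError(
                f"grid extent {extent} mm cannot contain a breast of outer "
                f"radius {outer} mm"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates in mm, origin at the grid centre."""
    axes = [
        (np.arange(n) + 0.5 - n / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _duct_segments(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Recursive binary tree of (start, end, level) segments from the nipple.

    The trunk starts near the breast surface on the +x axis (the nipple)
    and branches inward; endpoints are clamped to the fibroglandular
    candidate sphere.
    """
    r_cand = spec.breast_radius_mm - spec.fg_margin_mm
    if r_cand <= 0:
        return []
    nipple = np.array([0.92 * r_cand, 0.0, 0.0])
    segments: list[tuple[np.ndarray, np.ndarray, int]] = []

    def clamp(p: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(p)
        return p if r <= r_cand else p * (r_cand / r)

    def grow(p: np.ndarray, direction: np.ndarray, level: int) -> None:
        if level >= spec.duct_tree_depth:
            return
        length = spec.duct_branch_length_mm * (0.92 ** level)
        end = clamp(p + length * direction)
        segments.append((p, end, level))
        for _ in range(2):
            perturb = rng.normal(scale=0.55, size=3)
            child = direction + perturb
            norm = np.linalg.norm(child)
            if norm < 1e-9:
                child, norm = direction, 1.0
            grow(end, child / norm, level + 1)

    grow(nipple, np.array([-1.0, 0.0, 0.0]), 0)
    return segments


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each row of ``points`` to segment ab (mm)."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(points - proj, axis=1)


def _select_exact(potential: np.ndarray, n: int) -> np.ndarray:
    """Indices of the ``n`` smallest potentials, ties broken by index order."""
    if n <= 0:
        return np.empty(0, dtype=np.intp)
    order = np.lexsort((np.arange(potential.size), potential))
    return order[:n]


def _build_labels(
    spec: PhantomSpec,
    rng: np.random.Generator,
    n_gland: int,
    n_duct: int,
) -> np.ndarray:
    xx, yy, zz = _grid_coords(spec)
    r2 = xx ** 2 + yy ** 2 + zz ** 2
    outer = spec.breast_radius_mm + spec.skin_thickness_mm

    labels = np.full(spec.grid_shape, int(Tissue.WATER), dtype=np.uint8)
    if spec.breast_radius_mm <= 0:
        return labels
    breast = r2 <= outer ** 2
    interior = r2 <= spec.breast_radius_mm ** 2
    labels[breast & ~interior] = Tissue.SKIN
    labels[interior] = Tissue.FAT

    r_cand = spec.breast_radius_mm - spec.fg_margin_mm
    cand = r2 <= r_cand ** 2 if r_cand > 0 else np.zeros_like(breast)
    cand_idx = np.flatnonzero(cand.ravel())
    if n_gland + n_duct > cand_idx.size:
        raise ConfigurationError(
            f"requested {n_gland + n_duct} fibroglandular voxels but only "
            f"{cand_idx.size} candidate voxels are available inside the breast"
        )

    pts = np.column_stack([np.broadcast_to(c, spec.grid_shape).ravel()[cand_idx]
                           for c in (xx, yy, zz)])

    # ductal tree: distance to the branching skeleton, tapered by level
    segments = _duct_segments(spec, rng)
    if n_duct > 0 and segments:
        duct_pot = np.full(cand_idx.size, np.inf)
        for a, b, level in segments:
            taper = 0.85 ** level
            d = _segment_distance(pts, a, b) / (spec.duct_branch_radius_mm * taper)
            np.minimum(duct_pot, d, out=duct_pot)
        duct_sel = cand_idx[_select_exact(duct_pot, n_duct)]
    else:
        duct_sel = np.empty(0, dtype=np.intp)

    # glandular lobules: ellipsoid potentials around branch-tip-ish centres
    if n_gland > 0:
        gland_pot = np.full(cand_idx.size, np.inf)
        max_c = max(0.0, r_cand - 4.0)
        for _ in range(max(1, spec.n_lobules)):
            u = rng.normal(size=3)
            u /= max(np.linalg.norm(u), 1e-12)
            centre = u * max_c * rng.uniform(0.0, 0.75) ** (1.0 / 3.0)
            semi = rng.uniform(8.0, 16.0, size=3)
            d = np.sqrt((((pts - centre) / semi) ** 2).sum(axis=1))
            np.minimum(gland_pot, d, out=gland_pot)
        taken = np.zeros(cand_idx.size, dtype=bool)
        taken[np.searchsorted(cand_idx, duct_sel)] = True
        gland_pot[taken] = np.inf
        gland_sel = cand_idx[_select_exact(gland_pot, n_gland)]
    else:
        gland_sel = np.empty(0, dtype=np.intp)

    flat = labels.ravel()
    flat[gland_sel] = Tissue.GLAND
    flat[duct_sel] = Tissue.DUCT
    return labels


_SOS_BY_TISSUE = {
    Tissue.WATER: "sos_water",
    Tissue.SKIN: "sos_skin",
    Tissue.FAT: "sos_fat",
    Tissue.GLAND: "sos_gland",
    Tissue.DUCT: "sos_duct",
}


def _labels_to_sos(
    spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator
) -> SoSVolume:
    values = np.empty(labels.shape, dtype=np.float64)
    for tissue, attr in _SOS_BY_TISSUE.items():
        values[labels == tissue] = getattr(spec, attr)
    if spec.sos_noise_sd > 0:
        values = values + rng.normal(0.0, spec.sos_noise_sd, size=labels.shape)
        np.maximum(values, 1.0, out=values)  # keep values physical/positive
    return SoSVolume(values=values, voxel_size=spec.voxel_size)


def build_phantom(
    spec: PhantomSpec, seed: int = 0
) -> tuple[SoSVolume, TissueLabelVolume]:
    """Generate one speed-of-sound volume and its exact ground-truth labels.

    Voxels outside the breast are water; gland and duct compartments are
    carved to ``round(fraction * breast voxel count)`` voxels exactly.
    Identical (spec, seed) pairs produce bit-identical output.
    """
    rng = np.random.default_rng(seed)
    geom_rng, noise_rng = rng.spawn(2)

    # count breast voxels to convert fractions into exact voxel targets
    xx, yy, zz = _grid_coords(spec)
    outer = spec.breast_radius_mm + spec.skin_thickness_mm
    n_breast = int(np.count_nonzero(xx ** 2 + yy ** 2 + zz ** 2 <= outer ** 2)) \
        if spec.breast_radius_mm > 0 else 0
    n_gland = int(round(spec.gland_fraction * n_breast))
    n_duct = int(round(spec.duct_fraction * n_breast))

    labels = _build_labels(spec, geom_rng, n_gland, n_duct)
    vol = _labels_to_sos(spec, labels, noise_rng)
    return vol, TissueLabelVolume(labels=labels, voxel_size=spec.voxel_size)


def render_series_to_volumes(
    series: VolumeSeries,
    spec: PhantomSpec,
    seed: int = 0,
) -> list[tuple[SoSVolume, TissueLabelVolume]]:
    """Realize each timepoint of a volume series as a phantom image.

    The breast geometry (lobule and duct skeletons) is frozen from
    ``seed``, and at each timepoint the gland and duct compartments are
    grown/shrunk along their shape potentials to match that timepoint's
    true volumes to within one voxel; only the noise draw differs between
    timepoints.  Raises :class:`ConfigurationError` when a requested
    volume exceeds the breast's fibroglandular capacity.
    """
    rng = np.random.default_rng(seed)
    geom_rng, noise_master = rng.spawn(2)
    geom_state = geom_rng.bit_generator.state
    voxel_cc = spec.voxel_volume_mm3 / MM3_PER_CC

    out = []
    for obs, noise_rng in zip(series.observations,
                              noise_master.spawn(len(series.observations))):
        n_gland = int(round(obs.gland_cc / voxel_cc))
        n_duct = int(round(obs.duct_cc / voxel_cc))
        geom_rng.bit_generator.state = geom_state  # same geometry every timepoint
        labels = _build_labels(spec, geom_rng, n_gland, n_duct)
        vol = _labels_to_sos(spec, labels, noise_rng)
        out.append((vol, TissueLabelVolume(labels=labels, voxel_size=spec.voxel_size)))
    return out


# ---------------------------------------------------------------------------
# longitudinal cycle model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleModel:
    """Per-breast generative model for a volume series over the cycle.

    Volumes follow ``baseline * (1 + amplitude * bump(t)) * noise`` where
    ``bump`` is a raised-cosine window peaking at ``luteal_peak_day``
    (late luteal phase, just before menstruation) and zero at menses
    onset, and ``noise`` is a symmetric unit-mean multiplicative factor
    with the given per-observation coefficient of variation.
    ``measurement_noise_cv_duct`` lets the ductal channel carry a
    different noise level than the glandular one; when ``None`` the
    glandular value is used.
    """

    baseline_gland_cc: float = 21.6
    baseline_duct_cc: float = 9.0
    baseline_tbv_cc: float = 500.0
    cycle_length_days: float = 28.0
    luteal_amplitude_gland: float = 0.25
    luteal_amplitude_duct: float = 0.06
    luteal_peak_day: float = 24.0
    luteal_width_days: float = 4.0
    measurement_noise_cv: float = 0.19
    measurement_noise_cv_duct: float | None = None
    phase_offset_days: float = 0.0

    def __post_init__(self) -> None:
        if self.luteal_amplitude_gland < 0 or self.luteal_amplitude_duct < 0:
            raise ValueError("luteal amplitudes must be >= 0")
        if not (0.0 <= self.luteal_peak_day < self.cycle_length_days):
            raise ValueError("luteal_peak_day must lie within the cycle")
        if self.measurement_noise_cv < 0:
            raise ValueError("measurement_noise_cv must be >= 0")
        if self.luteal_width_days <= 0:
            raise ValueError("luteal_width_days must be > 0")

    @property
    def duct_noise_cv(self) -> float:
        return (self.measurement_noise_cv if self.measurement_noise_cv_duct is None
                else self.measurement_noise_cv_duct)


def luteal_bump(
    t: np.ndarray | float,
    cycle_length: float = 28.0,
    peak_day: float = 24.0,
    width: float = 4.0,
    phase_offset: float = 0.0,
) -> np.ndarray:
    """Raised-cosine luteal window, 1 at the peak and 0 outside +/- width.

    ``width`` is the half-width in days.  With the defaults the bump is
    supported on days 20-28 of a 28-day cycle: the fibroglandular rise
    sits just prior to menstruation and vanishes at menses onset.
    """
    phase = np.mod(np.asarray(t, dtype=float) - phase_offset, cycle_length)
    d = np.abs(phase - peak_day)
    d = np.minimum(d, cycle_length - d)  # circular distance to the peak
    out = np.where(d <= width, 0.5 * (1.0 + np.cos(np.pi * d / width)), 0.0)
    return out


def cyclic_cov(
    timepoints: Sequence[float],
    amplitude: float,
    cycle_length: float = 28.0,
    peak_day: float = 24.0,
    width: float = 4.0,
    n_offsets: int = 113,
) -> float:
    """Expected noise-free series CoV induced by the luteal bump alone.

    Averages the squared sample CoV of the deterministic series
    ``1 + amplitude * bump(t)`` over a uniform grid of cycle phase
    offsets, then returns the square root.  Used to split a target total
    CoV into its cyclic and measurement-noise parts.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2 or amplitude == 0.0:
        return 0.0
    offsets = np.linspace(0.0, cycle_length, n_offsets, endpoint=False)
    cov2 = np.empty(n_offsets)
    for i, off in enumerate(offsets):
        d = 1.0 + amplitude * luteal_bump(t, cycle_length, peak_day, width, off)
        cov2[i] = d.var(ddof=1) / d.mean() ** 2
    return float(np.sqrt(cov2.mean()))


def measurement_cv_for_target(
    target_cov: float,
    amplitude: float,
    timepoints: Sequence[float],
    cycle_length: float = 28.0,
    peak_day: float = 24.0,
    width: float = 4.0,
) -> float:
    """Noise CV needed so cyclic variation plus noise hits a target series CoV.

    Solves ``target^2 = cyclic^2 + noise^2`` (independent multiplicative
    components, small-CV approximation); returns 0 when the cyclic part
    alone already exceeds the target.
    """
    cyc = cyclic_cov(timepoints, amplitude, cycle_length, peak_day, width)
    return math.sqrt(max(target_cov ** 2 - cyc ** 2, 0.0))


def simulate_breast_series(
    model: CycleModel,
    group: str,
    timepoints: Sequence[float],
    seed: int = 0,
    subject_id: str = "S00",
    side: str = "L",
) -> VolumeSeries:
    """Simulate one breast's volumetrics at the given study days.

    Glandular volume at day t is
    ``baseline * (1 + amplitude * bump(t)) * eps`` with lognormal
    unit-mean noise ``eps``; ductal volume is analogous with its own
    amplitude and noise CV.  TBV is the TBV baseline plus the
    fibroglandular excursions (fat is assumed static over the cycle).
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2:
        raise ValueError("a series needs at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)

    bump = luteal_bump(t, model.cycle_length_days, model.luteal_peak_day,
                       model.luteal_width_days, model.phase_offset_days)

    def noisy(baseline: float, amplitude: float, cv: float) -> np.ndarray:
        det = baseline * (1.0 + amplitude * bump)
        if cv <= 0:
            return det
        # symmetric unit-mean multiplicative factor, truncated away from
        # zero; at the CVs in play the truncation is in the far tail, so
        # the factor keeps mean 1 and SD ~cv without the excess kurtosis
        # a lognormal would add (which distorts one-tailed variance tests)
        eps = np.maximum(1.0 + cv * rng.standard_normal(t.size), 0.05)
        return det * eps

    gland = noisy(model.baseline_gland_cc, model.luteal_amplitude_gland,
                  model.measurement_noise_cv)
    duct = noisy(model.baseline_duct_cc, model.luteal_amplitude_duct,
                 model.duct_noise_cv)
    tbv = model.baseline_tbv_cc + (gland - model.baseline_gland_cc) \
        + (duct - model.baseline_duct_cc)

    obs = [
        BreastVolumetrics(
            tbv_cc=float(tbv[i]), gland_cc=float(gland[i]),
            duct_cc=float(duct[i]),
            fat_cc=float(tbv[i] - gland[i] - duct[i]), skin_cc=0.0,
            scan_id=f"{subject_id}_{side}_d{int(round(t[i])):03d}",
            day=float(t[i]),
        )
        for i in range(t.size)
    ]
    return VolumeSeries(subject_id=subject_id, side=side, group=group,
                        observations=obs)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Per-group distributions from which breast-level cycle models are drawn.

    ``*_cov_target`` are the series CoV levels the group should exhibit;
    the per-observation noise CV is solved from them after subtracting
    the cyclic contribution.  ``size_sd`` is the SD of the per-breast
    log-size factor shared by the gland and duct baselines (it couples
    the two tissues and drives their cross-breast rank correlation);
    ``tissue_sd`` adds independent per-tissue spread and ``subject_sd``
    a factor shared by a subject's two breasts.

    ``gland_noise_exponent`` / ``duct_noise_exponent`` (gamma) set how
    the measurement-noise SD scales with the tissue baseline: SD
    proportional to (baseline)^gamma, anchored so a breast at the group
    baseline hits the CoV target.  gamma = 1 is constant per-breast CoV
    (fully proportional error); gamma = 0 is a constant absolute SD in
    cc across the group (a pure resolution floor).  Defaults: 0.5 for
    glands (bulk structures; boundary error grows with size but a floor
    remains) and 0.0 for ducts, whose calibre is at the scanner's
    resolution limit so their error is resolution-dominated.  With
    gamma < 1 a breast's CoV shrinks moderately with its size (larger
    breasts are relatively steadier) and the pooled per-scan deviations
    the variance battery compares stay close to homoscedastic within a
    group, keeping the F reference distribution calibrated.
    """

    gland_baseline_cc: float
    duct_baseline_cc: float
    tbv_baseline_cc: float
    gland_cov_target: float
    duct_cov_target: float
    gland_amplitude: float
    duct_amplitude: float
    size_sd: float = 0.20
    tissue_sd: float = 0.05
    subject_sd: float = 0.05
    cycle_length_days: float = 28.0
    luteal_peak_day: float = 24.0
    luteal_width_days: float = 4.0
    gland_noise_exponent: float = 0.5
    duct_noise_exponent: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gland_noise_exponent", "duct_noise_exponent"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


DEFAULT_GROUP_PARAMS: Mapping[str, GroupParams] = {
    # Baselines chosen so that CoV targets reproduce the study's group SD
    # scale (gland ~4.3 cc pre / ~2.2 cc post); the duct baseline is the
    # same in both groups because ductal tissue is the compartment that
    # does not change appreciably across menopause.
    "pre": GroupParams(
        gland_baseline_cc=21.6, duct_baseline_cc=9.0, tbv_baseline_cc=500.0,
        gland_cov_target=0.20, duct_cov_target=0.20,
        gland_amplitude=0.25, duct_amplitude=0.06,
    ),
    "peri": GroupParams(
        gland_baseline_cc=19.0, duct_baseline_cc=9.0, tbv_baseline_cc=470.0,
        gland_cov_target=0.17, duct_cov_target=0.20,
        gland_amplitude=0.15, duct_amplitude=0.05,
    ),
    "post": GroupParams(
        gland_baseline_cc=17.7, duct_baseline_cc=9.0, tbv_baseline_cc=450.0,
        gland_cov_target=0.125, duct_cov_target=0.20,
        gland_amplitude=0.04, duct_amplitude=0.03,
    ),
}

DEFAULT_TIMEPOINTS: tuple[float, ...] = tuple(float(d) for d in range(0, 56, 7))


@dataclass(frozen=True)
class CohortSpec:
    """A longitudinal study cohort: subjects per group, visit days, seed.

    Defaults mirror the study scale: 24 subjects (15 pre-, 5 peri-,
    4 post-menopausal), two breasts each, eight weekly visits spanning
    two 28-day cycles.
    """

    n_pre_subjects: int = 15
    n_peri_subjects: int = 5
    n_post_subjects: int = 4
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    group_params: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre_subjects + self.n_peri_subjects + self.n_post_subjects <= 0:
            raise ConfigurationError("cohort must contain at least one subject")
        if any(n < 0 for n in (self.n_pre_subjects, self.n_peri_subjects,
                               self.n_post_subjects)):
            raise ConfigurationError("subject counts must be >= 0")
        if len(self.timepoints) < 2:
            raise ConfigurationError("every breast needs at least 2 timepoints")

    @property
    def n_subjects(self) -> int:
        return self.n_pre_subjects + self.n_peri_subjects + self.n_post_subjects


def simulate_cohort(spec: CohortSpec) -> list[VolumeSeries]:
    """Simulate one VolumeSeries per breast (two per subject).

    Subject- and breast-level lognormal factors set the baselines; the
    per-breast size factor is shared between the gland and duct channels,
    so per-breast mean gland and duct volumes are positively coupled
    across the cohort.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cohort: list[VolumeSeries] = []
    counts = (("pre", spec.n_pre_subjects), ("peri", spec.n_peri_subjects),
              ("post", spec.n_post_subjects))
    for group, n_subj in counts:
        gp = spec.group_params[group]
        gland_cv = measurement_cv_for_target(
            gp.gland_cov_target, gp.gland_amplitude, spec.timepoints,
            gp.cycle_length_days, gp.luteal_peak_day, gp.luteal_width_days)
        duct_cv = measurement_cv_for_target(
            gp.duct_cov_target, gp.duct_amplitude, spec.timepoints,
            gp.cycle_length_days, gp.luteal_peak_day, gp.luteal_width_days)
        def factor(sd: float) -> float:
            # symmetric unit-mean spread factor, truncated away from zero;
            # symmetry keeps derived per-breast statistics (CoV, pooled
            # deviations) free of distributional skew the battery's
            # one-tailed reference distributions do not model
            return max(1.0 + rng.normal(0.0, sd), 0.2)

        for i in range(n_subj):
            subject_id = f"{group}{i + 1:02d}"
            subj_factor = factor(gp.subject_sd)
            phase = rng.uniform(0.0, gp.cycle_length_days)
            for side in ("L", "R"):
                size = factor(gp.size_sd)
                g_fac = factor(gp.tissue_sd)
                d_fac = factor(gp.tissue_sd)
                b_gland = gp.gland_baseline_cc * subj_factor * size * g_fac
                b_duct = gp.duct_baseline_cc * subj_factor * size * d_fac
                # noise SD ~ baseline^gamma: CV shrinks as (baseline/group)^-(1-gamma)
                cv_g = gland_cv * (gp.gland_baseline_cc / b_gland) \
                    ** (1.0 - gp.gland_noise_exponent)
                cv_d = duct_cv * (gp.duct_baseline_cc / b_duct) \
                    ** (1.0 - gp.duct_noise_exponent)
                model = CycleModel(
                    baseline_gland_cc=b_gland,
                    baseline_duct_cc=b_duct,
                    baseline_tbv_cc=gp.tbv_baseline_cc * subj_factor * size,
                    cycle_length_days=gp.cycle_length_days,
                    luteal_amplitude_gland=gp.gland_amplitude,
                    luteal_amplitude_duct=gp.duct_amplitude,
                    luteal_peak_day=gp.luteal_peak_day,
                    luteal_width_days=gp.luteal_width_days,
                    measurement_noise_cv=cv_g,
                    measurement_noise_cv_duct=cv_d,
                    phase_offset_days=phase,
                )
                series_seed = int(rng.integers(0, 2 ** 31 - 1))
                cohort.append(simulate_breast_series(
                    model, group, spec.timepoints, seed=series_seed,
                    subject_id=subject_id, side=side))
    return cohort
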