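"""Three-compartment tissue segmentation of speed-of-sound breast volumes.

Pipeline (``segment_tissues``):

1. bath separation — voxels outside a water speed-of-sound band, largest
   26-connected component, holes filled (``mask_breast``);
2. skin peel — high-SoS voxels within a peel depth (mm, geodesic from the
   water-facing border) are skin, the rest is breast interior
   (``peel_skin``);
3. fuzzy C-means (k = 2) on interior SoS values: the lower-center cluster
   is adipose tissue, the upper fibroglandular;
4. the fibroglandular compartment is subdivided into gland and duct by a
   second k = 2 FCM on its SoS values (ducts are the faster tissue), or
   by a fixed threshold if configured.

Classification always runs on the raw voxel values so that a noiseless
volume is segmented exactly.  When measurement noise is detected (its SD
is estimated from the corners of the bath), the water band is widened
accordingly and the final labels are cleaned with a 3x3x3 mode filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, EmptyScanError

__all__ = [
    "Tissue",
    "SoSVolume",
    "TissueLabelVolume",
    "FcmResult",
    "SegmentationParams",
    "fuzzy_c_means",
    "mask_breast",
    "peel_skin",
    "segment_tissues",
    "estimate_noise_sd",
]


class Tissue(IntEnum):
    """Label codes, ordered by typical speed of sound within the breast."""

    WATER = 0
    SKIN = 1
    FAT = 2
    GLAND = 3
    DUCT = 4


@dataclass(frozen=True)
class SoSVolume:
    """A 3D speed-of-sound map (m/s) with anisotropic voxel spacing in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    axial_axis: int = 2

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("speed-of-sound values must be finite and positive")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class TissueLabelVolume:
    """Per-voxel tissue codes sharing shape and spacing with the source volume."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {lab.shape}")
        if lab.min() < 0 or lab.max() > max(Tissue):
            raise ValueError("labels outside the known tissue codes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def count(self, tissue: Tissue) -> int:
        return int(np.count_nonzero(self.labels == tissue))


@dataclass(frozen=True)
class FcmResult:
    """Converged fuzzy C-means state: ascending centers, row-normalized memberships."""

    centers: np.ndarray           # (k,) ascending
    memberships: np.ndarray       # (n, k), rows sum to 1
    iterations: int
    converged: bool

    def hard_labels(self) -> np.ndarray:
        """Cluster index per sample by maximum membership."""
        return np.argmax(self.memberships, axis=1)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the three-compartment pipeline.

    ``water_sos`` and ``water_band_halfwidth`` define the bath band
    (water_sos +/- halfwidth, m/s); the band is widened to 4 estimated
    noise SDs when that is larger.  ``skin_peel_mm`` is the geodesic peel
    depth from the water-facing border; a voxel in the peel is skin only
    if its SoS lies above the fat/fibroglandular decision boundary (or
    above ``skin_sos_threshold`` when given), so fatty border voxels stay
    fat.  ``duct_split_rule`` is ``"fcm"`` (second k = 2 FCM on
    fibroglandular SoS, upper cluster = duct) or ``"threshold"`` (fixed
    ``duct_sos_threshold``).  ``label_cleanup`` applies the 3x3x3 mode
    filter: "auto" = only when noise is detected.
    """

    water_sos: float = 1500.0
    water_band_halfwidth: float = 10.0
    skin_peel_mm: float = 4.5
    skin_sos_threshold: float | None = None
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    min_center_separation: float = 2.0    # m/s; below this a split is degenerate
    duct_split_rule: str = "fcm"
    duct_sos_threshold: float = 1537.5
    label_cleanup: str = "auto"           # "auto" | "on" | "off"
    noise_floor_sd: float = 0.5           # m/s; below this the scan is treated as noiseless
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.skin_peel_mm < 0:
            raise ValueError("skin_peel_mm must be >= 0")
        if self.fcm_m <= 1.0:
            raise ValueError("FCM fuzzifier m must be > 1")
        if self.fcm_tol <= 0:
            raise ValueError("FCM tolerance must be > 0")
        if self.duct_split_rule not in ("fcm", "threshold"):
            raise ValueError(f"unknown duct_split_rule {self.duct_split_rule!r}")
        if self.label_cleanup not in ("auto", "on", "off"):
            raise ValueError(f"unknown label_cleanup {self.label_cleanup!r}")


# ---------------------------------------------------------------------------
# fuzzy C-means
# ---------------------------------------------------------------------------

def fuzzy_c_means(
    samples: Sequence[float] | np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    init: str = "quantile",
    seed: int | None = None,
) -> FcmResult:
    """Fuzzy C-means on scalar samples.

    Minimizes sum_ij u_ij^m (x_i - c_j)^2 by alternating membership and
    center updates until the largest center change drops below ``tol`` or
    ``max_iter`` is reached.  Default initialization places centers at
    evenly spaced sample quantiles, which makes the run fully
    deterministic; ``init="random"`` draws centers from the sample range
    using ``seed``.

    Returns centers sorted ascending with membership columns permuted to
    match, so cluster 0 is always the slowest class.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if x.size < k:
        raise DegenerateDataError(f"need at least k={k} samples, got {x.size}")
    if np.unique(x).size < k:
        raise DegenerateDataError(
            f"need at least {k} distinct sample values to form {k} clusters"
        )
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")

    if init == "quantile":
        centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        centers = rng.uniform(x.min(), x.max(), size=k)
    else:
        raise ValueError(f"unknown init {init!r}")
    centers = np.sort(centers)
    # collapse accidental duplicate initial centers
    for j in range(1, k):
        if centers[j] <= centers[j - 1]:
            centers[j] = centers[j - 1] + max(1e-12, 1e-6 * (x.max() - x.min() + 1.0))

    expo = 2.0 / (m - 1.0)
    u = np.empty((x.size, k))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        d2 = (x[:, None] - centers[None, :]) ** 2
        zero = d2 < 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)  # = |x - c|^(-2/(m-1))
            u = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            u[any_zero] = zero[any_zero].astype(float)
            u[any_zero] /= u[any_zero].sum(axis=1, keepdims=True)
        um = u ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            converged = True
            break

    order = np.argsort(centers)
    return FcmResult(centers=centers[order], memberships=u[:, order],
                     iterations=iterations, converged=converged)


# ---------------------------------------------------------------------------
# masking and skin peel
# ---------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def estimate_noise_sd(vol: SoSVolume, corner_frac: float = 0.08) -> float:
    """Robust noise SD estimate from the eight corner blocks of the bath.

    Assumes the breast is centred in the water bath so the corners of the
    grid hold pure water; uses 1.4826 x MAD so a stray non-water voxel
    cannot inflate the estimate.
    """
    v = vol.values
    n = [max(2, int(round(s * corner_frac))) for s in v.shape]
    blocks = []
    for sx in (slice(0, n[0]), slice(-n[0], None)):
        for sy in (slice(0, n[1]), slice(-n[1], None)):
            for sz in (slice(0, n[2]), slice(-n[2], None)):
                blocks.append(v[sx, sy, sz].ravel())
    samples = np.concatenate(blocks)
    mad = np.median(np.abs(samples - np.median(samples)))
    return float(1.4826 * mad)


def mask_breast(
    vol: SoSVolume,
    params: SegmentationParams | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Separate the breast from the water bath.

    Water is the band ``water_sos +/- max(halfwidth, 4 * noise SD)``.
    The mask is the largest 26-connected component of out-of-band voxels
    with interior holes filled; detached speckle is discarded by the
    largest-component rule.
    """
    params = params or SegmentationParams()
    if noise_sd is None:
        noise_sd = estimate_noise_sd(vol)
    half = max(params.water_band_halfwidth, 4.0 * noise_sd)
    non_water = np.abs(vol.values - params.water_sos) > half
    if not non_water.any():
        raise EmptyScanError("no voxels outside the water band (empty scan)")
    comps, n_comps = ndimage.label(non_water, structure=_CONN26)
    if n_comps == 0:
        raise EmptyScanError("no connected non-water component found")
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    mask = comps == np.argmax(sizes)
    if noise_sd > params.noise_floor_sd:
        # noise pits the component's surface; close single-voxel gaps so
        # hole-filling can recover the porous interior
        mask = ndimage.binary_closing(mask, structure=_CONN26)
    return ndimage.binary_fill_holes(mask)


def peel_skin(
    mask: np.ndarray,
    vol: SoSVolume,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the breast mask into a skin shell and an interior.

    Skin = voxels within ``skin_peel_mm`` (Euclidean distance in mm,
    anisotropic spacing respected) of the water-facing border AND with
    SoS above the fat/fibroglandular boundary, so that fatty voxels at
    the border stay in the interior.  The threshold is
    ``params.skin_sos_threshold`` if set, otherwise the midpoint of a
    k = 2 FCM on the masked SoS values.

    Returns ``(skin, interior)``; the two are disjoint and union to the mask.
    """
    params = params or SegmentationParams()
    if not mask.any():
        raise EmptyScanError("empty breast mask")
    if params.skin_peel_mm == 0.0:
        return np.zeros_like(mask), mask.copy()

    dist = ndimage.distance_transform_edt(mask, sampling=params_voxels(vol))
    shell = mask & (dist <= params.skin_peel_mm + 1e-9)

    thr = params.skin_sos_threshold
    if thr is None:
        fcm = fuzzy_c_means(vol.values[mask], k=2, m=params.fcm_m,
                            tol=params.fcm_tol, max_iter=params.fcm_max_iter)
        thr = float(fcm.centers.mean())
    skin = shell & (vol.values > thr)
    interior = mask & ~skin
    if not interior.any():
        raise DegenerateDataError(
            f"skin peel of {params.skin_peel_mm} mm leaves no breast interior"
        )
    return skin, interior


def params_voxels(vol: SoSVolume) -> tuple[float, float, float]:
    """EDT sampling argument: physical voxel spacing in mm."""
    return tuple(float(s) for s in vol.voxel_size)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _mode_filter(
    labels: np.ndarray,
    classes: Sequence[int],
    region: np.ndarray,
    min_support: int = 6,
    iterations: int = 2,
) -> np.ndarray:
    """Salt-and-pepper label cleanup restricted to ``region``.

    A voxel is relabelled to its 26-neighbourhood mode only when fewer
    than ``min_support`` neighbours share its current class.  Keeping the
    inertia condition (rather than always taking the mode) stops the
    filter from eroding the curved surfaces of genuine structures while
    still removing isolated noise-flipped voxels.  Ties break toward the
    slower tissue, deterministically.
    """
    kernel = np.ones((3, 3, 3), dtype=np.float32)
    kernel[1, 1, 1] = 0.0  # the voxel does not vote for itself
    out = labels.copy()
    cls = np.asarray(classes, dtype=labels.dtype)
    for _ in range(iterations):
        counts = np.stack([
            ndimage.convolve(((out == c) & region).astype(np.float32),
                             kernel, mode="constant", cval=0.0)
            for c in classes
        ])
        current = np.zeros(out.shape, dtype=np.intp)
        for j, c in enumerate(classes):
            current[out == c] = j
        own = np.take_along_axis(counts, current[None], axis=0)[0]
        winner = np.argmax(counts, axis=0)
        flip = region & (own < min_support)
        if not flip.any():
            break
        out[flip] = cls[winner[flip]]
    return out


def _split_two(
    values: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, tuple[float, float]] | None:
    """k = 2 FCM split of scalar values.

    Returns ``(upper-class boolean mask, (lower center, upper center))``,
    or ``None`` when the values carry no two-class structure (fewer than
    two distinct values, or centers closer than the configured minimum
    separation) — callers then keep the whole set in one class.
    """
    if np.unique(values).size < 2:
        return None
    fcm = fuzzy_c_means(values, k=2, m=params.fcm_m, tol=params.fcm_tol,
                        max_iter=params.fcm_max_iter)
    lo, hi = float(fcm.centers[0]), float(fcm.centers[1])
    if hi - lo < params.min_center_separation:
        return None
    # for scalar k=2 FCM, max membership is equivalent to nearest center
    return values > 0.5 * (lo + hi), (lo, hi)


def segment_tissues(
    vol: SoSVolume,
    params: SegmentationParams | None = None,
) -> TissueLabelVolume:
    """Run the full three-compartment segmentation on one volume.

    Returns a label volume over {water, skin, fat, gland, duct}.  Voxels
    never lose their bath/skin assignment; the interior is partitioned
    into fat vs. fibroglandular and the fibroglandular compartment into
    gland vs. duct (ducts have the higher speed of sound).  A compartment
    whose values show no two-class structure is left whole (all fat, or
    all gland), so phantoms without fibroglandular tissue segment cleanly.
    """
    params = params or SegmentationParams()
    noise_sd = estimate_noise_sd(vol)
    mask = mask_breast(vol, params, noise_sd=noise_sd)
    skin, interior = peel_skin(mask, vol, params)

    labels = np.full(vol.shape, int(Tissue.WATER), dtype=np.uint8)
    labels[skin] = Tissue.SKIN
    labels[interior] = Tissue.FAT

    interior_vals = vol.values[interior]
    split = _split_two(interior_vals, params)
    if split is not None:
        upper, (c_fat, c_fg) = split
        fg_vals = interior_vals[upper]
        duct_split = None
        if params.duct_split_rule == "threshold":
            duct_sel = fg_vals > params.duct_sos_threshold
            if duct_sel.any() and not duct_sel.all():
                duct_split = (duct_sel,
                              (float(fg_vals[~duct_sel].mean()),
                               float(fg_vals[duct_sel].mean())))
        else:
            duct_split = _split_two(fg_vals, params)

        if duct_split is None:
            interior_class = np.where(upper, int(Tissue.GLAND), int(Tissue.FAT))
        else:
            # Refine with symmetric midpoints: the k=2 fibroglandular
            # center is a gland/duct mixture mean, which would otherwise
            # bias the fat boundary toward the gland distribution.
            _, (c_gland, c_duct) = duct_split
            t_fat = 0.5 * (c_fat + c_gland)
            t_duct = (params.duct_sos_threshold
                      if params.duct_split_rule == "threshold"
                      else 0.5 * (c_gland + c_duct))
            interior_class = np.where(
                interior_vals <= t_fat, int(Tissue.FAT),
                np.where(interior_vals <= t_duct, int(Tissue.GLAND),
                         int(Tissue.DUCT)))
        labels[interior] = interior_class.astype(np.uint8)

    cleanup = params.label_cleanup == "on" or (
        params.label_cleanup == "auto" and noise_sd > params.noise_floor_sd
    )
    if cleanup:
        present = [int(c) for c in (Tissue.FAT, Tissue.GLAND, Tissue.DUCT)
                   if np.any(labels[interior] == c)]
        if len(present) > 1:
            labels = _mode_filter(labels, present, interior)

    return TissueLabelVolume(labels=labels, voxel_size=vol.voxel_size)
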