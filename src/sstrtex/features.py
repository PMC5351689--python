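"""Conventional and textural heterogeneity features for segmented PET lesions.

The texture pipeline follows the classical radiomics chain: SUV values
inside the lesion mask are discretized into ``Ng`` equal-width grey
levels, a grey-level co-occurrence matrix (GLCM; the spatial-dependence
matrix counting how often level *i* neighbours level *j*) and a
grey-level size-zone matrix (GLSZM; counting maximal connected zones of
equal level by size) are accumulated, and scalar features are read off
the normalized matrices.

Feature formulas (p(i,j) the normalized GLCM, Z(j,s) the GLSZM zone
counts, Nz the total zone count):

* entropy            = -sum p log2 p                   (bits)
* homogeneity        = sum p / (1 + |i - j|)           (inverse difference)
* correlation        = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j)
* contrast           = sum (i - j)^2 p
* short_zone_emphasis   = (1/Nz) sum_{j,s} Z(j,s) / s^2
* size_variation        = (1/Nz) sum_s (sum_j Z(j,s))^2   (zone-size non-uniformity)
* grey_level_uniformity = (1/Nz) sum_j (sum_s Z(j,s))^2
* intensity_variation   = grey-level analogue of size_variation
  (identical sum to grey_level_uniformity on a size-zone matrix; both
  are reported for completeness but neither belongs to the default
  8-feature analysis set)

First-order: cov = sigma/mu and skewness = m3/sigma^3 with population
moments.  Conventional: SUVmax, SUVmean, lesion volume (mL) and
TRE = volume_ml * SUVmean (the total-lesion-glycolysis analogue for
receptor imaging).

Lesions whose maximal axis-aligned extent is below ``min_diameter_mm``
(default 15 mm) are excluded to limit partial-volume effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from skimage.measure import label as cc_label

from .errors import DegenerateTextureError, FeatureError
from .io import LesionMask, PetVolume, check_aligned

#: the eight heterogeneity features entering the default analysis set
HETEROGENEITY_FEATURES = (
    "cov",
    "skewness",
    "entropy",
    "homogeneity",
    "correlation",
    "contrast",
    "short_zone_emphasis",
    "size_variation",
)

CONVENTIONAL_FEATURES = ("suv_max", "suv_mean", "volume_ml", "tre")

#: full ordered column set of a feature table
FEATURE_COLUMNS = CONVENTIONAL_FEATURES + HETEROGENEITY_FEATURES + (
    "grey_level_uniformity",
    "intensity_variation",
)

#: the 13 unique nearest-neighbour directions of a 3D grid (up to sign)
OFFSETS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: the 4 unique directions of a 2D grid
OFFSETS_2D = ((1, 0), (0, 1), (1, 1), (1, -1))


@dataclass
class ExtractionConfig:
    """Settings of the per-lesion feature extraction."""

    n_levels: int = 64
    glcm_distance: int = 1
    min_diameter_mm: float = 15.0
    aggregation_mode: str = "per_patient"


@dataclass
class DiscretizedLesion:
    """Integer grey levels (1..Ng) on the grid; 0 marks outside-mask voxels."""

    levels: np.ndarray
    n_levels: int
    bin_edges: np.ndarray


@dataclass
class GLCMatrix:
    p: np.ndarray
    offsets: tuple
    symmetric: bool


@dataclass
class GLSZMatrix:
    Z: np.ndarray  # (Ng, Smax) zone counts
    n_zones: int
    n_voxels: int


@dataclass
class FeatureVector:
    lesion_id: str = "lesion"
    site: str = "other"
    suv_max: float = np.nan
    suv_mean: float = np.nan
    volume_ml: float = np.nan
    tre: float = np.nan
    cov: float = np.nan
    skewness: float = np.nan
    entropy: float = np.nan
    homogeneity: float = np.nan
    correlation: float = np.nan
    contrast: float = np.nan
    short_zone_emphasis: float = np.nan
    size_variation: float = np.nan
    grey_level_uniformity: float = np.nan
    intensity_variation: float = np.nan
    degenerate_flags: tuple[str, ...] = ()
    diameter_mm: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}


@dataclass
class LesionExclusion:
    """Record of a lesion dropped by the size filter."""

    lesion_id: str
    site: str
    reason: str
    diameter_mm: float


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def max_diameter(mask: Union[LesionMask, np.ndarray], spacing_mm: Optional[Sequence[float]] = None) -> float:
    """Maximal axis-aligned extent of the mask in mm.

    For each axis the occupied index span plus one voxel is multiplied by
    the spacing along that axis; the largest of the three extents is the
    diameter.  A single voxel therefore has diameter equal to its largest
    spacing component, and a digitized sphere measures its nominal
    diameter to within one voxel.
    """
    if isinstance(mask, LesionMask):
        arr, spacing = mask.values, mask.spacing_mm
    else:
        arr = np.asarray(mask) == 1
        if spacing_mm is None:
            raise FeatureError("spacing_mm required when passing a bare array")
        spacing = tuple(float(s) for s in spacing_mm)
    if not arr.any():
        raise FeatureError("cannot measure diameter of an empty mask")
    idx = np.nonzero(arr)
    extents = [
        (int(ax.max()) - int(ax.min()) + 1) * s for ax, s in zip(idx, spacing)
    ]
    return float(max(extents))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(
    volume_values: np.ndarray, mask: np.ndarray, n_levels: int = 64
) -> DiscretizedLesion:
    """Equal-width binning of in-mask values into 1..Ng grey levels.

    Bins span [min, max] of the in-mask values; the maximum maps to level
    Ng.  A constant lesion collapses to a single level (Ng = 1).
    """
    if n_levels < 2:
        raise FeatureError(f"n_levels must be >= 2, got {n_levels}")
    mask = np.asarray(mask) == 1
    if not mask.any():
        raise FeatureError("empty mask")
    vals = np.asarray(volume_values, dtype=float)
    inm = vals[mask]
    lo, hi = float(inm.min()), float(inm.max())
    levels = np.zeros(vals.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        return DiscretizedLesion(levels=levels, n_levels=1, bin_edges=np.array([lo, hi]))
    edges = np.linspace(lo, hi, n_levels + 1)
    width = (hi - lo) / n_levels
    lv = np.floor((inm - lo) / width).astype(np.int32) + 1
    np.clip(lv, 1, n_levels, out=lv)
    levels[mask] = lv
    return DiscretizedLesion(levels=levels, n_levels=n_levels, bin_edges=edges)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def default_offsets(ndim: int, distance: int = 1) -> tuple:
    base = OFFSETS_3D if ndim == 3 else OFFSETS_2D
    return tuple(tuple(distance * c for c in off) for off in base)


def compute_glcm(
    d: DiscretizedLesion,
    distance: int = 1,
    offsets: Optional[Sequence[Sequence[int]]] = None,
    symmetric: bool = True,
) -> GLCMatrix:
    """Accumulate level co-occurrences over the grid offsets.

    Counts are summed over all offsets (13 unique 3D directions at the
    given distance by default) into a single matrix; pairs with either
    end outside the mask are ignored; with ``symmetric`` both orderings
    of each pair are counted.  Counts are normalized to probabilities.
    """
    levels = d.levels
    ng = max(d.n_levels, 1)
    if offsets is None:
        offsets = default_offsets(levels.ndim, distance)
    else:
        offsets = tuple(tuple(int(c) for c in off) for off in offsets)
    counts = np.zeros(ng * ng, dtype=np.int64)
    for off in offsets:
        if len(off) != levels.ndim:
            raise FeatureError(f"offset {off} does not match grid dimensionality {levels.ndim}")
        src = [slice(None)] * levels.ndim
        dst = [slice(None)] * levels.ndim
        for ax, o in enumerate(off):
            if o > 0:
                src[ax] = slice(0, levels.shape[ax] - o)
                dst[ax] = slice(o, levels.shape[ax])
            elif o < 0:
                src[ax] = slice(-o, levels.shape[ax])
                dst[ax] = slice(0, levels.shape[ax] + o)
        a = levels[tuple(src)]
        b = levels[tuple(dst)]
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        i = a[valid].astype(np.int64) - 1
        j = b[valid].astype(np.int64) - 1
        counts += np.bincount(i * ng + j, minlength=ng * ng)
        if symmetric:
            counts += np.bincount(j * ng + i, minlength=ng * ng)
    total = counts.sum()
    if total == 0:
        raise DegenerateTextureError(
            "no valid voxel pair under the requested offsets (scattered or single-voxel mask)"
        )
    p = counts.reshape(ng, ng).astype(float) / total
    return GLCMatrix(p=p, offsets=tuple(offsets), symmetric=symmetric)


def glcm_features(m: GLCMatrix) -> tuple[dict[str, float], tuple[str, ...]]:
    """Second-order features of a normalized co-occurrence matrix.

    Returns the feature dict and a tuple of degeneracy flags (correlation
    is reported as 0, flagged, when a marginal standard deviation is 0).
    """
    p = np.asarray(m.p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise FeatureError("co-occurrence matrix is not a normalized probability matrix")
    ng = p.shape[0]
    levels = np.arange(1, ng + 1, dtype=float)
    ii = levels[:, None]
    jj = levels[None, :]
    nonzero = p > 0
    entropy = float(-(p[nonzero] * np.log2(p[nonzero])).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((levels * pi).sum())
    mu_j = float((levels * pj).sum())
    var_i = float(((levels - mu_i) ** 2 * pi).sum())
    var_j = float(((levels - mu_j) ** 2 * pj).sum())
    flags: tuple[str, ...] = ()
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
        flags = ("correlation_degenerate",)
    else:
        correlation = float(
            (((ii - mu_i) * (jj - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return (
        dict(entropy=entropy, homogeneity=homogeneity, correlation=correlation, contrast=contrast),
        flags,
    )


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def compute_glszm(d: DiscretizedLesion) -> GLSZMatrix:
    """Count maximal fully-connected zones of equal grey level by size.

    Zones are 26-connected in 3D (8-connected in 2D).  The matrix
    conserves voxels: sum_s s * Z(j, s) equals the in-mask voxel count.
    """
    levels = d.levels
    in_mask = levels > 0
    if not in_mask.any():
        raise FeatureError("empty mask")
    ng = max(d.n_levels, 1)
    n_voxels = int(in_mask.sum())
    zone_sizes: dict[int, list[int]] = {}
    smax = 1
    for lv in np.unique(levels[in_mask]):
        lab = cc_label(levels == lv, connectivity=levels.ndim)
        sizes = np.bincount(lab.ravel())[1:]  # drop background
        zone_sizes[int(lv)] = sizes.tolist()
        smax = max(smax, int(sizes.max()))
    Z = np.zeros((ng, smax), dtype=np.int64)
    for lv, sizes in zone_sizes.items():
        for s in sizes:
            Z[lv - 1, s - 1] += 1
    return GLSZMatrix(Z=Z, n_zones=int(Z.sum()), n_voxels=n_voxels)


def glszm_features(z: GLSZMatrix) -> dict[str, float]:
    """Higher-order features of a size-zone matrix."""
    if z.n_zones < 1:
        raise FeatureError("size-zone matrix has no zones")
    Z = z.Z.astype(float)
    nz = float(z.n_zones)
    sizes = np.arange(1, Z.shape[1] + 1, dtype=float)
    by_size = Z.sum(axis=0)
    by_level = Z.sum(axis=1)
    return dict(
        short_zone_emphasis=float((Z / sizes[None, :] ** 2).sum() / nz),
        size_variation=float((by_size**2).sum() / nz),
        grey_level_uniformity=float((by_level**2).sum() / nz),
        intensity_variation=float((by_level**2).sum() / nz),
    )


# ---------------------------------------------------------------------------
# first-order and conventional
# ---------------------------------------------------------------------------

def first_order_features(values: Sequence[float]) -> tuple[dict[str, float], tuple[str, ...]]:
    """Coefficient of variation and skewness from population moments."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise FeatureError("need at least one value")
    mu = float(v.mean())
    sigma2 = float(((v - mu) ** 2).mean())
    if sigma2 == 0.0:
        return dict(cov=0.0, skewness=0.0), ("first_order_degenerate",)
    if mu == 0.0:
        raise FeatureError("coefficient of variation undefined for zero mean")
    sigma = np.sqrt(sigma2)
    m3 = float(((v - mu) ** 3).mean())
    return dict(cov=sigma / mu, skewness=m3 / sigma**3), ()


def conventional_features(
    values: Sequence[float], mask: np.ndarray, spacing_mm: Sequence[float]
) -> dict[str, float]:
    """SUVmax, SUVmean, lesion volume (mL) and TRE = volume * SUVmean."""
    v = np.asarray(values, dtype=float)
    mask = np.asarray(mask) == 1
    n = int(mask.sum())
    if n == 0:
        raise FeatureError("empty mask")
    if v.size != n:  # allow passing either in-mask values or the full grid
        v = v[mask]
    voxel_ml = float(np.prod([float(s) for s in spacing_mm])) / 1000.0
    volume_ml = n * voxel_ml
    suv_mean = float(v.mean())
    return dict(
        suv_max=float(v.max()),
        suv_mean=suv_mean,
        volume_ml=volume_ml,
        tre=volume_ml * suv_mean,
    )


# ---------------------------------------------------------------------------
# extraction and aggregation
# ---------------------------------------------------------------------------

def extract_lesion(
    volume: PetVolume, mask: LesionMask, config: Optional[ExtractionConfig] = None
) -> Union[FeatureVector, LesionExclusion]:
    """Run the full per-lesion feature chain, or exclude by the size filter."""
    config = config or ExtractionConfig()
    if not volume.is_suv:
        raise FeatureError("extract_lesion expects an SUV volume; call to_suv first")
    check_aligned(volume, mask)
    diameter = max_diameter(mask)
    if diameter < config.min_diameter_mm:
        return LesionExclusion(
            lesion_id=mask.lesion_id,
            site=mask.site,
            reason="below size threshold",
            diameter_mm=diameter,
        )
    inm = volume.values[mask.values]
    conv = conventional_features(inm, mask.values, volume.spacing_mm)
    first, flags1 = first_order_features(inm)
    d = discretize(volume.values, mask.values, config.n_levels)
    if d.n_levels == 1:
        # constant lesion: texture at its analytic limits
        glcm_vals = dict(entropy=0.0, homogeneity=1.0, correlation=0.0, contrast=0.0)
        flags2: tuple[str, ...] = ("correlation_degenerate",)
    else:
        glcm = compute_glcm(d, distance=config.glcm_distance)
        glcm_vals, flags2 = glcm_features(glcm)
    szm_vals = glszm_features(compute_glszm(d))
    return FeatureVector(
        lesion_id=mask.lesion_id,
        site=mask.site,
        **conv,
        **first,
        **glcm_vals,
        **szm_vals,
        degenerate_flags=flags1 + flags2,
        diameter_mm=diameter,
    )


def aggregate(
    vectors: Sequence[FeatureVector], mode: str = "per_patient"
) -> FeatureVector:
    """Aggregate included lesion vectors to one patient-level vector.

    ``per_patient``: arithmetic mean of every feature over all lesions.
    ``per_system``: keep the largest lesion (by volume) per site class,
    then mean over the kept lesions.
    """
    vectors = [v for v in vectors if isinstance(v, FeatureVector)]
    if not vectors:
        raise FeatureError("patient has no included lesions; unanalyzable")
    if mode == "per_patient":
        kept = list(vectors)
    elif mode == "per_system":
        by_site: dict[str, FeatureVector] = {}
        for v in vectors:
            if v.site not in by_site or v.volume_ml > by_site[v.site].volume_ml:
                by_site[v.site] = v
        kept = list(by_site.values())
    else:
        raise FeatureError(f"unknown aggregation mode {mode!r}")
    out = FeatureVector(lesion_id=f"aggregate[{mode}]", site="aggregate")
    for name in FEATURE_COLUMNS:
        setattr(out, name, float(np.mean([getattr(v, name) for v in kept])))
    flags = tuple(sorted({f for v in kept for f in v.degenerate_flags}))
    out.degenerate_flags = flags
    return out
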