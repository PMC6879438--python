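"""First-order SUV statistics and 3-D grey-level co-occurrence texture features.

The texture pipeline is: fixed-bin-number quantization of the masked SUV
range into G grey levels, co-occurrence counting at interpixel distance 1
along the 13 unique 3-D neighbour directions (unique up to sign among the 26
neighbours of a voxel), symmetrization, and per-direction evaluation of the
16 classical co-occurrence features (Entropy, Homogeneity, Contrast,
Correlation, Angular second moment, Difference entropy, Difference variance,
Inverse difference moment, Sum average, Sum entropy, Sum variance, Cluster
prominence, Cluster shade, Maximum probability and the two informational
measures of correlation), arithmetically averaged over the directions with
at least ``min_pairs`` voxel pairs (default 20).

All entropies use log base 2 by default; zero-probability cells are omitted
from entropy sums (the exact p->0 limit) rather than guarded with an
additive epsilon.  Direction offsets live in voxel-index space; the physical
anisotropy of the grid is deliberately ignored, as is conventional in
co-occurrence radiomics.

Absolute Entropy values depend on the bin count G (default 64) and on the
log base; cut-offs such as 3.5 are only meaningful for the configuration
they were derived under.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from .volumes import PETVolume, TMTVMask

__all__ = [
    "DIRECTIONS_13",
    "TEXTURE_FEATURE_NAMES",
    "FIRST_ORDER_NAMES",
    "FirstOrderFeatures",
    "QuantizedVolume",
    "GLCMSet",
    "TextureFeatures",
    "first_order",
    "quantize",
    "glcm_3d",
    "texture_features",
    "extract_all",
]

#: The 13 unique 3-D neighbour offsets up to sign.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0),
    (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

TEXTURE_FEATURE_NAMES = (
    "entropy",
    "homogeneity",
    "contrast",
    "correlation",
    "angular_second_moment",
    "difference_entropy",
    "difference_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "cluster_prominence",
    "cluster_shade",
    "maximum_probability",
    "imc1",
    "imc2",
)

FIRST_ORDER_NAMES = ("suv_max", "suv_mean", "suv_peak", "tmtv_ml", "tlg")


@dataclass
class FirstOrderFeatures:
    """SUVmax / SUVmean / SUVpeak, TMTV (mL) and TLG (= TMTV x SUVmean)."""

    suv_max: float
    suv_mean: float
    suv_peak: float
    tmtv_ml: float
    tlg: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FIRST_ORDER_NAMES}


@dataclass
class QuantizedVolume:
    """Integer grey levels 1..G on masked voxels; 0 marks unmasked voxels."""

    levels: np.ndarray
    n_bins: int
    mask: np.ndarray
    rule: str = "fixed-bin-number"


@dataclass
class GLCMSet:
    """Symmetrized co-occurrence count matrices for the 13 directions.

    ``pair_counts[d]`` is the number of ordered voxel pairs found for
    direction ``d`` before symmetrization; a direction is valid when it has
    at least ``min_pairs`` such pairs.
    """

    matrices: np.ndarray          # (13, G, G) symmetrized counts
    pair_counts: np.ndarray       # (13,) unsymmetrized ordered-pair counts
    n_bins: int
    distance: int = 1
    directions: tuple = DIRECTIONS_13

    def valid(self, min_pairs: int = 20) -> np.ndarray:
        return self.pair_counts >= min_pairs


@dataclass
class TextureFeatures:
    entropy: float
    homogeneity: float
    contrast: float
    correlation: float
    angular_second_moment: float
    difference_entropy: float
    difference_variance: float
    inverse_difference_moment: float
    sum_average: float
    sum_entropy: float
    sum_variance: float
    cluster_prominence: float
    cluster_shade: float
    maximum_probability: float
    imc1: float
    imc2: float
    n_valid_directions: int = field(default=13, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TEXTURE_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def _peak_sphere_offsets(spacing_mm, volume_ml: float = 1.0) -> np.ndarray:
    """Voxel offsets whose centres lie within a sphere of the given volume."""
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    reach = [int(math.floor(radius / s)) for s in spacing_mm]
    offsets = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                d = math.sqrt(
                    (dx * spacing_mm[0]) ** 2
                    + (dy * spacing_mm[1]) ** 2
                    + (dz * spacing_mm[2]) ** 2
                )
                if d <= radius:
                    offsets.append((dx, dy, dz))
    return np.array(offsets, dtype=int)


def suv_peak(volume: PETVolume, mask: np.ndarray, sphere_ml: float = 1.0) -> float:
    """Max over masked voxels of the mean SUV in a 1 mL sphere, clipped to the grid.

    The sphere is the set of voxels whose centres lie within the radius of a
    sphere of ``sphere_ml`` millilitres; at the grid edge the mean is taken
    over the in-grid part of the sphere only.
    """
    offsets = _peak_sphere_offsets(volume.spacing_mm, sphere_ml)
    grid = volume.grid
    coords = np.argwhere(mask)
    best = -np.inf
    shape = np.array(grid.shape)
    for c in coords:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        val = grid[pts[:, 0], pts[:, 1], pts[:, 2]].mean()
        if val > best:
            best = val
    return float(best)


def first_order(volume: PETVolume, mask: TMTVMask | np.ndarray) -> FirstOrderFeatures:
    """First-order SUV features over a TMTV; TLG is exactly TMTV x SUVmean."""
    m = mask.mask if isinstance(mask, TMTVMask) else np.asarray(mask, dtype=bool)
    if m.shape != volume.grid.shape:
        raise ValueError("mask shape does not match volume shape")
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.grid[m]
    tmtv_ml = float(m.sum()) * volume.voxel_volume_ml
    mean = float(vals.mean())
    return FirstOrderFeatures(
        suv_max=float(vals.max()),
        suv_mean=mean,
        suv_peak=suv_peak(volume, m),
        tmtv_ml=tmtv_ml,
        tlg=tmtv_ml * mean,
    )


# ---------------------------------------------------------------------------
# quantization and co-occurrence
# ---------------------------------------------------------------------------

def quantize(volume: PETVolume, mask: TMTVMask | np.ndarray, n_bins: int = 64) -> QuantizedVolume:
    """Fixed-bin-number discretization of the masked SUV range into 1..G.

    ``level = min(G, floor(G * (x - min) / (max - min)) + 1)``; a constant
    region maps every voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    m = mask.mask if isinstance(mask, TMTVMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.grid[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.grid.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor(n_bins * (volume.grid[m] - lo) / (hi - lo)).astype(np.int32) + 1
        np.minimum(lv, n_bins, out=lv)
        levels[m] = lv
    else:
        levels[m] = 1
    return QuantizedVolume(levels=levels, n_bins=n_bins, mask=m)


def glcm_3d(q: QuantizedVolume, distance: int = 1) -> GLCMSet:
    """Symmetrized co-occurrence counts at the given interpixel distance.

    For each direction, ordered pairs of in-mask voxels separated by
    ``distance * offset`` are counted and the count matrix is symmetrized by
    adding its transpose.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    G = q.n_bins
    lv = q.levels
    mask = q.mask
    mats = np.zeros((len(DIRECTIONS_13), G, G), dtype=np.int64)
    pair_counts = np.zeros(len(DIRECTIONS_13), dtype=np.int64)
    shape = lv.shape
    for d, off in enumerate(DIRECTIONS_13):
        off = tuple(o * distance for o in off)
        # slice pairs (a, a+off) staying inside the grid
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        both = mask[src] & mask[dst]
        i = lv[src][both] - 1
        j = lv[dst][both] - 1
        if i.size:
            counts = np.zeros((G, G), dtype=np.int64)
            np.add.at(counts, (i, j), 1)
            mats[d] = counts + counts.T
            pair_counts[d] = i.size
    return GLCMSet(matrices=mats, pair_counts=pair_counts, n_bins=G, distance=distance)


# ---------------------------------------------------------------------------
# texture features
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray, base: float) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos]) / np.log(base)
    return out


def features_from_matrix(p: np.ndarray, log_base: float = 2.0) -> dict[str, float]:
    """The 16 co-occurrence features of one normalized symmetric matrix.

    ``p`` must sum to 1.  Degenerate cases: when a marginal variance is zero
    (single occupied grey level) Correlation is defined as 1 and both
    informational measures of correlation as 0.
    """
    G = p.shape[0]
    i = np.arange(1, G + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = math.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sig_y = math.sqrt(float(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2G and p_{x-y}(k), k = 0..G-1
    ks_sum = np.arange(2, 2 * G + 1, dtype=float)
    p_sum = np.zeros(2 * G - 1)
    ks_diff = np.arange(0, G, dtype=float)
    p_diff = np.zeros(G)
    for a in range(G):
        for b in range(G):
            p_sum[a + b] += p[a, b]
            p_diff[abs(a - b)] += p[a, b]

    entropy = float(-_xlog2(p, log_base).sum())
    homogeneity = float((p / (1.0 + np.abs(ii - jj))).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sig_x > 0 and sig_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0
    asm = float((p ** 2).sum())
    diff_entropy = float(-_xlog2(p_diff, log_base).sum())
    da = float((ks_diff * p_diff).sum())
    diff_variance = float(((ks_diff - da) ** 2 * p_diff).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((ks_sum * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum, log_base).sum())
    sum_variance = float(((ks_sum - sum_average) ** 2 * p_sum).sum())
    cluster = ii + jj - mu_x - mu_y
    cluster_prominence = float((cluster ** 4 * p).sum())
    cluster_shade = float((cluster ** 3 * p).sum())
    max_prob = float(p.max())

    hx = float(-_xlog2(px, log_base).sum())
    hy = float(-_xlog2(py, log_base).sum())
    hxy = entropy
    outer = np.outer(px, py)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log(outer[pos]) / np.log(log_base)).sum())
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log(outer[pos2]) / np.log(log_base)).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
    imc2 = math.sqrt(max(arg, 0.0))

    return {
        "entropy": entropy,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
        "angular_second_moment": asm,
        "difference_entropy": diff_entropy,
        "difference_variance": diff_variance,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "maximum_probability": max_prob,
        "imc1": imc1,
        "imc2": imc2,
    }


def texture_features(
    glcms: GLCMSet, min_pairs: int = 20, log_base: float = 2.0
) -> TextureFeatures:
    """Per-direction features averaged over directions with enough pairs.

    Directions with fewer than ``min_pairs`` voxel pairs are excluded from
    the arithmetic mean; with no valid direction at all the matrix is
    unusable and an error is raised.
    """
    valid = glcms.valid(min_pairs)
    if not valid.any():
        raise ValueError(
            f"no direction has the minimum of {min_pairs} voxel pairs; "
            "the region is too small for co-occurrence texture analysis"
        )
    per_dir = []
    for d in np.flatnonzero(valid):
        mat = glcms.matrices[d].astype(float)
        per_dir.append(features_from_matrix(mat / mat.sum(), log_base))
    averaged = {
        name: float(np.mean([f[name] for f in per_dir])) for name in TEXTURE_FEATURE_NAMES
    }
    return TextureFeatures(**averaged, n_valid_directions=int(valid.sum()))


def extract_all(
    volume: PETVolume,
    mask: TMTVMask | np.ndarray,
    n_bins: int = 64,
    distance: int = 1,
    min_pairs: int = 20,
    log_base: float = 2.0,
) -> dict[str, float]:
    """First-order + texture feature vector for one patient (one dict row)."""
    fo = first_order(volume, mask)
    q = quantize(volume, mask, n_bins)
    glcms = glcm_3d(q, distance)
    tex = texture_features(glcms, min_pairs, log_base)
    row = fo.as_dict()
    row.update(tex.as_dict())
    return row
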