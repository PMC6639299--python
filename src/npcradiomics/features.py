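"""The 208-feature radiomics roster.

For every (image, ROI mask) pair the extractor emits, in a fixed order,

* 10 intensity-histogram features            ``HIST.<name>``
* 22 gray-level co-occurrence features       ``GLCM.<name>``
*  9 gray-level run-length features          ``GLRLM.<name>``
* 164 wavelet features: the 41 histogram/GLCM/GLRLM features recomputed on
  each of the four sub-bands of a single-level slice-wise 2-D discrete
  wavelet transform                          ``<LL|LH|HL|HH>_<FAMILY>.<name>``
*  3 fractal features                        ``FRAC.<name>``

Texture matrices pool the four in-plane unit-distance directions (0, 45, 90,
135 degrees) across all slices; through-plane offsets are excluded because
transversal MRI slice spacing is anisotropic.  Gray levels are quantized to
32 equal-width bins over the ROI min-max range, recomputed per sub-band.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
import pywt

from .imaging_io import EmptyROIError, ImageVolume, ROIMask

# In-plane unit-distance offsets (row, col): 0, 45, 90, 135 degrees.
INPLANE_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

HIST_NAMES = ["mean", "median", "min", "max", "range", "variance",
              "skewness", "kurtosis", "energy", "entropy"]
GLCM_NAMES = [
    # Haralick's fourteen
    "angular_second_moment", "contrast", "correlation",
    "sum_of_squares_variance", "inverse_difference_moment", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "information_Measure_I", "information_Measure_II",
    "maximal_correlation_coefficient",
    # eight standard additions
    "autocorrelation", "cluster_shade", "cluster_prominence", "dissimilarity",
    "homogeneity2", "maximum_probability", "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
]
GLRLM_NAMES = ["SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
               "SRLGE", "SRHGE"]
FRAC_NAMES = ["box_counting_dimension", "intensity_fractal_dimension",
              "lacunarity"]
SUBBANDS = ["LL", "LH", "HL", "HH"]
WAVELET = "coif1"


def feature_roster() -> list[str]:
    """The fixed, ordered list of all 208 feature names."""
    names = [f"HIST.{n}" for n in HIST_NAMES]
    names += [f"GLCM.{n}" for n in GLCM_NAMES]
    names += [f"GLRLM.{n}" for n in GLRLM_NAMES]
    for band in SUBBANDS:
        names += [f"{band}_HIST.{n}" for n in HIST_NAMES]
        names += [f"{band}_GLCM.{n}" for n in GLCM_NAMES]
        names += [f"{band}_GLRLM.{n}" for n in GLRLM_NAMES]
    names += [f"FRAC.{n}" for n in FRAC_NAMES]
    assert len(names) == 208
    return names


FEATURE_ROSTER = feature_roster()


@dataclass(frozen=True)
class QuantizationSpec:
    """Equal-width gray-level quantization over the ROI min-max range."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


DEFAULT_QUANTIZATION = QuantizationSpec()


@dataclass
class GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix.

    ``p[i, j]`` is the joint probability of quantized levels ``i+1`` and
    ``j+1`` co-occurring at unit distance (pooled over directions).
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("GLCM entries must be >= 0 and sum to 1")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        self.p = p

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize_roi(volume: ImageVolume | np.ndarray, mask: ROIMask | np.ndarray,
                 spec: QuantizationSpec = DEFAULT_QUANTIZATION) -> np.ndarray:
    """Map ROI intensities to levels 1..Ng; voxels outside the mask get 0.

    Bins are equal-width over [roi_min, roi_max].  A constant ROI maps every
    voxel to level 1.
    """
    vox = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    msk = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask)
    msk = msk.astype(bool)
    if not msk.any():
        raise EmptyROIError("cannot quantize an empty ROI")
    values = vox[msk]
    lo, hi = float(values.min()), float(values.max())
    out = np.zeros(vox.shape, dtype=np.int32)
    if hi == lo:
        out[msk] = 1
        return out
    ng = spec.n_levels
    levels = np.floor((values - lo) / (hi - lo) * ng).astype(np.int32) + 1
    np.clip(levels, 1, ng, out=levels)
    out[msk] = levels
    return out


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

def histogram_features(volume: ImageVolume | np.ndarray,
                       mask: ROIMask | np.ndarray,
                       spec: QuantizationSpec = DEFAULT_QUANTIZATION,
                       ) -> "OrderedDict[str, float]":
    """Ten first-order statistics of the ROI intensity distribution.

    Moments are population moments; kurtosis is the non-excess m4/m2^2.
    Energy and entropy are computed on the quantized gray-level histogram.
    A constant ROI yields variance 0, skewness 0, kurtosis 0, entropy 0 and
    energy 1 by convention.
    """
    vox = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    msk = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask)
    msk = msk.astype(bool)
    if not msk.any():
        raise EmptyROIError("histogram features need a nonempty ROI")
    x = vox[msk].astype(float)
    mean = float(x.mean())
    centered = x - mean
    m2 = float(np.mean(centered ** 2))
    if m2 > 0:
        skew = float(np.mean(centered ** 3)) / m2 ** 1.5
        kurt = float(np.mean(centered ** 4)) / m2 ** 2
    else:
        skew = 0.0
        kurt = 0.0
    q = quantize_roi(vox, msk, spec)
    counts = np.bincount(q[msk], minlength=spec.n_levels + 1)[1:]
    p = counts[counts > 0] / counts.sum()
    energy = float(np.sum(p ** 2))
    entropy = float(-np.sum(p * np.log2(p)))
    return OrderedDict([
        ("mean", mean),
        ("median", float(np.median(x))),
        ("min", float(x.min())),
        ("max", float(x.max())),
        ("range", float(x.max() - x.min())),
        ("variance", m2),
        ("skewness", skew),
        ("kurtosis", kurt),
        ("energy", energy),
        ("entropy", entropy),
    ])


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm(volume: ImageVolume | np.ndarray, mask: ROIMask | np.ndarray,
         spec: QuantizationSpec = DEFAULT_QUANTIZATION) -> GLCMatrix:
    """Pooled, symmetrized, normalized co-occurrence matrix.

    Pairs are counted slice-wise along the four in-plane unit-distance
    directions; both voxels of a pair must lie inside the mask.  Both
    orderings of each pair are accumulated, so the matrix is symmetric.
    """
    q = quantize_roi(volume, mask, spec)
    ng = spec.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for dr, dc in INPLANE_DIRECTIONS:
        a, b = _shifted_pairs(q, dr, dc)
        valid = (a > 0) & (b > 0)
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pair for GLCM")
    return GLCMatrix(counts / total)


def _shifted_pairs(q: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantized values at paired positions offset by (dr, dc) in-plane."""
    rs = slice(max(dr, 0), q.shape[1] + min(dr, 0))
    cs = slice(max(dc, 0), q.shape[2] + min(dc, 0))
    rs2 = slice(max(-dr, 0), q.shape[1] + min(-dr, 0))
    cs2 = slice(max(-dc, 0), q.shape[2] + min(-dc, 0))
    return q[:, rs, cs].ravel(), q[:, rs2, cs2].ravel()


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(g: GLCMatrix) -> "OrderedDict[str, float]":
    """The 14 Haralick features plus 8 standard additions (22 total)."""
    p = g.p
    ng = g.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    sums = (ii + jj).astype(int)
    diffs = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(sums.ravel(), weights=p.ravel(),
                        minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(diffs.ravel(), weights=p.ravel(), minlength=ng)[:ng]
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    hxy = float(-np.sum(_xlog2(p)))
    pxy = np.outer(px, py)
    hxy1 = float(-np.sum(np.where(pxy > 0, p * np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)))
    hxy2 = float(-np.sum(_xlog2(pxy)))
    hx = float(-np.sum(_xlog2(px)))
    hy = float(-np.sum(_xlog2(py)))

    asm = float(np.sum(p ** 2))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if var_x > 0 and var_y > 0:
        correlation = float((np.sum(ii * jj * p) - mu_x * mu_y)
                            / math.sqrt(var_x * var_y))
    else:
        correlation = 0.0
    sos_variance = float(np.sum((ii - mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    sum_avg = float(np.sum(k_sum * p_sum))
    sum_var = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    sum_ent = float(-np.sum(_xlog2(p_sum)))
    diff_avg = float(np.sum(k_diff * p_diff))
    diff_var = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    diff_ent = float(-np.sum(_xlog2(p_diff)))
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
    imc2 = math.sqrt(arg) if arg > 0 else 0.0
    mcc = _maximal_correlation_coefficient(p, px, py)

    autocorr = float(np.sum(ii * jj * p))
    shade = float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p))
    prominence = float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p))
    dissim = float(np.sum(np.abs(ii - jj) * p))
    homog2 = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    maxprob = float(p.max())
    idn = float(np.sum(p / (1.0 + np.abs(ii - jj) / ng)))
    idmn = float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng ** 2)))

    return OrderedDict([
        ("angular_second_moment", asm),
        ("contrast", contrast),
        ("correlation", correlation),
        ("sum_of_squares_variance", sos_variance),
        ("inverse_difference_moment", idm),
        ("sum_average", sum_avg),
        ("sum_variance", sum_var),
        ("sum_entropy", sum_ent),
        ("entropy", hxy),
        ("difference_variance", diff_var),
        ("difference_entropy", diff_ent),
        ("information_Measure_I", imc1),
        ("information_Measure_II", imc2),
        ("maximal_correlation_coefficient", mcc),
        ("autocorrelation", autocorr),
        ("cluster_shade", shade),
        ("cluster_prominence", prominence),
        ("dissimilarity", dissim),
        ("homogeneity2", homog2),
        ("maximum_probability", maxprob),
        ("inverse_difference_normalized", idn),
        ("inverse_difference_moment_normalized", idmn),
    ])


def _maximal_correlation_coefficient(p: np.ndarray, px: np.ndarray,
                                     py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Haralick's Q matrix.

    Restricted to gray levels with positive marginal mass; degenerate
    matrices (< 2 occupied levels) return 0 by convention.
    """
    active = px > 0
    if active.sum() < 2:
        return 0.0
    pa = p[np.ix_(active, active)]
    pxa = px[active]
    pya = py[active]
    q = (pa / pxa[:, None]) @ (pa / pya[:, None]).T
    eigs = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
    second = max(float(eigs[1]), 0.0)
    return math.sqrt(min(second, 1.0))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm(volume: ImageVolume | np.ndarray, mask: ROIMask | np.ndarray,
          spec: QuantizationSpec = DEFAULT_QUANTIZATION,
          directions: tuple[tuple[int, int], ...] = INPLANE_DIRECTIONS,
          ) -> np.ndarray:
    """Run-length matrix R[g-1, l-1] pooled over in-plane directions.

    Runs are maximal collinear sequences of equal quantized level; an
    out-of-mask voxel breaks the run.
    """
    q = quantize_roi(volume, mask, spec)
    ng = spec.n_levels
    max_len = max(q.shape[1], q.shape[2])
    counts = np.zeros((ng, max_len), dtype=np.int64)
    for direction in directions:
        for line in _scan_lines(q, direction):
            _accumulate_runs(line, counts)
    return counts


def _scan_lines(q: np.ndarray, direction: tuple[int, int]):
    """Yield 1-D arrays of quantized values along a given in-plane direction."""
    dr, dc = direction
    n_slices, n_rows, n_cols = q.shape
    for s in range(n_slices):
        plane = q[s]
        if (dr, dc) == (0, 1):
            yield from plane
        elif (dr, dc) == (-1, 0):
            yield from plane.T
        elif (dr, dc) == (-1, 1):
            # anti-diagonals, traversed bottom-left to top-right
            flipped = plane[::-1]
            for off in range(-(n_rows - 1), n_cols):
                yield np.diagonal(flipped, offset=off)
        else:  # (-1, -1): main diagonals of the up-flipped plane reversed
            for off in range(-(n_rows - 1), n_cols):
                yield np.diagonal(plane, offset=off)


def _accumulate_runs(line: np.ndarray, counts: np.ndarray) -> None:
    if line.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [line.size]))
    for s, e in zip(starts, ends):
        g = line[s]
        if g > 0:  # level 0 = outside mask, breaks runs and is not counted
            counts[g - 1, e - s - 1] += 1


def glrlm_features(volume: ImageVolume | np.ndarray,
                   mask: ROIMask | np.ndarray,
                   spec: QuantizationSpec = DEFAULT_QUANTIZATION,
                   directions: tuple[tuple[int, int], ...] = INPLANE_DIRECTIONS,
                   ) -> "OrderedDict[str, float]":
    """Nine run-length statistics of the pooled run-length matrix."""
    r = glrlm(volume, mask, spec, directions).astype(float)
    nr = r.sum()
    if nr == 0:
        raise EmptyROIError("empty run-length matrix")
    g = np.arange(1, r.shape[0] + 1, dtype=float)[:, None]
    length = np.arange(1, r.shape[1] + 1, dtype=float)[None, :]
    n_scanned = float(np.sum(r * length))  # total voxel-passes over all lines
    return OrderedDict([
        ("SRE", float(np.sum(r / length ** 2)) / nr),
        ("LRE", float(np.sum(r * length ** 2)) / nr),
        ("GLN", float(np.sum(r.sum(axis=1) ** 2)) / nr),
        ("RLN", float(np.sum(r.sum(axis=0) ** 2)) / nr),
        ("RP", nr / n_scanned),
        ("LGRE", float(np.sum(r / g ** 2)) / nr),
        ("HGRE", float(np.sum(r * g ** 2)) / nr),
        ("SRLGE", float(np.sum(r / (g ** 2 * length ** 2))) / nr),
        ("SRHGE", float(np.sum(r * g ** 2 / length ** 2)) / nr),
    ])


# ---------------------------------------------------------------------------
# Wavelet sub-bands
# ---------------------------------------------------------------------------

def wavelet_subbands(volume: ImageVolume | np.ndarray,
                     mask: ROIMask | np.ndarray,
                     ) -> "OrderedDict[str, tuple[np.ndarray, np.ndarray]]":
    """Single-level slice-wise 2-D DWT of the full image (Coiflet-1).

    Returns the four sub-band (volume, mask) pairs LL, LH, HL, HH.  The mask
    is downsampled to the sub-band grid: a sub-band voxel is foreground iff
    any of its parent voxels is foreground.  Periodized boundary handling
    keeps the transform orthonormal, so per-slice energy is conserved for
    even-sized slices.
    """
    vox = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    msk = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask)
    msk = msk.astype(bool)
    if vox.shape[1] < 2 or vox.shape[2] < 2:
        raise ValueError("each in-plane dimension must be >= 2")
    n_slices = vox.shape[0]
    bands: dict[str, list[np.ndarray]] = {b: [] for b in SUBBANDS}
    for s in range(n_slices):
        ca, (ch, cv, cd) = pywt.dwt2(vox[s], WAVELET, mode="periodization")
        bands["LL"].append(ca)
        bands["LH"].append(ch)
        bands["HL"].append(cv)
        bands["HH"].append(cd)
    sub_shape = bands["LL"][0].shape
    sub_mask = _downsample_mask(msk, sub_shape)
    if not sub_mask.any():
        raise EmptyROIError("sub-band mask is empty")
    out: "OrderedDict[str, tuple[np.ndarray, np.ndarray]]" = OrderedDict()
    for b in SUBBANDS:
        out[b] = (np.stack(bands[b]), sub_mask)
    return out


def _downsample_mask(mask: np.ndarray, sub_shape: tuple[int, int]) -> np.ndarray:
    n_slices, n_rows, n_cols = mask.shape
    pad_r = 2 * sub_shape[0] - n_rows
    pad_c = 2 * sub_shape[1] - n_cols
    padded = np.pad(mask, ((0, 0), (0, max(pad_r, 0)), (0, max(pad_c, 0))))
    blocks = padded[:, :2 * sub_shape[0], :2 * sub_shape[1]].reshape(
        n_slices, sub_shape[0], 2, sub_shape[1], 2)
    return blocks.any(axis=(2, 4)).astype(np.uint8)


# ---------------------------------------------------------------------------
# Fractal features
# ---------------------------------------------------------------------------

def fractal_features(volume: ImageVolume | np.ndarray,
                     mask: ROIMask | np.ndarray,
                     spec: QuantizationSpec = DEFAULT_QUANTIZATION,
                     ) -> "OrderedDict[str, float]":
    """Box-counting dimension, intensity (differential box-counting)
    dimension and gliding-box lacunarity (box size 3) of the ROI."""
    vox = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, float)
    msk = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask)
    msk = msk.astype(bool)
    if not msk.any():
        raise EmptyROIError("fractal features need a nonempty ROI")
    return OrderedDict([
        ("box_counting_dimension", _box_counting_dimension(msk)),
        ("intensity_fractal_dimension",
         _differential_box_counting(vox, msk, spec)),
        ("lacunarity", _lacunarity(vox, msk, box=3)),
    ])


def _bounding_box(mask: np.ndarray) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _box_counting_dimension(mask: np.ndarray) -> float:
    """Slope of log N(s) vs log(1/s) over dyadic 3-D box sizes."""
    sub = mask[_bounding_box(mask)]
    max_extent = max(sub.shape)
    scales = []
    s = 1
    while s <= max_extent / 2:
        scales.append(s)
        s *= 2
    if len(scales) < 2:
        raise ValueError("mask too small for box counting (needs >= 2 scales)")
    log_n, log_inv_s = [], []
    for s in scales:
        shape = tuple(-(-d // s) for d in sub.shape)
        padded = np.zeros(tuple(c * s for c in shape), dtype=bool)
        padded[:sub.shape[0], :sub.shape[1], :sub.shape[2]] = sub
        blocks = padded.reshape(shape[0], s, shape[1], s, shape[2], s)
        n_boxes = int(blocks.any(axis=(1, 3, 5)).sum())
        log_n.append(math.log(n_boxes))
        log_inv_s.append(math.log(1.0 / s))
    slope = np.polyfit(log_inv_s, log_n, 1)[0]
    return float(slope)


def _differential_box_counting(vox: np.ndarray, mask: np.ndarray,
                               spec: QuantizationSpec) -> float:
    """Sarkar-Chaudhuri differential box counting on the quantized intensity
    surface, applied slice-wise within the ROI bounding box and pooled."""
    q = quantize_roi(vox, mask, spec).astype(float)
    bb = _bounding_box(mask)
    q = q[bb]
    m = mask[bb]
    side = max(q.shape[1], q.shape[2])
    ng = spec.n_levels
    scales = []
    s = 2
    while s <= side / 2:
        scales.append(s)
        s *= 2
    if len(scales) < 2:
        # small ROI fallbacks: non-dyadic, then unit-scale anchored
        if side >= 6:
            scales = [2, 3]
        elif side >= 4:
            scales = [1, 2]
        else:
            raise ValueError("ROI too small for differential box counting")
    log_n, log_inv_s = [], []
    for s in scales:
        h = max(s * ng / side, 1e-12)  # box height in gray-level units
        total = 0
        for z in range(q.shape[0]):
            plane, pm = q[z], m[z]
            for r0 in range(0, plane.shape[0], s):
                for c0 in range(0, plane.shape[1], s):
                    cell_m = pm[r0:r0 + s, c0:c0 + s]
                    if not cell_m.any():
                        continue
                    vals = plane[r0:r0 + s, c0:c0 + s][cell_m]
                    total += int(vals.max() // h) - int(vals.min() // h) + 1
        log_n.append(math.log(max(total, 1)))
        log_inv_s.append(math.log(1.0 / s))
    slope = np.polyfit(log_inv_s, log_n, 1)[0]
    return float(slope)


def _lacunarity(vox: np.ndarray, mask: np.ndarray, box: int = 3) -> float:
    """Gliding-box lacunarity var/mean^2 + 1 of box mass (sum of in-mask
    intensities over fully in-mask boxes); 1 for a constant field."""
    bb = _bounding_box(mask)
    v = vox[bb]
    m = mask[bb].astype(float)
    if min(v.shape) < box:
        raise ValueError(f"ROI smaller than gliding box size {box}")
    from scipy.ndimage import uniform_filter
    vol = box ** 3
    mass = uniform_filter(v * m, size=box, mode="constant") * vol
    cover = uniform_filter(m, size=box, mode="constant") * vol
    full = cover > vol - 0.5  # boxes entirely inside the mask
    if not full.any():
        full = cover > 0.5  # fall back to any-coverage boxes
    masses = mass[full]
    mean = masses.mean()
    if mean == 0:
        return 1.0
    return float(masses.var() / mean ** 2 + 1.0)


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_all(volume: ImageVolume | np.ndarray, mask: ROIMask | np.ndarray,
                spec: QuantizationSpec = DEFAULT_QUANTIZATION,
                ) -> "OrderedDict[str, float]":
    """The complete 208-entry feature vector, in roster order."""
    out: "OrderedDict[str, float]" = OrderedDict()

    def _family(prefix: str, fn, *args):
        try:
            values = fn(*args)
        except Exception as exc:
            raise type(exc)(f"[{prefix}] {exc}") from exc
        for name, value in values.items():
            out[f"{prefix}.{name}"] = float(value)

    _family("HIST", histogram_features, volume, mask, spec)
    g = glcm(volume, mask, spec)
    _family("GLCM", glcm_features, g)
    _family("GLRLM", glrlm_features, volume, mask, spec)
    for band, (sub_vox, sub_mask) in wavelet_subbands(volume, mask).items():
        _family(f"{band}_HIST", histogram_features, sub_vox, sub_mask, spec)
        gb = glcm(sub_vox, sub_mask, spec)
        _family(f"{band}_GLCM", glcm_features, gb)
        _family(f"{band}_GLRLM", glrlm_features, sub_vox, sub_mask, spec)
    _family("FRAC", fractal_features, volume, mask, spec)

    assert list(out.keys()) == FEATURE_ROSTER
    bad = [k for k, v in out.items() if not math.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return out
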