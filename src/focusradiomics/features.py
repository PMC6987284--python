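"""3D radiomic features: 43 per time-point, 215 per dynamic case.

Per time-point the extractor computes

* 6 first-order intensity statistics over the masked voxels,
* 5 shape descriptors from the (single) lesion mask, replicated across the
  five time-points so each carries the full 43-feature block,
* 12 grey-level co-occurrence matrix (GLCM) statistics — 6 quantities,
  each summarised as mean and standard deviation over the 13 unique 3D
  directions of the 26-neighbourhood,
* 20 grey-level run-length matrix (GLRLM) statistics — 10 quantities with
  the same mean/SD aggregation.

Texture matrices are built on a per-ROI, per-time-point equal-width
quantisation of the masked intensities (32 grey levels by default); only
masked voxels contribute pairs/runs, and runs break at mask boundaries.
GLCMs are symmetric (each pair counted in both orientations) and normalised
to probabilities; entropy uses base-2 logarithms.  Direction aggregation SD
is the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DynamicSeries, LesionMask, SyntheticCase

GLCM_NAMES = ("Energy", "Entropy", "InverseDifferenceMoment", "Inertia",
              "ClusterShade", "ClusterProminence")
GLRLM_NAMES = ("ShortRunEmphasis", "LongRunEmphasis",
               "GreyLevelNonUniformity", "RunLengthNonUniformity",
               "LowGreyLevelRunEmphasis", "HighGreyLevelRunEmphasis",
               "ShortRunLowGreyLevelEmphasis", "ShortRunHighGreyLevelEmphasis",
               "LongRunLowGreyLevelEmphasis", "LongRunHighGreyLevelEmphasis")
INTENSITY_NAMES = ("Max", "Min", "Mean", "Sigma", "Variance",
                   "IntegratedIntensity")
SHAPE_NAMES = ("Eccentricity", "Elongation", "MajorAxisLength",
               "MinorAxisLength", "Volume")


def feature_names_per_timepoint() -> list:
    """The 43 feature names of one time-point block, in canonical order."""
    names = list(INTENSITY_NAMES) + list(SHAPE_NAMES)
    for base in GLCM_NAMES:
        names += [f"{base}_mean", f"{base}_sd"]
    for base in GLRLM_NAMES:
        names += [f"{base}_mean", f"{base}_sd"]
    return names


def feature_names() -> list:
    """All 215 feature names, T0 block first."""
    per_t = feature_names_per_timepoint()
    return [f"{n}_T{t}" for t in range(5) for n in per_t]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def crop_to_bbox(series: DynamicSeries, mask: LesionMask, margin: int = 0):
    """Crop series and mask to the mask's bounding box plus a voxel margin,
    clipped to the volume bounds.  Masked statistics are unchanged by this;
    it only avoids analysing irrelevant image regions."""
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    idx = np.nonzero(m)
    sl = tuple(
        slice(max(0, int(ax.min()) - margin),
              min(m.shape[d], int(ax.max()) + 1 + margin))
        for d, ax in enumerate(idx))
    cropped = DynamicSeries(series.data[(slice(None),) + sl], series.spacing,
                            series.times)
    return cropped, LesionMask(m[sl], mask.spacing)


@dataclass
class QuantizedROI:
    """Masked voxels quantised to integer grey levels 1..n_levels."""

    levels: np.ndarray      # int array, 0 outside mask
    n_levels: int
    mask: np.ndarray        # bool
    spacing: tuple


def quantize(volume: np.ndarray, mask: np.ndarray, n_levels: int = 32,
             spacing: tuple = (1.0, 1.0, 1.0)) -> QuantizedROI:
    """Equal-width binning of masked intensities into 1..n_levels.

    ``level = min(floor((v - min) / (max - min) * n_levels) + 1, n_levels)``;
    a constant ROI maps every voxel to level 1 (degenerate rule), keeping
    unenhanced time-points processable.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = volume[mask]
    levels = np.zeros(volume.shape, dtype=np.int64)
    if vals.size:
        mn, mx = vals.min(), vals.max()
        if mx == mn:
            levels[mask] = 1
        else:
            lev = np.floor((vals - mn) / (mx - mn) * n_levels).astype(np.int64) + 1
            levels[mask] = np.minimum(lev, n_levels)
    return QuantizedROI(levels, int(n_levels), mask, tuple(spacing))


# ---------------------------------------------------------------------------
# first-order and shape features
# ---------------------------------------------------------------------------

def intensity_features(volume: np.ndarray, mask: np.ndarray,
                       spacing: tuple) -> dict:
    vals = np.asarray(volume, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    voxvol = float(np.prod(spacing))
    var = float(vals.var())         # population variance
    return {
        "Max": float(vals.max()),
        "Min": float(vals.min()),
        "Mean": float(vals.mean()),
        "Sigma": float(np.sqrt(var)),
        "Variance": var,
        "IntegratedIntensity": float(vals.sum()) * voxvol,
    }


def shape_features(mask: np.ndarray, spacing: tuple) -> dict:
    """Equivalent-ellipsoid shape descriptors from the voxel-coordinate
    covariance: axis lengths 4*sqrt(lambda), Elongation = sqrt(l1/l2) >= 1,
    Eccentricity = sqrt(1 - l3/l1)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 1:
        raise ValueError("empty mask")
    voxvol = float(np.prod(spacing))
    out = {"Volume": n * voxvol}
    if n < 2:
        warnings.warn("fewer than 2 voxels: axes and eccentricity set to 0")
        out.update({"Eccentricity": 0.0, "Elongation": 0.0,
                    "MajorAxisLength": 0.0, "MinorAxisLength": 0.0})
        return out
    coords = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    cov = np.cov(coords.T, ddof=0)
    lam = np.sort(np.clip(np.linalg.eigvalsh(cov), 0.0, None))[::-1]
    l1, l2, l3 = lam
    out["MajorAxisLength"] = 4.0 * np.sqrt(l1)
    out["MinorAxisLength"] = 4.0 * np.sqrt(l3)
    if l2 > 0:
        out["Elongation"] = float(np.sqrt(l1 / l2))
    else:
        warnings.warn("degenerate (collinear) mask: elongation set to 0")
        out["Elongation"] = 0.0
    out["Eccentricity"] = float(np.sqrt(1.0 - l3 / l1)) if l1 > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def direction_set_3d() -> list:
    """The 13 unique displacement vectors of the 26-neighbourhood modulo
    sign: each (dz, dy, dx) with first nonzero component positive."""
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                first = next(v for v in d if v != 0)
                if first > 0:
                    dirs.append(d)
    return dirs


def _shifted_views(arr: np.ndarray, d: tuple):
    """Views (a, b) such that b is a shifted by +d, over the overlap."""
    sl_a, sl_b = [], []
    for dim, off in zip(arr.shape, d):
        if off >= 0:
            sl_a.append(slice(0, dim - off))
            sl_b.append(slice(off, dim))
        else:
            sl_a.append(slice(-off, dim))
            sl_b.append(slice(0, dim + off))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_matrix(q: QuantizedROI, direction: tuple) -> np.ndarray | None:
    """Symmetric, normalised co-occurrence matrix for one direction, or
    None when the direction yields no valid masked voxel pair."""
    lev_a, lev_b = _shifted_views(q.levels, direction)
    msk_a, msk_b = _shifted_views(q.mask, direction)
    both = msk_a & msk_b
    if not both.any():
        return None
    i = lev_a[both] - 1
    j = lev_b[both] - 1
    n = q.n_levels
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T          # count both orientations
    return counts / counts.sum()


def glcm_stats(q: QuantizedROI, direction: tuple) -> dict | None:
    p = glcm_matrix(q, direction)
    if p is None:
        return None
    n = q.n_levels
    i = np.arange(1, n + 1)[:, None].astype(float)
    j = np.arange(1, n + 1)[None, :].astype(float)
    mu_x = float((i * p).sum())
    mu_y = float((j * p).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    s = i + j - mu_x - mu_y
    return {
        "Energy": float((p * p).sum()),
        "Entropy": entropy,
        "InverseDifferenceMoment": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Inertia": float(((i - j) ** 2 * p).sum()),
        "ClusterShade": float((s ** 3 * p).sum()),
        "ClusterProminence": float((s ** 4 * p).sum()),
    }


def glrlm_matrix(q: QuantizedROI, direction: tuple) -> np.ndarray | None:
    """Run-length count matrix r[level-1, runlen-1] for one direction, or
    None when the mask admits no run.  Runs are maximal same-level voxel
    segments along the direction, restricted to the mask (a run breaks at
    mask boundaries)."""
    mask = q.mask
    lev = q.levels
    if not mask.any():
        return None
    d = np.asarray(direction)
    shape = np.asarray(mask.shape)
    starts = np.argwhere(mask)
    # a voxel starts a run if its predecessor is out of bounds, unmasked,
    # or has a different level
    prev = starts - d
    ok = np.all((prev >= 0) & (prev < shape), axis=1)
    is_start = np.ones(len(starts), dtype=bool)
    pz, py, px = prev[ok].T
    sz, sy, sx = starts[ok].T
    same = mask[pz, py, px] & (lev[pz, py, px] == lev[sz, sy, sx])
    is_start[ok] = ~same
    runs = {}
    for z, y, x in starts[is_start]:
        g = lev[z, y, x]
        length = 1
        nz_, ny_, nx_ = z + d[0], y + d[1], x + d[2]
        while (0 <= nz_ < shape[0] and 0 <= ny_ < shape[1]
               and 0 <= nx_ < shape[2] and mask[nz_, ny_, nx_]
               and lev[nz_, ny_, nx_] == g):
            length += 1
            nz_, ny_, nx_ = nz_ + d[0], ny_ + d[1], nx_ + d[2]
        runs[(int(g), length)] = runs.get((int(g), length), 0) + 1
    max_len = max(l for _, l in runs)
    r = np.zeros((q.n_levels, max_len), dtype=float)
    for (g, l), c in runs.items():
        r[g - 1, l - 1] = c
    return r


def glrlm_stats(q: QuantizedROI, direction: tuple) -> dict | None:
    r = glrlm_matrix(q, direction)
    if r is None or r.sum() == 0:
        return None
    n_levels, max_len = r.shape
    i = np.arange(1, n_levels + 1)[:, None].astype(float)
    j = np.arange(1, max_len + 1)[None, :].astype(float)
    nr = r.sum()
    return {
        "ShortRunEmphasis": float((r / j ** 2).sum() / nr),
        "LongRunEmphasis": float((j ** 2 * r).sum() / nr),
        "GreyLevelNonUniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "RunLengthNonUniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "LowGreyLevelRunEmphasis": float((r / i ** 2).sum() / nr),
        "HighGreyLevelRunEmphasis": float((i ** 2 * r).sum() / nr),
        "ShortRunLowGreyLevelEmphasis": float((r / (i ** 2 * j ** 2)).sum() / nr),
        "ShortRunHighGreyLevelEmphasis": float((i ** 2 * r / j ** 2).sum() / nr),
        "LongRunLowGreyLevelEmphasis": float((j ** 2 * r / i ** 2).sum() / nr),
        "LongRunHighGreyLevelEmphasis": float((i ** 2 * j ** 2 * r).sum() / nr),
    }


def _aggregate_directions(stat_fn, q: QuantizedROI, names: tuple) -> dict:
    """Mean and sample SD of each statistic over the valid 3D directions."""
    rows = [s for s in (stat_fn(q, d) for d in direction_set_3d())
            if s is not None]
    if not rows:
        raise ValueError("no direction yields a valid texture matrix")
    out = {}
    for name in names:
        vals = np.array([row[name] for row in rows])
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# per-case extraction
# ---------------------------------------------------------------------------

def extract_case(series: DynamicSeries, mask: LesionMask, n_levels: int = 32,
                 margin: int = 2) -> pd.Series:
    """The 215-value feature vector of one (registered) case.

    Shape features are computed once from the single lesion mask and
    replicated across the five time-points, so every time-point carries a
    full 43-feature block.
    """
    series, mask = crop_to_bbox(series, mask, margin=margin)
    spacing = mask.spacing
    shape = shape_features(mask.data, spacing)
    values = {}
    for t in range(5):
        vol = series.data[t]
        feats = dict(intensity_features(vol, mask.data, spacing))
        feats.update(shape)
        q = quantize(vol, mask.data, n_levels=n_levels, spacing=spacing)
        feats.update(_aggregate_directions(glcm_stats, q, GLCM_NAMES))
        feats.update(_aggregate_directions(glrlm_stats, q, GLRLM_NAMES))
        for name in feature_names_per_timepoint():
            values[f"{name}_T{t}"] = feats[name]
    vec = pd.Series(values, dtype=float).reindex(feature_names())
    if vec.isna().any() or not np.isfinite(vec.to_numpy()).all():
        raise ValueError("non-finite feature value")
    return vec


def extract_cohort(cases: list, n_levels: int = 32,
                   margin: int = 2) -> pd.DataFrame:
    """Feature table: one row per case, 215 feature columns + 'label',
    indexed by case_id."""
    rows, labels, ids = [], [], []
    for case in cases:
        rows.append(extract_case(case.series, case.mask, n_levels=n_levels,
                                 margin=margin))
        labels.append(case.label)
        ids.append(case.case_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="case_id"))
    table["label"] = labels
    return table
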