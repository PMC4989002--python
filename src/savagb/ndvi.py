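"""NDVI time-series stratification for plot placement.

The normalized difference vegetation index, NDVI = (NIR - Red)/(NIR + Red),
is averaged per pixel across scene dates, optionally rescaled to 0-255 by
a linear min-max stretch, clustered by k-means into strata (one value per
pixel), and pixel centroids are drawn at random per stratum to place
calibration and validation plots; the two samples are disjoint.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def ndvi(nir: np.ndarray | float, red: np.ndarray | float) -> np.ndarray | float:
    """NDVI in [-1, 1]; NaN where both bands are zero (no signal)."""
    nir_a = np.asarray(nir, dtype=float)
    red_a = np.asarray(red, dtype=float)
    if np.any(nir_a < 0) or np.any(red_a < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir_a + red_a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, (nir_a - red_a) / denom)
    return float(out) if np.ndim(out) == 0 else out


def mean_ndvi(stack: np.ndarray) -> np.ndarray:
    """Per-pixel mean NDVI across dates (axis 0), ignoring NaN dates."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (dates, rows, cols) with >= 1 date")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        return np.nanmean(stack, axis=0)


def rescale_255(raster: np.ndarray) -> np.ndarray:
    """Linear min-max stretch to integers 0..255, rounding half-up.

    NaN cells stay NaN (returned as a float array when any are present).
    """
    arr = np.asarray(raster, dtype=float)
    valid = ~np.isnan(arr)
    if not valid.any():
        raise ValueError("raster has no valid cells")
    lo, hi = arr[valid].min(), arr[valid].max()
    if hi == lo:
        raise ValueError("constant raster cannot be rescaled")
    scaled = (arr - lo) / (hi - lo) * 255.0
    rounded = np.floor(scaled + 0.5)  # half-up
    if valid.all():
        return rounded.astype(np.int64)
    out = np.where(valid, rounded, np.nan)
    return out


def stratify(mean_raster: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """K-means strata over pixel values; -1 marks invalid (NaN) pixels.

    Stratum labels are relabelled in increasing order of cluster centre so
    the labelling is stable across runs.
    """
    arr = np.asarray(mean_raster, dtype=float)
    valid = ~np.isnan(arr)
    values = arr[valid].reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(values)) < k:
        raise ValueError(f"k={k} exceeds the number of distinct pixel values")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values)
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = np.full(arr.shape, -1, dtype=int)
    labels[valid] = relabel[km.labels_]
    return labels


def sample_strata(
    labels: np.ndarray,
    n_per_stratum: int,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
    cell_size: float = 1.0,
    validation_fraction: float = 0.0,
) -> pd.DataFrame:
    """Random pixel centroids per stratum for plot placement.

    Returns columns ``stratum, row, col, x, y, role`` where ``x, y`` are
    cell-centre map coordinates (origin at the lower-left corner of the
    grid) and role is ``train`` or ``validate``; the two roles never share
    a pixel.  When a stratum has fewer pixels than requested, all of them
    are returned with a warning.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n_validate = int(round(n_per_stratum * validation_fraction))
    nrows = labels.shape[0]
    frames = []
    for stratum in np.unique(labels[labels >= 0]):
        rows, cols = np.nonzero(labels == stratum)
        want = n_per_stratum + n_validate
        if len(rows) < want:
            warnings.warn(
                f"stratum {stratum}: only {len(rows)} pixels for "
                f"{want} requested; using all", stacklevel=2,
            )
            want = len(rows)
        idx = rng.choice(len(rows), size=want, replace=False)
        role = np.array(["train"] * min(n_per_stratum, want)
                        + ["validate"] * max(0, want - n_per_stratum))
        frames.append(
            pd.DataFrame(
                {
                    "stratum": stratum,
                    "row": rows[idx],
                    "col": cols[idx],
                    "x": origin[0] + (cols[idx] + 0.5) * cell_size,
                    "y": origin[1] + (nrows - rows[idx] - 0.5) * cell_size,
                    "role": role,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def stratify_and_sample(
    mean_raster: np.ndarray,
    k: int,
    n_per_stratum: int,
    seed: int = 0,
    **sample_kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: k-means strata, then per-stratum sampling."""
    labels = stratify(mean_raster, k, seed=seed)
    return sample_strata(labels, n_per_stratum, seed=seed, **sample_kwargs)
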