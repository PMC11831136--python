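"""Raw-intensity preprocessing.

Serial sections shrink toward the tendon end of the muscle, so per-slice
protein input spans a wide range that ordinary label-free normalization does
not cover.  The pipeline therefore (1) floors implausibly low raw
intensities to missing, (2) drops sections without any signal, (3) applies a
variance-stabilizing generalized-log transform with robust per-sample
calibration, and (4) makes every profile relative to the per-slice total
protein input by subtracting log2 of the slice's summed raw intensity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError, ValidationError

DEFAULT_FLOOR = 1e4


def floor_filter(values: pd.DataFrame, floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Set non-finite values and values strictly below ``floor`` to missing.

    Idempotent; observed values are never altered.
    """
    if floor <= 0:
        raise ValidationError("floor must be positive")
    arr = values.to_numpy(dtype=float, copy=True)
    arr[~np.isfinite(arr)] = np.nan
    with np.errstate(invalid="ignore"):
        arr[arr < floor] = np.nan
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


def drop_empty_samples(
    values: pd.DataFrame, ann: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove samples whose post-floor total intensity is zero.

    Recomputes ``total_intensity`` from the current (floored) matrix with
    missing treated as 0, mirroring a column sum with NA removal.
    """
    totals = values.fillna(0.0).sum(axis=0)
    keep = totals[totals > 0].index
    if len(keep) == 0:
        raise PipelineError("no usable slices: all samples are empty after flooring")
    ann = ann.loc[[c for c in values.columns if c in set(keep)]].copy()
    ann["total_intensity"] = totals.loc[ann.index]
    return values[ann.index], ann


def vst_normalize(
    values: pd.DataFrame,
    trim_fraction: float = 0.1,
    glog_softening: float | None = None,
) -> pd.DataFrame:
    """Variance-stabilizing transform with per-sample calibration.

    Each sample is calibrated by a positive scale factor estimated robustly
    under the assumption that most proteins are non-differential between
    samples: the factor is the trimmed mean (``trim_fraction`` per tail) of
    log-ratios against the row-median reference profile.  Calibrated
    intensities are then passed through an arsinh-style generalized log,

        h(u) = log2(u + sqrt(u^2 + c^2)) - 1,

    which converges to ``log2(u)`` for large intensities.  The softening
    constant ``c`` defaults to a small fraction of the lowest observed
    calibrated intensity, so on floor-filtered data the transform is within a
    few thousandths of a plain log2 while remaining finite near zero.

    Missing cells stay missing.  Raises :class:`PipelineError` when a sample
    shares no proteins with the reference (suggesting the ``log2-median``
    fallback).
    """
    if values.shape[1] < 2:
        raise ValidationError("variance stabilization needs at least 2 samples")
    n_with_data = int(values.notna().any(axis=1).sum())
    if n_with_data < 42:
        warnings.warn(
            f"only {n_with_data} proteins carry data; the robust calibration "
            "may be unstable",
            stacklevel=2,
        )
    arr = values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(arr, axis=1)
    usable = np.isfinite(ref) & (ref > 0)
    log_ratio = np.log2(arr[usable]) - np.log2(ref[usable])[:, None]

    scale = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        lr = log_ratio[:, j]
        lr = lr[np.isfinite(lr)]
        if lr.size == 0:
            raise PipelineError(
                f"robust calibration failed for sample {values.columns[j]!r}: "
                "no overlap with the reference profile; consider "
                "normalization='log2-median'"
            )
        scale[j] = 2.0 ** stats.trim_mean(lr, trim_fraction)

    u = arr / scale
    if glog_softening is None:
        finite = u[np.isfinite(u) & (u > 0)]
        if finite.size == 0:
            raise PipelineError("no positive intensities to normalize")
        glog_softening = float(np.quantile(finite, 0.005)) / 10.0
    c2 = max(glog_softening, np.finfo(float).tiny) ** 2
    out = np.log2(u + np.sqrt(u * u + c2)) - 1.0
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_median_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Simple fallback: log2 then per-sample median centering.

    The grand median of the sample medians is added back so values stay on
    an absolute log2-intensity scale.
    """
    arr = values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        logged = np.log2(arr)
    logged[~np.isfinite(logged)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(logged, axis=0)
    out = logged - med + np.nanmedian(med)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def total_intensity_correct(values: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Subtract log2 of each slice's total raw intensity.

    Makes profiles relative to the per-slice protein input (equivalently,
    dividing raw intensities by the slice sum), compensating the shrinking
    section area toward the tendon.
    """
    totals = ann.loc[values.columns, "total_intensity"].to_numpy(dtype=float)
    if not np.all(totals > 0):
        raise AssertionError("zero-total samples must be dropped before correction")
    return values - np.log2(totals)
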