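"""Quantitative trend statistic along the slice axis.

To find proteins whose abundance changes smoothly over the tissue — the
markers later used to align replicates — each replicate is scored with the
SAM-style quantitative statistic: the least-squares slope of abundance on
slice index, standardized by its standard error plus an exchangeability
("fudge") factor s0 shared by all proteins of the replicate,

    d_i = r_i / (se_i + s0),
    r_i  = sum_j x_ij (y_j - ybar) / sum_j (y_j - ybar)^2,
    se_i = sqrt( RSS_i / (n - 2) / sum_j (y_j - ybar)^2 ).

s0 damps the otherwise explosive scores of near-constant proteins; it is
chosen once per replicate by scanning the percentiles 0, 5, ..., 100 of the
se distribution and minimizing the coefficient of variation of the median
absolute deviation of d computed within quantile bins of se.  Seeded
permutations of the response provide a null score distribution.

A plain |t|-of-slope alternative (``method="tslope"``, s0 = 0) is available
for data where the moderated statistic is not wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class SamResult:
    """Per-protein trend scores of one replicate plus the permutation null."""

    scores: pd.DataFrame  # columns: d, slope, se; index: protein
    s0: float
    null_scores: np.ndarray  # shape (nperms, n_proteins)


def _slope_stats(x: np.ndarray, y: np.ndarray):
    """Vectorized per-row OLS of x_i on y: returns (slopes, se)."""
    n = y.size
    yc = y - y.mean()
    syy = float(np.sum(yc * yc))
    slopes = x @ yc / syy
    xc = x - x.mean(axis=1, keepdims=True)
    sxx = np.sum(xc * xc, axis=1)
    rss = np.maximum(sxx - slopes**2 * syy, 0.0)
    se = np.sqrt(rss / (n - 2) / syy)
    return slopes, se


def choose_s0(slopes: np.ndarray, se: np.ndarray, n_bins: int = 100) -> float:
    """SAM recipe for the exchangeability factor.

    Candidates are the 0, 5, ..., 100 percentiles of the se distribution;
    the winner minimizes the coefficient of variation of the MAD of
    ``slope/(se + s0)`` computed within (up to ``n_bins``) quantile bins of
    se.  Ties break toward the smaller candidate.
    """
    candidates = np.percentile(se, np.arange(0, 101, 5))
    n_bins = min(n_bins, se.size)
    if n_bins < 2:
        return float(candidates[10])  # median se: nothing to calibrate on
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bins = pd.qcut(se, n_bins, labels=False, duplicates="drop")
    best, best_cv = candidates[0], np.inf
    for cand in candidates:
        d = slopes / (se + cand)
        mads = (
            pd.Series(d)
            .groupby(bins)
            .apply(lambda v: stats.median_abs_deviation(v, scale="normal"))
            .to_numpy()
        )
        mads = mads[np.isfinite(mads)]
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-15:
            best, best_cv = cand, cv
    return float(best)


def sam_quant_scores(
    values: pd.DataFrame,
    response,
    nperms: int = 1000,
    rng_seed: int = 0,
    s0: float | None = None,
    method: str = "sam",
) -> SamResult:
    """Score each protein's trend against a quantitative response.

    Parameters
    ----------
    values
        proteins x samples matrix of one replicate, no missing cells.
    response
        slice index per sample (>= 2 distinct values required).
    s0
        override the fudge factor (0 recovers the ordinary t statistic of
        the slope); ignored for ``method="tslope"`` which forces 0.
    """
    y = np.asarray(response, dtype=float)
    x = values.to_numpy(dtype=float)
    if x.shape[1] != y.size:
        raise ValidationError("response length must match the number of samples")
    if y.size < 4:
        raise ValidationError("need at least 4 samples")
    if np.unique(y).size < 2:
        raise ValidationError("constant response")
    if np.isnan(x).any():
        raise ValidationError("missing cells present; impute first")

    slopes, se = _slope_stats(x, y)
    if method == "tslope":
        s0_val = 0.0
    elif s0 is not None:
        s0_val = float(s0)
    else:
        s0_val = choose_s0(slopes, se)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = slopes / (se + s0_val)

    rng = np.random.default_rng(rng_seed)
    null = np.empty((nperms, x.shape[0]))
    for p in range(nperms):
        yp = rng.permutation(y)
        sl, sep = _slope_stats(x, yp)
        with np.errstate(divide="ignore", invalid="ignore"):
            null[p] = sl / (sep + s0_val)

    scores = pd.DataFrame({"d": d, "slope": slopes, "se": se}, index=values.index)
    return SamResult(scores=scores, s0=s0_val, null_scores=null)


def combine_scores(
    scores: dict[str, pd.Series] | pd.DataFrame,
    replicate_order=None,
    min_abs_mean: float = 5.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Combine per-replicate d scores into the marker-selection table.

    ``absdiff`` is the absolute value of the summed successive differences
    of d along the replicate ordering (telescoping to |d_last - d_first|);
    ``fscore = mean / absdiff`` rewards strong trends that agree across
    replicates.  The table is ordered by |fscore| descending, proteins with
    absdiff = 0 excluded from that ordering (fscore undefined) but still
    eligible as markers.  Markers are proteins with |mean| strictly above
    ``min_abs_mean``.
    """
    if isinstance(scores, dict):
        table = pd.DataFrame(scores)
    else:
        table = scores.copy()
    if replicate_order is not None:
        table = table[list(replicate_order)]
    table = table.dropna().sort_index()

    if table.shape[1] == 1:
        warnings.warn(
            "single replicate: absdiff undefined; markers fall back to |d|",
            stacklevel=2,
        )
        d = table.iloc[:, 0]
        out = pd.DataFrame({"mean": d, "absdiff": np.nan, "fscore": np.nan})
        markers = list(out.index[out["mean"].abs() > min_abs_mean])
        return out, markers

    arr = table.to_numpy()
    mean = arr.mean(axis=1)
    absdiff = np.abs(np.diff(arr, axis=1).sum(axis=1))
    with np.errstate(divide="ignore"):
        fscore = np.where(absdiff > 0, mean / absdiff, np.nan)
    out = pd.DataFrame(
        {"mean": mean, "absdiff": absdiff, "fscore": fscore}, index=table.index
    )
    order = out["fscore"].abs().sort_values(ascending=False, na_position="last").index
    out = out.loc[order]
    markers = list(out.index[out["mean"].abs() > min_abs_mean])
    return out, markers
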