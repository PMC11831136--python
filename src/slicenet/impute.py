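"""Distance-aware imputation of spatial profiles.

Missing values are replaced per replicate and protein from neighbouring
slices: a local ordinary-least-squares line over a window on the *dense*
slice grid (so physically lost sections reduce the available points), with
two guards — predictions may never fall below the replicate block's minimum
observed value, and windows with too few observed points either fall back to
a stochastic low-abundance draw or stay missing.  Whatever remains missing
afterwards is filled per sample from that sample's low-intensity tail
(a downshifted-normal draw in the Perseus tradition).

Observed cells are never modified by either operation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PipelineError

logger = logging.getLogger(__name__)


@dataclass
class ImputeParams:
    """Tunables of the distance-based imputation.

    width_forward / width_backward
        slices ahead/behind the missing slice included in the window,
        counted on the dense grid (default 10 each, i.e. +-200 um at 20 um).
    min_data_required
        exclusive lower bound on observed points needed for a linear fit;
        with fewer the fallback path is taken.  For sparse data values
        below 5 are not recommended.
    fallback
        ``"impute"`` draws a single low-abundance value, ``"none"`` leaves
        the cell missing (the pipeline default, which then relies on
        :func:`global_downshift_impute`).
    sel
        low-quantile fraction defining the "low tail" used by the fallback
        draw's spread.
    m_offset / sd_offset
        downshift of the fallback mean in SD units, and shrink factor of
        the fallback spread.
    """

    width_forward: int = 10
    width_backward: int = 10
    min_data_required: int = 3
    fallback: str = "none"
    sel: float = 0.05
    m_offset: float = 1.6
    sd_offset: float = 0.8
    rng_seed: int = 0

    def __post_init__(self):
        if self.width_forward < 0 or self.width_backward < 0:
            raise ValueError("window widths must be >= 0")
        if self.min_data_required < 1:
            raise ValueError("min_data_required must be >= 1")
        if not 0.0 < self.sel < 1.0:
            raise ValueError("sel must lie in (0, 1)")
        if self.m_offset < 0 or self.sd_offset <= 0:
            raise ValueError("m_offset must be >= 0 and sd_offset > 0")
        if self.fallback not in ("impute", "none"):
            raise ValueError("fallback must be 'impute' or 'none'")


def _ols_predict(slices: np.ndarray, obs: np.ndarray, at: float) -> float:
    """Least-squares line value ~ slice evaluated at ``at``."""
    xm = slices.mean()
    ym = obs.mean()
    sxx = float(np.sum((slices - xm) ** 2))
    if sxx == 0.0:  # identical slice coordinates cannot occur on the dense grid
        return ym
    slope = float(np.sum((slices - xm) * (obs - ym))) / sxx
    return ym + slope * (at - xm)


def impute_by_distance(
    values: pd.DataFrame, ann: pd.DataFrame, params: ImputeParams | None = None
) -> pd.DataFrame:
    """Impute missing cells from neighbouring slices via local linear fits.

    For every replicate and protein, each missing slice s considers the
    window [s - width_backward, s + width_forward] on the dense slice grid.
    If strictly more than ``min_data_required`` observed points lie in the
    window, the OLS line of value on slice predicts the cell; predictions
    below the minimum observed value of the whole replicate block are
    rejected (left missing).  Otherwise the fallback applies: a single draw
    from ``Normal(mean(xm) - m_offset*sd(xm), sd_offset * sd(low tail of
    xm))`` where xm collects all replicate-block values strictly inside this
    protein's observed range — or the cell stays missing with
    ``fallback="none"``.

    All fits use only originally observed values; cells are visited in a
    fixed order (replicate, protein, slice ascending) so a given seed yields
    identical output.
    """
    if params is None:
        params = ImputeParams()
    rng = np.random.default_rng(params.rng_seed)
    ann = ann.loc[values.columns]
    out = values.copy()
    counts = {"linear": 0, "rejected": 0, "fallback": 0, "left_missing": 0}

    for rep in sorted(ann["replicate"].unique()):
        sub = ann[ann["replicate"] == rep].sort_values("slice", kind="stable")
        cols = list(sub.index)
        slices = sub["slice"].to_numpy(dtype=float)
        block = values[cols].to_numpy(dtype=float)
        finite_block = block[np.isfinite(block)]
        block_min = finite_block.min() if finite_block.size else np.nan

        for i in range(block.shape[0]):
            z = block[i]
            missing = np.isnan(z)
            if not missing.any():
                continue
            obs_mask = ~missing
            fills: list[tuple[int, float]] = []
            for j in np.flatnonzero(missing):
                s = slices[j]
                in_win = (
                    (slices >= s - params.width_backward)
                    & (slices <= s + params.width_forward)
                    & obs_mask
                )
                n_obs = int(in_win.sum())
                if n_obs > params.min_data_required:
                    pred = _ols_predict(slices[in_win], z[in_win], s)
                    if pred < block_min:
                        counts["rejected"] += 1
                    else:
                        fills.append((j, pred))
                        counts["linear"] += 1
                elif params.fallback == "impute":
                    val = _fallback_draw(z, finite_block, params, rng)
                    if val is None:
                        counts["left_missing"] += 1
                    else:
                        fills.append((j, val))
                        counts["fallback"] += 1
                else:
                    counts["left_missing"] += 1
            for j, v in fills:
                out.iloc[i, out.columns.get_loc(cols[j])] = v
    logger.info("impute_by_distance: %s", counts)
    return out


def _fallback_draw(z, finite_block, params: ImputeParams, rng) -> float | None:
    obs = z[np.isfinite(z)]
    if obs.size < 2:
        return None
    lo, hi = obs.min(), obs.max()
    xm = finite_block[(finite_block > lo) & (finite_block < hi)]
    if xm.size < 2:
        return None
    tail = xm[xm < np.quantile(xm, params.sel)]
    spread = np.std(tail, ddof=1) if tail.size >= 2 else np.nan
    if not np.isfinite(spread):
        return None
    mean = xm.mean() - params.m_offset * np.std(xm, ddof=1)
    return float(rng.normal(mean, spread * params.sd_offset))


def global_downshift_impute(
    values: pd.DataFrame, sel: float = 0.05, rng_seed: int = 0
) -> pd.DataFrame:
    """Fill remaining missing cells from each sample's low-intensity tail.

    Per sample, missing cells are drawn from ``Normal(mean, sd)`` of the
    sample's values below its ``sel``-quantile.  When fewer than two such
    values exist the tail widens to the lowest ``max(2, ceil(sel*n))``
    values (logged as a warning).  Output contains no missing cells and is
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    out = values.copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        missing = np.isnan(x)
        obs = x[~missing]
        if obs.size == 0:
            raise PipelineError(f"sample {col!r} has no observed values to impute from")
        if not missing.any():
            continue
        tail = obs[obs < np.quantile(obs, sel)]
        if tail.size < 2:
            k = max(2, math.ceil(sel * obs.size))
            k = min(k, obs.size)
            tail = np.sort(obs)[:k]
            warnings.warn(
                f"sample {col!r}: low tail widened to the lowest {k} values",
                stacklevel=2,
            )
        mu = tail.mean()
        sd = np.std(tail, ddof=1) if tail.size >= 2 else 0.0
        x[missing] = rng.normal(mu, sd, size=int(missing.sum()))
        out[col] = x
    return out
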