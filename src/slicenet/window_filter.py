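"""Sliding-window evaluation of missing values.

A window of ``after + 1`` consecutive samples (default 11 slices, roughly
200 um at 20 um thickness) slides along each replicate's profile.  A protein
is kept when, averaged over replicates, its *best* window still reaches the
required data rate — i.e. somewhere along the axis the protein is densely
observed, even if whole tissue regions lack it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import PipelineError


@dataclass(frozen=True)
class WindowSpec:
    """Forward-looking window over sample order within a replicate.

    after
        number of subsequent samples included; window length = after + 1.
    max_na_fraction
        a protein is selected when the mean (over replicates) of its minimal
        per-window missing fraction is <= this threshold (inclusive);
        0.3 corresponds to a 70% data rate.
    complete_only
        only windows fully inside the profile are evaluated.
    """

    after: int = 10
    max_na_fraction: float = 0.3
    complete_only: bool = True

    def __post_init__(self):
        if self.after < 0:
            raise ValueError("after must be >= 0")
        if not 0.0 <= self.max_na_fraction <= 1.0:
            raise ValueError("max_na_fraction must lie in [0, 1]")


def sliding_na_fractions(profile, spec: WindowSpec) -> np.ndarray:
    """Per-window missing fractions of one ordered profile.

    Returns one value per start position with a complete window
    ``[i, i + after]``; an empty array when the profile is shorter than the
    window.
    """
    x = np.asarray(profile, dtype=float)
    w = spec.after + 1
    if x.size < w:
        return np.empty(0)
    windows = sliding_window_view(np.isnan(x), w)
    return windows.sum(axis=1) / w


def replicate_window_scores(
    values: pd.DataFrame, ann: pd.DataFrame, spec: WindowSpec
) -> pd.DataFrame:
    """Minimum window missing-fraction per protein and replicate.

    Replicates shorter than the window contribute a NaN column.  Samples are
    ordered by slice within each replicate; control samples are ignored.
    """
    ann = ann.loc[values.columns]
    ann = ann[~ann["is_control"]] if "is_control" in ann else ann
    scores = {}
    for rep, sub in ann.groupby("replicate", sort=True):
        cols = sub.sort_values("slice", kind="stable").index
        block = values[cols].to_numpy(dtype=float)
        w = spec.after + 1
        if block.shape[1] < w:
            scores[rep] = np.full(values.shape[0], np.nan)
            continue
        windows = sliding_window_view(np.isnan(block), w, axis=1)
        scores[rep] = windows.sum(axis=2).min(axis=1) / w
    return pd.DataFrame(scores, index=values.index)


def select_proteins(
    values: pd.DataFrame, ann: pd.DataFrame, spec: WindowSpec
) -> list[str]:
    """Proteins whose mean-of-minima window missing fraction passes the cut.

    Raises :class:`PipelineError` when no replicate is long enough to host a
    single window.
    """
    table = replicate_window_scores(values, ann, spec)
    if table.isna().all(axis=None):
        raise PipelineError("window too large for data: no replicate yields windows")
    mean_min = table.mean(axis=1, skipna=True)
    selected = mean_min[mean_min <= spec.max_na_fraction]
    return list(selected.index)
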