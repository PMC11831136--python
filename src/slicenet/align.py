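"""Replicate alignment on a common relative axis.

Biological replicates differ in tissue length and in where the sectioning
started, so their slice axes are first mapped to relative positions in
[0, 1] and then shifted against a reference replicate.  The shift is found
by smoothing each marker protein's profile onto a dense uniform grid with
local polynomial (loess) regression and scanning lagged Pearson
correlations between the reference and the other replicate in both pairing
directions; the median shift over marker proteins, per direction, decides
how much (and which way) the replicate is compressed or stretched.

The applied shift is a single global offset per replicate pair — no
nonlinear warping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .errors import PipelineError, ValidationError


def relative_positions(ann: pd.DataFrame) -> pd.DataFrame:
    """Add ``perc``: per replicate, (slice - min)/(max - min) in [0, 1]."""
    ann = ann.copy()
    perc = np.full(len(ann), np.nan)
    for rep, sub in ann.groupby("replicate", sort=False):
        s = sub["slice"].to_numpy(dtype=float)
        if s.size < 2 or s.max() == s.min():
            raise ValidationError(
                f"replicate {rep!r} has fewer than 2 distinct slices"
            )
        perc[ann.index.get_indexer(sub.index)] = (s - s.min()) / (s.max() - s.min())
    ann["perc"] = perc
    return ann


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights on a grid.

    At each grid point the nearest ``ceil(span * n)`` observations receive
    tricube weights on their scaled distance and a degree-``degree``
    polynomial is fit by weighted least squares; the fitted value at the
    grid point is returned.  Grid points outside the data range yield NaN
    (no extrapolation).  Exact for polynomials up to ``degree``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = x.size
    q = int(np.ceil(span * n))
    q = max(min(q, n), degree + 1)

    dist = np.abs(x[None, :] - grid[:, None])  # (G, n)
    h = np.partition(dist, q - 1, axis=1)[:, q - 1] * (1.0 + 1e-9)
    h[h == 0] = np.finfo(float).tiny
    w = (1.0 - np.clip(dist / h[:, None], 0.0, 1.0) ** 3) ** 3

    u = x[None, :] - grid[:, None]
    p = degree + 1
    powers = [w * u**k for k in range(2 * degree + 1)]
    moments = np.stack([pw.sum(axis=1) for pw in powers], axis=1)  # (G, 2d+1)
    rhs = np.stack([(w * u**k * y[None, :]).sum(axis=1) for k in range(p)], axis=1)
    a = np.empty((grid.size, p, p))
    for i in range(p):
        for j in range(p):
            a[:, i, j] = moments[:, i + j]
    beta0 = np.full(grid.size, np.nan)
    try:
        beta = np.linalg.solve(a, rhs[..., None])[..., 0]
        beta0 = beta[:, 0]
    except np.linalg.LinAlgError:
        for g in range(grid.size):
            try:
                beta0[g] = np.linalg.solve(a[g], rhs[g])[0]
            except np.linalg.LinAlgError:
                beta0[g] = np.linalg.lstsq(a[g], rhs[g], rcond=None)[0][0]
    # solve() on a stacked batch raises only if *some* matrix is singular;
    # redo row-wise in that case, otherwise guard non-finite rows
    bad = ~np.isfinite(beta0)
    for g in np.flatnonzero(bad):
        beta0[g] = np.linalg.lstsq(a[g], rhs[g], rcond=None)[0][0]

    beta0[(grid < x.min()) | (grid > x.max())] = np.nan
    return beta0


def smooth_to_grid(
    values,
    positions,
    grid_n: int = 5000,
    span: float = 0.75,
    protein: str | None = None,
) -> np.ndarray:
    """Smooth one profile onto the uniform [0, 1] grid.

    Requires at least 4 observed points; raises :class:`PipelineError`
    naming the protein otherwise.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(positions, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 4:
        raise PipelineError(
            f"too few points to smooth profile{f' of {protein!r}' if protein else ''}"
        )
    grid = np.linspace(0.0, 1.0, grid_n)
    return loess_smooth(x[ok], y[ok], grid, span=span)


@dataclass
class ShiftResult:
    """Best lag of one profile pair in both pairing directions.

    ``lo`` slides the second profile's head against the reference's tail
    (the replicate sits to the *right* of the reference, shift subtracted);
    ``up`` is the opposite direction (shift added).  Shift values follow the
    grid convention value[|lag|] = (lag - 1) * spacing.
    """

    lag_lo: int
    lag_up: int
    shift_lo: float
    shift_up: float
    corr_lo: float
    corr_up: float


def _lagged_pearson(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """r(l) = Pearson correlation of a[l:] with b[:n-l], for l = 1..max_lag."""
    n = a.size
    lags = np.arange(1, max_lag + 1)
    dots = signal.correlate(a, b, mode="full")  # dots[n-1+l] = sum a[l+j] b[j]
    dot = dots[n - 1 + lags]
    ca, ca2 = np.cumsum(a[::-1]), np.cumsum(a[::-1] ** 2)  # suffix sums of a
    cb, cb2 = np.cumsum(b), np.cumsum(b**2)  # prefix sums of b
    m = n - lags
    sa = ca[m - 1]
    qa = ca2[m - 1]
    sb = cb[m - 1]
    qb = cb2[m - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = dot - sa * sb / m
        var = (qa - sa**2 / m) * (qb - sb**2 / m)
        r = cov / np.sqrt(var)
    r[var <= 0] = np.nan
    return r


def pairwise_best_shift(
    g_ref: np.ndarray,
    g_other: np.ndarray,
    spacing: float | None = None,
    max_lag: int | None = None,
) -> ShiftResult:
    """Scan lagged correlations between two dense profiles.

    Leading/trailing NaN stretches (unsmoothed grid ends) are trimmed to the
    common finite range first.  Lags run from 1 to half the (trimmed) grid;
    ties in correlation break toward the smallest lag, i.e. the least
    deformation.  Negative best correlations are reported as-is.
    """
    g1 = np.asarray(g_ref, dtype=float)
    g2 = np.asarray(g_other, dtype=float)
    if g1.size != g2.size:
        raise ValidationError("profiles must share the grid")
    if spacing is None:
        spacing = 1.0 / (g1.size - 1)
    ok = np.isfinite(g1) & np.isfinite(g2)
    if not ok.any():
        raise PipelineError("no shared finite range between profiles")
    lo_i, hi_i = np.flatnonzero(ok)[[0, -1]]
    g1, g2 = g1[lo_i : hi_i + 1], g2[lo_i : hi_i + 1]
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise PipelineError("profiles contain interior missing values")
    n = g1.size
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 2)

    r_up = _lagged_pearson(g1, g2, max_lag)  # other leads: shift added
    r_lo = _lagged_pearson(g2, g1, max_lag)  # other lags: shift subtracted

    def best(r):
        if np.all(np.isnan(r)):
            return 1, np.nan
        idx = int(np.nanargmax(r))
        return idx + 1, float(r[idx])

    lag_up, corr_up = best(r_up)
    lag_lo, corr_lo = best(r_lo)
    return ShiftResult(
        lag_lo=lag_lo,
        lag_up=lag_up,
        shift_lo=(lag_lo - 1) * spacing,
        shift_up=(lag_up - 1) * spacing,
        corr_lo=corr_lo,
        corr_up=corr_up,
    )


@dataclass
class AlignmentResult:
    grid_n: int
    #: (reference, other) -> DataFrame indexed by marker with lo/up shifts
    per_protein_shifts: dict = field(default_factory=dict)
    #: rows "lo"/"up", one column per pair
    median_shift: pd.DataFrame | None = None
    #: winning direction per pair
    winners: dict = field(default_factory=dict)
    #: per-sample aligned positions
    applied: pd.Series | None = None


def estimate_marker_shifts(
    values: pd.DataFrame,
    ann: pd.DataFrame,
    markers,
    reference_replicate: str,
    grid_n: int = 5000,
    span: float = 0.75,
) -> dict:
    """Per-marker fractional shifts for every (reference, other) pair."""
    ann = ann.loc[values.columns]
    reps = sorted(ann["replicate"].unique())
    if reference_replicate not in reps:
        raise PipelineError(
            f"reference replicate {reference_replicate!r} not found"
        )
    spacing = 1.0 / (grid_n - 1)
    cols = {
        rep: ann[ann["replicate"] == rep].sort_values("perc", kind="stable").index
        for rep in reps
    }
    shifts: dict = {}
    for other in reps:
        if other == reference_replicate:
            continue
        rows = {}
        for prot in markers:
            g = {}
            for rep in (reference_replicate, other):
                sub = cols[rep]
                g[rep] = smooth_to_grid(
                    values.loc[prot, sub].to_numpy(),
                    ann.loc[sub, "perc"].to_numpy(),
                    grid_n=grid_n,
                    span=span,
                    protein=prot,
                )
            res = pairwise_best_shift(g[reference_replicate], g[other], spacing=spacing)
            rows[prot] = {
                "shift_lo": res.shift_lo,
                "shift_up": res.shift_up,
                "corr_lo": res.corr_lo,
                "corr_up": res.corr_up,
            }
        shifts[(reference_replicate, other)] = pd.DataFrame(rows).T
    return shifts


def median_shift_and_apply(
    per_protein_shifts: dict,
    ann: pd.DataFrame,
    reference_replicate: str,
) -> tuple[pd.DataFrame, AlignmentResult]:
    """Apply the median marker shift of the winning direction per pair.

    The winning direction is the one with the larger median shift: for
    cleanly trending markers the wrong pairing direction collapses onto a
    near-zero lag, so the substantive displacement identifies the true
    geometry.  "lo" subtracts the shift from the replicate's ``perc``,
    "up" adds it; the reference replicate keeps ``perc2 = perc``.
    """
    pairs = [p for p in per_protein_shifts if p[0] == reference_replicate]
    if not pairs:
        raise PipelineError(f"reference replicate {reference_replicate!r} not found")
    ann = ann.copy()
    if "perc" not in ann:
        raise ValidationError("annotations lack 'perc'; run relative_positions first")
    ann["perc2"] = ann["perc"]

    med = {}
    winners = {}
    for pair in pairs:
        table = per_protein_shifts[pair]
        if len(table) < 3:
            raise ValidationError(
                f"pair {pair}: need >= 3 marker proteins, got {len(table)}"
            )
        lo = float(table["shift_lo"].median())
        up = float(table["shift_up"].median())
        med[pair] = {"lo": lo, "up": up}
        direction = "lo" if lo >= up else "up"  # first max on ties
        winners[pair] = direction
        other = pair[1]
        mask = ann["replicate"] == other
        if direction == "lo":
            ann.loc[mask, "perc2"] = ann.loc[mask, "perc"] - lo
        else:
            ann.loc[mask, "perc2"] = ann.loc[mask, "perc"] + up

    result = AlignmentResult(
        grid_n=0,
        per_protein_shifts=per_protein_shifts,
        median_shift=pd.DataFrame(med),
        winners=winners,
        applied=ann["perc2"].copy(),
    )
    return ann, result


def align_replicates(
    values: pd.DataFrame,
    ann: pd.DataFrame,
    markers,
    reference_replicate: str,
    grid_n: int = 5000,
    span: float = 0.75,
) -> tuple[pd.DataFrame, AlignmentResult]:
    """Estimate and apply marker-based shifts; returns (ann with perc2, report)."""
    shifts = estimate_marker_shifts(
        values, ann, markers, reference_replicate, grid_n=grid_n, span=span
    )
    ann2, result = median_shift_and_apply(shifts, ann, reference_replicate)
    result.grid_n = grid_n
    return ann2, result


def _range01(row: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(row), np.nanmax(row)
    return (row - lo) / (hi - lo)


def finalize(
    values: pd.DataFrame, ann: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the final z-scaled and z+0-1-ranged matrices.

    Variant 1 centers and scales each protein to unit variance within each
    replicate; variant 2 additionally maps each protein to [0, 1] across all
    samples.  Columns are ordered by (replicate, perc2).  Proteins with zero
    variance within any replicate are dropped with a warning.
    """
    if values.isna().any(axis=None):
        raise ValidationError("finalize requires a fully imputed matrix")
    ann = ann.loc[values.columns]
    order = ann.sort_values(["replicate", "perc2"], kind="stable").index
    values = values[order]
    ann = ann.loc[order]

    z = values.copy().astype(float)
    drop = pd.Series(False, index=values.index)
    for rep, sub in ann.groupby("replicate", sort=False):
        block = values[sub.index].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        drop |= pd.Series((sd == 0).ravel(), index=values.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            z[sub.index] = (block - mu) / sd
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} zero-variance proteins", stacklevel=2
        )
        z = z[~drop]
    zr = z.apply(lambda row: pd.Series(_range01(row.to_numpy()), index=row.index), axis=1)
    return z, zr
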