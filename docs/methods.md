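# Methods

This note documents the models and numerical choices behind `slicenet`, in
the order the pipeline applies them, together with what the synthetic-data
generator does and does not emulate.

## Data model

The input is a wide proteins × samples matrix of non-negative raw LFQ
intensities with missing cells, one column per tissue section ("slice").
Sample names carry the biological replicate and the slice index
(`PG.Quant_<replicate>_…slice<k>` by default); both are extracted with
configurable regular expressions, so other naming schemes only need two
patterns. Slice indices are 1-based integers per replicate and may have
gaps (lost sections); all window logic operates on the dense slice grid
from the replicate's minimum to maximum index, so a physical gap genuinely
reduces the data available near it. Control wells (cell-lysate QC, blanks)
are flagged at import via a regex and excluded before normalization.

## Preprocessing

**Floor (`floor = 1e4`).** Raw intensities below 10^4 are indistinguishable
from noise on the instruments this kind of data comes from; they and all
non-finite values become missing. The comparison is strict (`< floor`),
and the operation is idempotent.

**Variance stabilization (`normalization = "vst"`).** Each sample *j* gets
a positive scale factor `s_j = 2^trim_mean(log2 x_ij − log2 ref_i)` with a
10 %-per-tail trimmed mean against the row-median reference profile — a
robust calibration that assumes most proteins are non-differential between
samples. Calibrated intensities pass through the generalized log

    h(u) = log2(u + sqrt(u² + c²)) − 1,

which equals `log2(u)` up to `0.36·(c/u)²` for `u ≫ c`. The softening
constant `c` defaults to 1/10 of the 0.5 % quantile of calibrated
intensities: on floor-filtered data the transform is therefore within a few
thousandths of a plain log2 while staying finite and compressive near
zero. We target the transform's defining properties (symmetry for
identical samples, absorption of per-sample scale factors, the log2
high-intensity limit), not bitwise agreement with any particular reference
implementation. A `log2-median` per-sample centering is available as a
fallback for data too sparse for the robust fit. The spec'd minimum of ~42
proteins for a stable robust fit is surfaced as a warning, not an error.

**Total-input correction.** `value_ij ← value_ij − log2(Σ_i raw_ij)` (sums
over floored raw intensities, missing as 0, computed before the
transform). This deliberately re-expresses every profile *relative to the
slice's total protein input*, compensating the shrinking section area
toward the tendon. Note the composition of calibration and correction is
invariant to scaling the whole matrix, but scaling a *single* slice is
absorbed by the calibration and then shifted by the correction — that is
the intended "relative to input" semantics, not a bug.

## Sliding-window filter

Windows are forward-looking over sample order within a replicate:
position *i* covers samples `[i, i+after]`, complete windows only.
Default `after = 10` (11 slices ≈ 220 µm at 20 µm thickness, matching the
~200 µm scanning scale of the protocol); useful values span 5–20 slices
depending on tissue heterogeneity. A protein's per-replicate score is the
*minimum* window missing-fraction — the best local stretch — and the
protein is selected when the mean of these minima over replicates is
`≤ max_na_fraction` (default 0.3, inclusive). Replicates shorter than the
window contribute nothing; if no replicate can host a window the filter
errors out. When replicates disagree strongly (one perfect, one absent)
the mean of minima is the only aggregation applied.

## Imputation

Two passes, observed cells never modified, one seeded RNG stream with a
fixed visitation order (replicate, protein, slice ascending):

1. **Distance-based linear pass.** For each missing slice *s*, the window
   `[s − width_backward, s + width_forward]` (defaults 10/10) on the dense
   grid is collected; when strictly more than `min_data_required`
   (default 3) observed points lie in it, the OLS line of value on slice
   predicts the cell. Predictions below the minimum observed value of the
   whole replicate block are rejected (left missing) — extrapolating a
   steep trend below anything ever observed is not evidence. The strict
   `>` bound is a single gate on observed points; for sparse tissues at
   least 5 points per window is recommended. The optional per-cell
   fallback (`fallback = "impute"`) draws once from
   `N(mean(xm) − 1.6·sd(xm), 0.8·sd(low tail of xm))`, where `xm` are all
   replicate-block values strictly inside the protein's observed range;
   the pipeline default is `fallback = "none"` followed by pass 2.
2. **Per-sample low-tail pass.** Remaining cells are drawn from
   `N(mean, sd)` of the sample's values below its 5 % quantile — a
   downshifted-normal in the Perseus tradition, justified by the
   missing-not-at-random character of proteomic dropout. Tails with fewer
   than two values widen to the lowest `max(2, ⌈sel·n⌉)` values with a
   logged warning.

## Trend statistic

The per-replicate score of protein *i* against slice index *y* is

    d_i = r_i / (se_i + s0),   r_i = Σ_j x_ij (y_j − ȳ) / Σ_j (y_j − ȳ)²,

with `se_i` the usual slope standard error from the per-protein
least-squares line. The exchangeability factor `s0` damps the explosive
scores of near-constant proteins: candidates are the 0, 5, …, 100
percentiles of `{se_i}`, and the winner minimizes the coefficient of
variation of `MAD(d)` computed within up to 100 quantile bins of `se`
(fewer bins when fewer proteins; ties to the smaller candidate). `s0` is
chosen once per replicate and reused for the seeded permutations of *y*
that form the null distribution. A plain `|t|`-of-slope alternative
(`trend.method = "tslope"`, `s0 = 0`) is exposed for users who prefer an
unmoderated statistic; other trend detectors (temporal-regulation models,
mutual information, ANOVA) are deliberately out of scope.

Scores are combined across replicates as `mean`, `absdiff = |Σ successive
differences|` (which telescopes to `|d_last − d_first|`; the summed form is
implemented verbatim), and `fscore = mean/absdiff` — large when the trend
is strong and consistent. `fscore` is undefined (and the protein excluded
from the fscore ordering, though not from marker eligibility) when
`absdiff = 0`. Markers are proteins with `|mean| > 5`, strict.

## Alignment

Each replicate's axis is first mapped to `perc = (slice − min)/(max − min)`.
For every (reference, other) pair and marker protein, both profiles are
smoothed onto a uniform 5000-point grid by local quadratic regression with
tricube weights (loess). The default span is 0.75 — the upstream
convention — but for markers much narrower than the tissue (a junction
sigmoid occupying ~10 % of the axis) that span averages over two-thirds of
the profile and biases the correlation peak by up to ~0.02 of the axis;
the recovery analyses in this package use `span = 0.3`, which resolves
junction-scale features and recovers planted offsets to ~0.001. The span
is a config key precisely because profile smoothness must be matched to
feature width.

The lag scan computes, for each lag ℓ = 1 … grid/2, the Pearson
correlation of one profile's tail (`g[ℓ:]`) against the other's head
(`g[:G−ℓ]`), in both pairing directions ("up": the other replicate leads;
"lo": it trails). Degenerate (zero-variance) overlaps yield no value; ties
break toward the smallest lag (least deformation). Per direction, the
median shift over markers is taken; the direction with the **larger median
shift** wins and is applied as `perc2 = perc ± shift`. The larger-shift
rule works because for a cleanly trending marker the wrong direction
collapses onto a near-zero lag while the true direction carries the
substantive displacement. The reference replicate (explicit config, first
replicate by default) is never moved, and shifts are only ever anchored to
the reference — no transitive composition across pairs, and no nonlinear
warping: one global shift per replicate pair.

**Finalization.** Columns are ordered by (replicate, perc2); each protein
is centered and scaled to unit variance within each replicate (zero-variance
proteins dropped with a warning), and a second variant additionally maps
each protein to [0, 1] across all samples. The delay analysis runs on the
ranged variant with replicate blocks concatenated in that column order —
mirroring how the finalized matrix is consumed downstream. A caveat worth
knowing: concatenation places replicate boundaries inside the profiles the
delay scan sees; with few, well-aligned replicates the effect is small,
but a per-replicate mode that averages delay curves is a reasonable
alternative we do not make the default.

## Delay network

For profiles of length *n*, overlaps shrink from *n* down to
`delayt = ⌊0.45·n⌋`; below that floor rank correlations of two short
monotone segments drift toward 1 regardless of content, which is exactly
the artifact the floor prevents (raise `delayt` if delays look too large).
The two half-curves (each direction) are concatenated with the duplicate
zero-delay entry removed, giving delays −D…+D with `D = n − delayt`.
Spearman correlation is the default (profiles are monotonic-transform
invariant after ranging); Pearson is a config switch. The delay argmax
takes the first maximum, i.e. the most negative delay, on exact ties.

Edges: pairs with `|delay| ≥ 20` grid units are discarded (strict), each
pair contributes its reverse with negated delay, and only `delay ≥ 0`
edges are kept, so zero-delay pairs appear in both directions. DPI pruning
is a single pass evaluated against the full unpruned graph: edge `x→y`
(delay *d*, correlation *c*) is removed iff some common intermediate has
both leg delays strictly positive, leg sum `< d·(1 + 0.1)`, and absolute
mean leg correlation `≥ |c| − 0.1`. A negative-delay edge cannot reach the
pruning routine after the directed build; if one ever does it is kept and
logged rather than silently handled. Delays are reported in grid units
(≈ slices); when `slice_thickness_um` is configured the exported table
also carries `delay × thickness` in µm. The pairwise scan is O(p²·n²);
the pipeline caps the network stage at the `network_max_proteins = 60`
most variable profiles by default — desk-scale hardware handles that in
seconds, and the cap is a config key, not a method property.

## Synthetic data

The generator emulates: per-protein archetypes (junction sigmoids with
center 0.3–0.7 and width 0.04–0.1 of the axis, Gaussian bumps, linear
ramps, flat housekeeping profiles), base abundances log-uniform over
2^17–2^30 (~4 decades, a high-dynamic-range tissue), an exponential
per-slice loading decay with end/start ratio 0.12 (mirroring section areas
shrinking from ~1.7 to ~0.2 mm²), log2-Gaussian measurement noise
(sd 0.25), replicate-specific axis offsets, logistic intensity-dependent
dropout centered at the 10^4 floor so the floor filter is genuinely
exercised, and uniform random dropout (rate 0.05). Three replicates of
~60 slices are the default — three is the minimum replicate count the
protocol contemplates, and 60 slices exercises every window mechanism
without the full ~175-section scale of a 3.5 mm muscle. Everything is
reconstructable from the recorded truth and seed.

Not emulated: peptide-level structure and rollup, chromatographic or
spectral artifacts, spatially correlated dropout (e.g. a torn section
losing one tissue type), and nonlinear axis distortions. Passing recovery
tests therefore demonstrate the estimators' correctness under the stated
generative model, not robustness to every failure mode of real sections.

## Determinism

One integer seed drives everything: per-stage seeds are derived as
`(seed·1000003 + offset) mod 2³¹`, imputation visits cells in a fixed
order, permutations are generated from a seeded generator, and pipeline
artifacts are written with round-trip float formatting so a run stopped
after any stage and resumed from disk is bit-identical to an uninterrupted
run.

## Known limitations

- The alignment model is a single global shift per replicate; stretched or
  locally distorted replicates need warping methods out of scope here.
- The trend statistic assumes a monotone component; purely localized
  (bump) profiles score near zero and never become alignment markers.
- Delay units are profile grid columns of the concatenated finalized
  matrix, a proxy for slices; they are not corrected for the axis shifts
  applied during alignment.
- The DPI test uses delays and correlations only; it has no notion of
  statistical significance for either.
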