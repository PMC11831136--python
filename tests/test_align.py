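import numpy as np
import pandas as pd
import pytest

from slicenet import align, simulate
from slicenet.errors import PipelineError, ValidationError
from tests.conftest import profile_frame, toy_annotations


class TestRelativePositions:
    def test_consecutive_slices(self):
        ann = toy_annotations({"A": [1, 2, 3, 4, 5]})
        out = align.relative_positions(ann)
        assert list(out["perc"]) == [0.0, 0.25, 0.5, 0.75, 1.0]

    def test_translation_invariance(self):
        a = align.relative_positions(toy_annotations({"A": [1, 2, 3, 4, 5]}))
        b = align.relative_positions(toy_annotations({"A": [3, 4, 5, 6, 7]}))
        assert list(a["perc"]) == list(b["perc"])

    def test_matches_formula_on_random_slice_sets(self, rng):
        slices = np.unique(rng.integers(1, 100, size=12))
        ann = align.relative_positions(toy_annotations({"A": slices}))
        expect = (slices - slices.min()) / (slices.max() - slices.min())
        np.testing.assert_allclose(ann["perc"], expect)

    def test_single_slice_replicate_errors(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            align.relative_positions(toy_annotations({"A": [1]}))


class TestLoessSmooth:
    def test_exact_on_quadratic(self, rng):
        x = np.sort(rng.uniform(0, 1, 40))
        y = 3.0 * x**2 - 2.0 * x + 0.5
        grid = np.linspace(x.min(), x.max(), 200)
        fit = align.loess_smooth(x, y, grid)
        np.testing.assert_allclose(fit, 3.0 * grid**2 - 2.0 * grid + 0.5, atol=1e-6)

    def test_constant_profile(self, rng):
        x = np.sort(rng.uniform(0, 1, 20))
        fit = align.loess_smooth(x, np.full(20, 4.2), np.linspace(0, 1, 50))
        inside = (np.linspace(0, 1, 50) >= x.min()) & (np.linspace(0, 1, 50) <= x.max())
        np.testing.assert_allclose(fit[inside], 4.2, atol=1e-9)

    def test_no_extrapolation(self, rng):
        x = np.linspace(0.2, 0.8, 30)
        fit = align.loess_smooth(x, x**2, np.linspace(0, 1, 100))
        g = np.linspace(0, 1, 100)
        assert np.isnan(fit[g < 0.2]).all()
        assert np.isnan(fit[g > 0.8]).all()
        assert np.isfinite(fit[(g >= 0.2) & (g <= 0.8)]).all()

    def test_noisy_sigmoid_within_variance_bound(self, rng):
        n, sigma, span = 120, 0.1, 0.3
        x = np.linspace(0, 1, n)
        truth = 1.0 / (1 + np.exp(-(x - 0.5) / 0.15))
        y = truth + rng.normal(0, sigma, n)
        grid = np.linspace(0.2, 0.8, 50)  # interior points only
        fit = align.loess_smooth(x, y, grid, span=span)
        truth_g = 1.0 / (1 + np.exp(-(grid - 0.5) / 0.15))
        assert np.max(np.abs(fit - truth_g)) < 3 * sigma / np.sqrt(span * n)

    def test_too_few_points_named_error(self):
        with pytest.raises(PipelineError, match="MYPROT"):
            align.smooth_to_grid([1.0, 2.0], [0.0, 1.0], protein="MYPROT")


class TestPairwiseBestShift:
    def _sigmoid_grid(self, n=5000, center=0.5):
        g = np.linspace(0, 1, n)
        return 1.0 / (1 + np.exp(-(g - center) / 0.08))

    def test_identical_profiles_give_zero_shift(self):
        g = self._sigmoid_grid()
        res = align.pairwise_best_shift(g, g.copy())
        assert max(res.shift_lo, res.shift_up) <= 1.0 / 4999

    def test_constructed_shift_recovered(self):
        g = self._sigmoid_grid()
        shifted = np.roll(g, 250)
        shifted[:250] = g[0]
        res = align.pairwise_best_shift(g, shifted)
        # "lo" pairs the shifted profile's head with the reference's tail
        winner = res.shift_lo if res.corr_lo >= res.corr_up else res.shift_up
        assert winner == pytest.approx(250 / 5000, abs=2 / 4999)

    def test_anticorrelated_profiles_report_negative_corr(self):
        g = np.linspace(0, 1, 400)
        res = align.pairwise_best_shift(g, -g + np.sin(40 * g) * 0.01)
        assert res.corr_lo < 0 and res.corr_up < 0

    def test_swapping_profiles_swaps_directions(self):
        g = self._sigmoid_grid(2000)
        shifted = np.roll(g, 140)
        shifted[:140] = g[0]
        fwd = align.pairwise_best_shift(g, shifted)
        rev = align.pairwise_best_shift(shifted, g)
        assert fwd.lag_lo == rev.lag_up
        assert fwd.lag_up == rev.lag_lo


class TestMedianShiftAndApply:
    def _shifts(self, lo, up, n=4):
        return {
            ("R1", "R2"): pd.DataFrame(
                {
                    "shift_lo": np.full(n, float(lo)),
                    "shift_up": np.full(n, float(up)),
                    "corr_lo": 0.9,
                    "corr_up": 0.8,
                },
                index=[f"P{i}" for i in range(n)],
            )
        }

    def _ann(self):
        return align.relative_positions(
            toy_annotations({"R1": range(1, 6), "R2": range(1, 6)})
        )

    def test_equal_shifts_apply_directly(self):
        ann2, res = align.median_shift_and_apply(self._shifts(0.0, 0.1), self._ann(), "R1")
        r2 = ann2[ann2["replicate"] == "R2"]
        np.testing.assert_allclose(r2["perc2"], r2["perc"] + 0.1)
        r1 = ann2[ann2["replicate"] == "R1"]
        np.testing.assert_allclose(r1["perc2"], r1["perc"])
        assert res.winners[("R1", "R2")] == "up"

    def test_lo_direction_subtracts(self):
        ann2, res = align.median_shift_and_apply(self._shifts(0.2, 0.0), self._ann(), "R1")
        r2 = ann2[ann2["replicate"] == "R2"]
        np.testing.assert_allclose(r2["perc2"], r2["perc"] - 0.2)

    def test_median_robust_to_outlier(self):
        shifts = self._shifts(0.0, 0.1, n=3)
        shifts[("R1", "R2")].loc["P2", "shift_up"] = 0.4
        ann2, res = align.median_shift_and_apply(shifts, self._ann(), "R1")
        assert res.median_shift[("R1", "R2")]["up"] == pytest.approx(0.1)

    def test_reference_not_found(self):
        with pytest.raises(PipelineError, match="reference"):
            align.median_shift_and_apply(self._shifts(0, 0.1), self._ann(), "R9")

    def test_too_few_markers(self):
        with pytest.raises(ValidationError, match="3 marker"):
            align.median_shift_and_apply(self._shifts(0, 0.1, n=2), self._ann(), "R1")


class TestEndToEndShiftRecovery:
    @pytest.mark.parametrize("offsets", [(0.0, 0.05, -0.08), (0.0, 0.28, -0.15)])
    def test_planted_offsets_recovered(self, offsets):
        """Clean sigmoidal markers pin replicate offsets to within 0.01."""
        values, ann, truth = simulate.generate(
            n_proteins=12,
            n_slices_per_replicate=(90, 90, 90),
            archetype_weights=(1, 0, 0, 0),
            noise_sd=0.05,
            replicate_offsets=offsets,
            loading_decay=1.0,
            mcar_rate=0.0,
            mnar_midpoint=1e-3,
            seed=5,
        )
        profiles = np.log2(values)
        ann = align.relative_positions(ann)
        markers = list(values.index[:6])
        _, res = align.align_replicates(
            profiles, ann, markers, "S1", grid_n=5000, span=0.3
        )
        for (ref, other), winner in res.winners.items():
            med = res.median_shift[(ref, other)]
            recovered = -med["lo"] if winner == "lo" else med["up"]
            assert recovered == pytest.approx(
                truth.replicate_offsets[other], abs=0.01
            )


class TestFinalize:
    def _setup(self, rng):
        ann = toy_annotations({"A": range(1, 7), "B": range(1, 7)})
        ann = align.relative_positions(ann)
        ann["perc2"] = ann["perc"]
        vals = profile_frame(rng.normal(size=(5, 12)), ann)
        return vals, ann

    def test_range_variant_attains_bounds(self, rng):
        vals, ann = self._setup(rng)
        _, zr = align.finalize(vals, ann)
        assert np.allclose(zr.min(axis=1), 0.0)
        assert np.allclose(zr.max(axis=1), 1.0)

    def test_single_replicate_equals_plain_zscore(self, rng):
        ann = align.relative_positions(toy_annotations({"A": range(1, 9)}))
        ann["perc2"] = ann["perc"]
        vals = profile_frame(rng.normal(size=(3, 8)), ann)
        z, _ = align.finalize(vals, ann)
        arr = vals.to_numpy()
        expect = (arr - arr.mean(1, keepdims=True)) / arr.std(1, ddof=1, keepdims=True)
        np.testing.assert_allclose(z.to_numpy(), expect)

    def test_matches_two_step_oracle(self, rng):
        vals, ann = self._setup(rng)
        z, zr = align.finalize(vals, ann)
        for rep in ("A", "B"):
            cols = ann.index[ann["replicate"] == rep]
            block = vals[cols].to_numpy()
            expect = (block - block.mean(1, keepdims=True)) / block.std(
                1, ddof=1, keepdims=True
            )
            np.testing.assert_allclose(z[cols].to_numpy(), expect)
        zarr = z.to_numpy()
        rng01 = (zarr - zarr.min(1, keepdims=True)) / (
            zarr.max(1, keepdims=True) - zarr.min(1, keepdims=True)
        )
        np.testing.assert_allclose(zr.to_numpy(), rng01)

    def test_zero_variance_protein_dropped(self, rng):
        vals, ann = self._setup(rng)
        vals.iloc[2, :6] = 1.0  # constant within replicate A
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _ = align.finalize(vals, ann)
        assert "P2" not in z.index

    def test_columns_ordered_by_replicate_then_perc2(self, rng):
        vals, ann = self._setup(rng)
        ann.loc[ann["replicate"] == "B", "perc2"] = ann.loc[
            ann["replicate"] == "B", "perc"
        ] - 0.3
        shuffled = vals.sample(frac=1, axis=1, random_state=0)
        z, _ = align.finalize(shuffled, ann)
        key = ann.loc[list(z.columns)]
        assert list(z.columns) == list(
            key.sort_values(["replicate", "perc2"], kind="stable").index
        )
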