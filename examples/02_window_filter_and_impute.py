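"""Select locally well-observed proteins and impute the gaps.

An 11-slice window (about 200 um at 20 um thickness) slides along each
replicate; a protein is kept when its best window reaches a 70% data rate
on average across replicates.  Missing cells are then filled from
neighbouring slices by local least-squares lines, and whatever remains by
a draw from each slice's low-intensity tail.
"""

from slicenet import impute, preprocess, simulate, window_filter

values, ann, _ = simulate.generate(
    n_proteins=150, n_slices_per_replicate=(60, 56, 64), seed=1
)
floored = preprocess.floor_filter(values)
floored, ann = preprocess.drop_empty_samples(floored, ann)
profiles = preprocess.total_intensity_correct(preprocess.vst_normalize(floored), ann)

spec = window_filter.WindowSpec(after=10, max_na_fraction=0.3)
selected = window_filter.select_proteins(profiles, ann, spec)
print(f"{len(selected)} of {profiles.shape[0]} proteins pass the sliding-window filter")

sub = profiles.loc[selected]
n_missing = int(sub.isna().sum().sum())
linear = impute.impute_by_distance(sub, ann, impute.ImputeParams(rng_seed=1))
left = int(linear.isna().sum().sum())
full = impute.global_downshift_impute(linear, rng_seed=2)
print(f"{n_missing} missing cells: {n_missing - left} filled by local linear fits, "
      f"{left} by the per-slice low-tail draw")
print(f"final matrix complete: {not full.isna().any(axis=None)}")

# Local fits handle cells surrounded by data; the low-tail draw covers
# stretches where a protein is absent (true low abundance in that region).
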