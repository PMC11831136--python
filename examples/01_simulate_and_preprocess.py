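"""Generate a synthetic serial-section dataset and normalize it.

The generator mimics a sectioned muscle: smooth abundance trends along the
slice axis, shrinking per-slice protein input toward the tendon, and
intensity-dependent plus random dropout.  Preprocessing floors implausible
intensities, drops empty slices, variance-stabilizes, and makes profiles
relative to each slice's total protein input.
"""

import numpy as np

from slicenet import preprocess, simulate

values, ann, truth = simulate.generate(
    n_proteins=150, n_slices_per_replicate=(60, 56, 64), seed=1
)
print(f"raw matrix: {values.shape[0]} proteins x {values.shape[1]} slices, "
      f"{values.isna().to_numpy().mean():.1%} missing")

floored = preprocess.floor_filter(values)
floored, ann = preprocess.drop_empty_samples(floored, ann)
normalized = preprocess.vst_normalize(floored)
corrected = preprocess.total_intensity_correct(normalized, ann)
print(f"after 1e4 floor: {floored.isna().to_numpy().mean():.1%} missing")
print(f"normalized range: {np.nanmin(corrected.to_numpy()):.1f} .. "
      f"{np.nanmax(corrected.to_numpy()):.1f} (log2, relative to slice input)")

# The floor turns low-intensity cells into missing values; the corrected
# matrix is on a log2 scale where column loading differences are removed,
# so remaining structure reflects spatial trends, not section area.
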