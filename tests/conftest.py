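import numpy as np
import pandas as pd
import pytest


def toy_annotations(replicate_slices, prefix="PG.Quant"):
    """Annotation frame for {replicate: [slice, ...]} with standard names."""
    rows = []
    for rep, slices in replicate_slices.items():
        for s in slices:
            rows.append((f"{prefix}_{rep}_slice{s}", rep, int(s), False))
    ann = pd.DataFrame(
        rows, columns=["sample_id", "replicate", "slice", "is_control"]
    ).set_index("sample_id")
    ann["total_intensity"] = 1.0
    return ann[["replicate", "slice", "total_intensity", "is_control"]]


def profile_frame(arr, ann, proteins=None):
    """Wrap a (proteins x samples) array with the annotation's sample order."""
    arr = np.asarray(arr, dtype=float)
    if proteins is None:
        proteins = [f"P{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=proteins, columns=ann.index)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
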