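"""Synthetic serial-section datasets with known ground truth.

The generator emulates the structure of a sectioned-muscle experiment:
smooth spatial abundance trends along the slice axis (sigmoids at the
muscle-tendon junction, localized bumps, ramps, flat housekeeping
profiles), per-slice loading decay as the section area shrinks toward the
tendon, base abundances spanning several orders of magnitude,
intensity-dependent (MNAR) plus completely random (MCAR) dropout, and
replicate-specific axis offsets.  Every generated cell is reconstructable
from the recorded truth and seed, so recovery tests can compare pipeline
output against the parameters that produced the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError

ARCHETYPES = ("sigmoid", "bump", "ramp", "flat")


@dataclass
class SyntheticTruth:
    """Generative parameters of one synthetic dataset."""

    seed: int
    replicates: list
    n_slices: list
    archetypes: list  # one dict per protein: kind + parameters
    base_log2: list  # per-protein base abundance, log2
    replicate_offsets: dict  # replicate -> axis shift (fraction of [0,1])
    noise_sd: float
    loading: dict  # replicate -> per-slice loading factor
    mcar_rate: float
    mnar_midpoint: float
    mnar_scale: float
    masked_cells: list = field(default_factory=list)  # (protein, sample, kind)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _archetype_value(arch: dict, p: np.ndarray) -> np.ndarray:
    kind = arch["kind"]
    if kind == "sigmoid":
        return arch["amplitude"] / (1.0 + np.exp(-(p - arch["p0"]) / arch["width"]))
    if kind == "bump":
        return arch["amplitude"] * np.exp(-((p - arch["p0"]) ** 2) / (2 * arch["width"] ** 2))
    if kind == "ramp":
        return arch["slope"] * p
    if kind == "flat":
        return np.zeros_like(p)
    raise ValidationError(f"unknown archetype {kind!r}")


def _draw_archetype(rng, weights) -> dict:
    kind = rng.choice(ARCHETYPES, p=weights)
    if kind == "sigmoid":
        return {
            "kind": "sigmoid",
            "amplitude": float(rng.uniform(3.0, 5.0) * rng.choice([-1, 1])),
            "p0": float(rng.uniform(0.3, 0.7)),
            "width": float(rng.uniform(0.04, 0.1)),
        }
    if kind == "bump":
        return {
            "kind": "bump",
            "amplitude": float(rng.uniform(2.0, 4.0)),
            "p0": float(rng.uniform(0.2, 0.8)),
            "width": float(rng.uniform(0.05, 0.15)),
        }
    if kind == "ramp":
        return {"kind": "ramp", "slope": float(rng.uniform(2.0, 4.0) * rng.choice([-1, 1]))}
    return {"kind": "flat"}


def generate(
    n_proteins: int = 200,
    n_slices_per_replicate=(60, 56, 64),
    replicate_names=None,
    archetype_weights=(0.3, 0.2, 0.2, 0.3),
    noise_sd: float = 0.25,
    replicate_offsets=None,
    loading_decay: float = 0.12,
    mcar_rate: float = 0.05,
    mnar_midpoint: float = 1e4,
    mnar_scale: float = 1.0,
    base_log2_range=(17.0, 30.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a raw quantification matrix with annotations and truth.

    Raw intensity of protein i in slice k of replicate r is

        2 ** (archetype_i(perc + offset_r) + noise) * loading_r(k) * base_i

    followed by MNAR dropout (logistic in log2 intensity around
    ``mnar_midpoint``, steepness ``mnar_scale`` log2 units) and MCAR
    dropout at ``mcar_rate``.  ``loading_decay`` is the end-to-start ratio
    of the exponential per-slice loading curve (the shrinking section
    area); 1.0 disables the decay.  Deterministic for a fixed seed.
    """
    if n_proteins < 10:
        raise ValidationError("n_proteins must be >= 10")
    if any(n < 12 for n in n_slices_per_replicate):
        raise ValidationError("every replicate needs >= 12 slices (one full window)")
    if loading_decay <= 0 or noise_sd < 0 or not 0 <= mcar_rate < 1:
        raise ValidationError("infeasible generator parameters")
    weights = np.asarray(archetype_weights, dtype=float)
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    if replicate_names is None:
        replicate_names = [f"S{i+1}" for i in range(len(n_slices_per_replicate))]
    if replicate_offsets is None:
        offsets = {r: 0.0 for r in replicate_names}
    elif isinstance(replicate_offsets, dict):
        offsets = {r: float(replicate_offsets.get(r, 0.0)) for r in replicate_names}
    else:
        offsets = {r: float(o) for r, o in zip(replicate_names, replicate_offsets)}

    archetypes = [_draw_archetype(rng, weights) for _ in range(n_proteins)]
    for arch in archetypes:
        if arch.get("width", 1.0) <= 0:
            raise ValidationError("archetype widths must be positive")
    base_log2 = rng.uniform(*base_log2_range, size=n_proteins)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]

    columns, records, loading = [], [], {}
    blocks = []
    for rep, n_slices in zip(replicate_names, n_slices_per_replicate):
        slices = np.arange(1, n_slices + 1)
        perc = (slices - 1) / (n_slices - 1)
        load = loading_decay ** (perc)  # geometric decay to loading_decay
        loading[rep] = load.tolist()
        signal = np.stack(
            [_archetype_value(a, perc + offsets[rep]) for a in archetypes]
        )  # (proteins, slices)
        noise = rng.normal(0.0, noise_sd, size=signal.shape)
        raw = 2.0 ** (signal + noise + base_log2[:, None]) * load[None, :]
        blocks.append(raw)
        for k in slices:
            name = f"PG.Quant_{rep}_slice{k}"
            columns.append(name)
            records.append((name, rep, int(k), False))

    raw = np.concatenate(blocks, axis=1)
    values = pd.DataFrame(raw, index=proteins, columns=columns)
    values.index.name = "protein"

    # intensity-dependent dropout, then completely-random dropout
    with np.errstate(divide="ignore"):
        logi = np.log2(raw)
    p_mnar = 1.0 / (1.0 + np.exp((logi - np.log2(mnar_midpoint)) / mnar_scale))
    u = rng.random(raw.shape)
    mnar_mask = u < p_mnar
    mcar_mask = rng.random(raw.shape) < mcar_rate

    masked = []
    arr = values.to_numpy()
    for i, j in zip(*np.nonzero(mnar_mask | mcar_mask)):
        kind = "mnar" if mnar_mask[i, j] else "mcar"
        masked.append([proteins[i], columns[j], kind])
        arr[i, j] = np.nan
    values = pd.DataFrame(arr, index=proteins, columns=columns)

    ann = pd.DataFrame(
        records, columns=["sample_id", "replicate", "slice", "is_control"]
    ).set_index("sample_id")
    ann["total_intensity"] = values.fillna(0.0).sum(axis=0)
    ann = ann[["replicate", "slice", "total_intensity", "is_control"]]

    truth = SyntheticTruth(
        seed=seed,
        replicates=list(replicate_names),
        n_slices=list(n_slices_per_replicate),
        archetypes=archetypes,
        base_log2=base_log2.tolist(),
        replicate_offsets=offsets,
        noise_sd=noise_sd,
        loading={k: v for k, v in loading.items()},
        mcar_rate=mcar_rate,
        mnar_midpoint=mnar_midpoint,
        mnar_scale=mnar_scale,
        masked_cells=masked,
    )
    return values, ann, truth


def plant_delay_chain(
    base_profile,
    delays,
    noise_sd: float = 0.0,
    seed: int = 0,
    names=None,
) -> tuple[pd.DataFrame, dict]:
    """Shifted copies of a profile with known pairwise delays.

    ``delays[k]`` shifts copy k+1 relative to copy k by that many grid
    units (positive = displaced toward larger positions, edges held).
    Returns the profile matrix and the truth dict of cumulative shifts.
    Shifts close to half the profile length are not reliably recoverable.
    """
    base = np.asarray(base_profile, dtype=float)
    n = base.size
    cum = np.concatenate([[0], np.cumsum(np.asarray(delays, dtype=int))])
    if np.any(np.abs(cum) >= n):
        raise ValidationError("shifts must stay small relative to the profile")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"C{k}" for k in range(cum.size)]
    rows = {}
    for name, s in zip(names, cum):
        idx = np.clip(np.arange(n) - s, 0, n - 1)
        rows[name] = base[idx] + rng.normal(0.0, noise_sd, size=n)
    profiles = pd.DataFrame(rows).T
    truth = {"cumulative_shifts": dict(zip(names, cum.tolist()))}
    return profiles, truth
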