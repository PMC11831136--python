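"""End-to-end orchestration of the profile pipeline.

Stages run in a fixed order, each persisting its artifact into the output
directory so any stage can be re-run from its predecessor's output:

  preprocess -> filter -> impute -> markers -> align -> network

Every source of randomness is seeded from the single run seed (per-stage
seeds are derived deterministically), so a rerun with the same config and
seed is bit-identical, and a stopped run resumed from disk equals a single
uninterrupted run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as align_mod
from . import impute as impute_mod
from . import io as io_mod
from . import network as net_mod
from . import preprocess as pre_mod
from . import simulate as sim_mod
from . import spatial_stats as stats_mod
from . import window_filter as win_mod
from .errors import PipelineError

logger = logging.getLogger(__name__)

STAGES = ["preprocess", "filter", "impute", "markers", "align", "network"]


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run, serialized into the run log."""

    out_dir: str = "slicenet_out"
    seed: int = 0
    # input: either a quantification table on disk or generator settings
    input_path: str | None = None
    quant_block: str = "PG.Quant"
    control_regex: str | None = None
    simulate: dict | None = None
    # preprocess
    floor: float = pre_mod.DEFAULT_FLOOR
    normalization: str = "vst"  # or "log2-median"
    trim_fraction: float = 0.1
    # window filter
    window_after: int = 10
    window_max_na_fraction: float = 0.3
    # impute
    impute_width_forward: int = 10
    impute_width_backward: int = 10
    impute_min_data_required: int = 3
    impute_fallback: str = "none"
    impute_sel: float = 0.05
    impute_m_offset: float = 1.6
    impute_sd_offset: float = 0.8
    # markers
    sam_nperms: int = 1000
    marker_min_abs_mean: float = 5.0
    trend_method: str = "sam"  # or "tslope"
    # align
    align_grid_n: int = 5000
    align_span: float = 0.75
    reference_replicate: str | None = None  # default: first replicate
    # network
    network_delay_limit: int = net_mod.DEFAULT_DELAY_LIMIT
    network_dpi_tolerance: float = net_mod.DEFAULT_DPI_TOLERANCE
    network_method: str = "spearman"
    network_delayt_fraction: float = net_mod.DEFAULT_DELAYT_FRACTION
    network_max_proteins: int | None = 60
    slice_thickness_um: float | None = None

    def stage_seed(self, tag: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        offsets = {"simulate": 0, "impute": 1, "downshift": 2, "sam": 3}
        return (self.seed * 1_000_003 + offsets[tag] + 17) % (2**31)


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def _read_matrix(path: Path) -> pd.DataFrame:
    # round_trip parsing keeps resumed runs bit-identical to uninterrupted ones
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def _write_ann(ann: pd.DataFrame, path: Path) -> None:
    ann.to_csv(path, sep="\t")


def _read_ann(path: Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ann["replicate"] = ann["replicate"].astype(str)
    return ann


def _load_input(config: PipelineConfig):
    if config.simulate is not None:
        params = dict(config.simulate)
        params.setdefault("seed", config.stage_seed("simulate"))
        values, ann, _truth = sim_mod.generate(**params)
        return values, ann
    if config.input_path is None:
        raise PipelineError("config needs either input_path or simulate parameters")
    return io_mod.read_quant_table(
        config.input_path, block=config.quant_block, control_regex=config.control_regex
    )


def run_pipeline(
    config: PipelineConfig, stop_after: str | None = None, resume: bool = False
) -> dict:
    """Execute the pipeline, returning a dict of artifact paths.

    ``stop_after`` halts after the named stage; ``resume=True`` loads any
    stage whose artifacts already exist in ``out_dir`` instead of
    recomputing it.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise PipelineError(f"unknown stage {stop_after!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "normalized": out / "normalized.tsv",
        "annotations": out / "annotations.tsv",
        "window_scores": out / "window_scores.tsv",
        "selected": out / "selected_proteins.txt",
        "imputed": out / "imputed.tsv",
        "marker_scores": out / "marker_scores.tsv",
        "markers": out / "markers.txt",
        "annotations_aligned": out / "annotations_aligned.tsv",
        "alignment_report": out / "alignment_report.tsv",
        "final_z": out / "final_z.tsv",
        "final_zr": out / "final_zr.tsv",
        "edges_unpruned": out / "edges_unpruned.csv",
        "edges": out / "edges.csv",
        "run_log": out / "run_log.json",
    }
    log: dict = {"config": dataclasses.asdict(config), "stages": {}}
    state: dict = {}

    def done(stage: str) -> bool:
        files = {
            "preprocess": ["normalized", "annotations"],
            "filter": ["selected", "window_scores"],
            "impute": ["imputed"],
            "markers": ["marker_scores", "markers"],
            "align": ["annotations_aligned", "final_z", "final_zr", "alignment_report"],
            "network": ["edges", "edges_unpruned"],
        }[stage]
        return all(paths[k].exists() for k in files)

    for stage in STAGES:
        if resume and done(stage):
            logger.info("stage %s: loading artifacts", stage)
            _load_stage(stage, state, paths)
        else:
            logger.info("stage %s: running", stage)
            try:
                _run_stage(stage, state, paths, config, log)
            except Exception:
                logger.error("stage %s failed; last good artifacts kept", stage)
                raise
        if stage == stop_after:
            break

    with open(paths["run_log"], "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}


def _load_stage(stage: str, state: dict, paths: dict) -> None:
    if stage == "preprocess":
        state["normalized"] = _read_matrix(paths["normalized"])
        state["ann"] = _read_ann(paths["annotations"])
    elif stage == "filter":
        state["selected"] = paths["selected"].read_text().split()
    elif stage == "impute":
        state["imputed"] = _read_matrix(paths["imputed"])
    elif stage == "markers":
        state["markers"] = paths["markers"].read_text().split()
    elif stage == "align":
        state["ann_aligned"] = _read_ann(paths["annotations_aligned"])
        state["final_z"] = _read_matrix(paths["final_z"])
        state["final_zr"] = _read_matrix(paths["final_zr"])
    elif stage == "network":
        state["edges"] = io_mod.read_edge_list(paths["edges"])


def _run_stage(
    stage: str, state: dict, paths: dict, config: PipelineConfig, log: dict
) -> None:
    if stage == "preprocess":
        values, ann = _load_input(config)
        n_raw = values.shape
        values = pre_mod.floor_filter(values, config.floor)
        values, ann = pre_mod.drop_empty_samples(values, ann)
        keep = ~ann["is_control"]
        dropped = list(ann.index[~keep])
        for name in dropped:
            logger.info("dropping control sample %s", name)
        values, ann = values[ann.index[keep]], ann[keep]
        if config.normalization == "vst":
            normalized = pre_mod.vst_normalize(values, config.trim_fraction)
        elif config.normalization == "log2-median":
            normalized = pre_mod.log2_median_normalize(values)
        else:
            raise PipelineError(f"unknown normalization {config.normalization!r}")
        normalized = pre_mod.total_intensity_correct(normalized, ann)
        state["normalized"], state["ann"] = normalized, ann
        _write_matrix(normalized, paths["normalized"])
        _write_ann(ann, paths["annotations"])
        log["stages"]["preprocess"] = {
            "proteins_in": n_raw[0],
            "samples_in": n_raw[1],
            "samples_out": normalized.shape[1],
            "controls_dropped": dropped,
        }
    elif stage == "filter":
        spec = win_mod.WindowSpec(
            after=config.window_after, max_na_fraction=config.window_max_na_fraction
        )
        scores = win_mod.replicate_window_scores(state["normalized"], state["ann"], spec)
        selected = win_mod.select_proteins(state["normalized"], state["ann"], spec)
        if not selected:
            raise PipelineError("no proteins pass the sliding-window data-rate filter")
        state["selected"] = selected
        scores.to_csv(paths["window_scores"], sep="\t")
        paths["selected"].write_text("\n".join(selected) + "\n")
        log["stages"]["filter"] = {
            "proteins_in": state["normalized"].shape[0],
            "proteins_selected": len(selected),
        }
    elif stage == "impute":
        params = impute_mod.ImputeParams(
            width_forward=config.impute_width_forward,
            width_backward=config.impute_width_backward,
            min_data_required=config.impute_min_data_required,
            fallback=config.impute_fallback,
            sel=config.impute_sel,
            m_offset=config.impute_m_offset,
            sd_offset=config.impute_sd_offset,
            rng_seed=config.stage_seed("impute"),
        )
        sub = state["normalized"].loc[state["selected"]]
        n_missing_before = int(sub.isna().sum().sum())
        imputed = impute_mod.impute_by_distance(sub, state["ann"], params)
        n_after_linear = int(imputed.isna().sum().sum())
        imputed = impute_mod.global_downshift_impute(
            imputed, sel=config.impute_sel, rng_seed=config.stage_seed("downshift")
        )
        state["imputed"] = imputed
        _write_matrix(imputed, paths["imputed"])
        log["stages"]["impute"] = {
            "missing_before": n_missing_before,
            "imputed_linear": n_missing_before - n_after_linear,
            "imputed_downshift": n_after_linear,
        }
    elif stage == "markers":
        ann = state["ann"]
        d_scores = {}
        for rep in sorted(ann["replicate"].unique()):
            sub = ann[ann["replicate"] == rep].sort_values("slice", kind="stable")
            res = stats_mod.sam_quant_scores(
                state["imputed"][sub.index],
                sub["slice"].to_numpy(),
                nperms=config.sam_nperms,
                rng_seed=config.stage_seed("sam"),
                method=config.trend_method,
            )
            d_scores[rep] = res.scores["d"]
        table, markers = stats_mod.combine_scores(
            d_scores, min_abs_mean=config.marker_min_abs_mean
        )
        state["markers"] = markers
        table.to_csv(paths["marker_scores"], sep="\t")
        paths["markers"].write_text("\n".join(markers) + "\n")
        log["stages"]["markers"] = {"n_markers": len(markers)}
    elif stage == "align":
        ann = align_mod.relative_positions(state["ann"])
        reference = config.reference_replicate or sorted(ann["replicate"].unique())[0]
        ann2, result = align_mod.align_replicates(
            state["imputed"],
            ann,
            state["markers"],
            reference,
            grid_n=config.align_grid_n,
            span=config.align_span,
        )
        z, zr = align_mod.finalize(state["imputed"], ann2)
        state["ann_aligned"], state["final_z"], state["final_zr"] = ann2, z, zr
        _write_ann(ann2, paths["annotations_aligned"])
        _write_matrix(z, paths["final_z"])
        _write_matrix(zr, paths["final_zr"])
        report = []
        for pair, table in result.per_protein_shifts.items():
            t = table.copy()
            t.insert(0, "pair", f"{pair[0]}-{pair[1]}")
            t.insert(1, "winner", result.winners[pair])
            report.append(t)
        pd.concat(report).to_csv(paths["alignment_report"], sep="\t")
        log["stages"]["align"] = {
            "reference": reference,
            "median_shift": json.loads(result.median_shift.to_json())
            if result.median_shift is not None
            else None,
        }
    elif stage == "network":
        zr = state["final_zr"]
        if (
            config.network_max_proteins is not None
            and zr.shape[0] > config.network_max_proteins
        ):
            # rank by profile variability so the pairwise scan stays tractable
            spread = zr.std(axis=1).sort_values(ascending=False, kind="stable")
            zr = zr.loc[sorted(spread.index[: config.network_max_proteins])]
        edges, pruned = net_mod.infer_network(
            zr,
            delay_limit=config.network_delay_limit,
            dpi_tolerance=config.network_dpi_tolerance,
            method=config.network_method,
            delayt_fraction=config.network_delayt_fraction,
        )
        if config.slice_thickness_um is not None:
            pruned = pruned.copy()
            pruned["delay_um"] = pruned["delay"] * config.slice_thickness_um
        state["edges"] = pruned
        io_mod.write_edge_list(edges, paths["edges_unpruned"])
        cols = io_mod.EDGE_COLUMNS + (
            ["delay_um"] if "delay_um" in pruned.columns else []
        )
        out_edges = pruned[cols]
        if "delay_um" in out_edges.columns:
            tmp = out_edges.copy()
            tmp.index = tmp["source"] + "-" + tmp["target"]
            tmp.to_csv(paths["edges"], index_label="", quoting=3)
        else:
            io_mod.write_edge_list(out_edges, paths["edges"])
        log["stages"]["network"] = {
            "proteins": zr.shape[0],
            "edges_before_dpi": len(edges),
            "edges_after_dpi": len(pruned),
        }
    else:  # pragma: no cover
        raise PipelineError(f"unknown stage {stage!r}")
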