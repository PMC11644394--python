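"""End-to-end run: generate/load -> filter -> segment -> metrics ->
aggregate -> agreement, with per-stage record counts and CSV outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import filters, metrics, segmentation
from .series import DEVICE, REFERENCE, PairedNight, read_cohort
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger("hrvgate")

LEVELS = ("5min", "30min", "night")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``input_mode`` is "synthetic" (generate a cohort from ``sim``) or
    "csv" (read a cohort manifest from ``input_dir``). All randomness
    flows from ``seed``, which overrides ``sim.seed``.
    """

    input_mode: str = "synthetic"
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None
    thresholds: tuple[float, ...] = segmentation.DEFAULT_THRESHOLDS
    levels: tuple[str, ...] = LEVELS
    hf_band: tuple[float, float] = metrics.HF_BAND
    lf_band: tuple[float, float] = metrics.LF_BAND
    ls_oversample: int = metrics.LS_OVERSAMPLE
    min_spectral_samples: int = metrics.MIN_SPECTRAL_SAMPLES
    plaus_low_ms: float = filters.PLAUSIBLE_LOW_MS
    plaus_high_ms: float = filters.PLAUSIBLE_HIGH_MS
    neighbor_span: int = filters.NEIGHBOR_SPAN
    max_rel_change: float = filters.MAX_REL_CHANGE
    ref_min_nn: int = segmentation.REFERENCE_MIN_NN
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "csv"):
            raise ValueError("input_mode must be 'synthetic' or 'csv'")
        thr = tuple(self.thresholds)
        if len(set(thr)) != len(thr) or list(thr) != sorted(thr):
            raise ValueError("thresholds must be sorted and unique")
        for t in thr:
            if not 0.0 < t <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")
        for lvl in self.levels:
            if lvl not in LEVELS:
                raise ValueError(f"unknown level {lvl!r}")


@dataclass
class RunResult:
    status: str  # "ok" | "empty"
    config: RunConfig
    segments: pd.DataFrame
    metrics_5min: pd.DataFrame
    paired: pd.DataFrame
    summary: pd.DataFrame
    errors: pd.DataFrame
    heatmap: pd.DataFrame
    retention: pd.DataFrame
    counts: dict
    rejected_files: list[str]


def _night_frames(night: PairedNight, cfg: RunConfig):
    """Masks, grid, assignments, validity and per-window metrics for one
    paired night. Metrics are threshold-independent, so they are computed
    once here and gated later."""
    grid = segmentation.make_grid(night.device.tib_s)
    qc = filters.device_quality_mask(
        night.device,
        low_ms=cfg.plaus_low_ms,
        high_ms=cfg.plaus_high_ms,
        span=cfg.neighbor_span,
    )
    ref_mask = filters.filter_reference_nn(
        night.reference,
        low_ms=cfg.plaus_low_ms,
        high_ms=cfg.plaus_high_ms,
        max_rel_change=cfg.max_rel_change,
    )
    dev_ok = qc.final_ok
    ref_ok = ref_mask.final_ok
    dev_assign = segmentation.assign_intervals(night.device, grid)
    ref_assign = segmentation.assign_intervals(night.reference, grid)
    dev_prop = segmentation.validity_proportion(night.device, dev_assign, dev_ok, grid)
    ref_counts = segmentation.valid_counts(ref_assign, ref_ok, grid)

    mkw = dict(
        hf_band=cfg.hf_band,
        lf_band=cfg.lf_band,
        oversample=cfg.ls_oversample,
        min_spectral_samples=cfg.min_spectral_samples,
    )
    dev_metrics = metrics.night_metrics_table(
        night.participant_id,
        DEVICE,
        dev_assign,
        night.device.intervals,
        night.device.interval_end_times,
        dev_ok,
        grid,
        **mkw,
    )
    ref_metrics = metrics.night_metrics_table(
        night.participant_id,
        REFERENCE,
        ref_assign,
        night.reference.intervals,
        night.reference.interval_end_times,
        ref_ok,
        grid,
        **mkw,
    )
    counts = {
        "participant_id": night.participant_id,
        "group": night.group,
        "n_windows": grid.n_windows,
        "device": {
            **qc.stage_counts(),
            "n_dropped_outside_tib": dev_assign.n_dropped,
        },
        "reference": {
            "n_intervals": int(ref_ok.size),
            "final_ok": int(ref_ok.sum()),
            "n_dropped_outside_tib": ref_assign.n_dropped,
        },
    }
    return {
        "grid": grid,
        "dev_prop": dev_prop,
        "ref_counts": ref_counts,
        "dev_assign": dev_assign,
        "ref_assign": ref_assign,
        "dev_ok": dev_ok,
        "ref_ok": ref_ok,
        "dev_metrics": dev_metrics,
        "ref_metrics": ref_metrics,
        "counts": counts,
    }


def _paired_rows_for_night(
    night: PairedNight, frames: dict, cfg: RunConfig
) -> tuple[list[dict], dict]:
    """Paired metric rows at every level x threshold for one night."""
    grid = frames["grid"]
    ref_flags = segmentation.accept_reference_segment(
        frames["ref_counts"], cfg.ref_min_nn
    )
    ref_night_ok = segmentation.accept_night(ref_flags, REFERENCE, grid.n_windows)
    dev = frames["dev_metrics"].set_index("window_idx")
    ref = frames["ref_metrics"].set_index("window_idx")
    rows: list[dict] = []
    night_counts = {"reference_night_accepted": bool(ref_night_ok), "thresholds": {}}
    for thr in cfg.thresholds:
        dev_flags = segmentation.accept_device_segment(frames["dev_prop"], thr)
        dev_night_ok = segmentation.accept_night(dev_flags, DEVICE)
        paired_windows = segmentation.pair_segments(dev_flags, ref_flags)
        night_counts["thresholds"][thr] = {
            "device_segments_accepted": int(dev_flags.sum()),
            "device_night_accepted": bool(dev_night_ok),
            "paired_segments": int(paired_windows.size),
        }
        if not (dev_night_ok and ref_night_ok) or paired_windows.size == 0:
            continue
        base = {
            "participant_id": night.participant_id,
            "group": night.group,
            "threshold": thr,
        }
        for metric in metrics.METRIC_COLUMNS:
            dv = dev.loc[paired_windows, metric].to_numpy(dtype=float)
            rv = ref.loc[paired_windows, metric].to_numpy(dtype=float)
            ok = np.isfinite(dv) & np.isfinite(rv)
            widx = paired_windows[ok]
            dv, rv = dv[ok], rv[ok]
            if "5min" in cfg.levels:
                for w, d, r in zip(widx, dv, rv):
                    rows.append(
                        {
                            **base,
                            "level": "5min",
                            "metric": metric,
                            "window_idx": int(w),
                            "device_value": d,
                            "reference_value": r,
                        }
                    )
            for level in ("30min", "night"):
                if level not in cfg.levels:
                    continue
                agg_d = metrics.aggregate(widx, dv, level)
                agg_r = metrics.aggregate(widx, rv, level)
                for key in agg_d:
                    rows.append(
                        {
                            **base,
                            "level": level,
                            "metric": metric,
                            "window_idx": key,
                            "device_value": agg_d[key],
                            "reference_value": agg_r[key],
                        }
                    )
    return rows, night_counts


def _retention_table(per_night: list[dict], cfg: RunConfig) -> pd.DataFrame:
    """Device 5-min segment retention per group x threshold (percent of
    all grid windows passing the validity proportion threshold)."""
    rows = []
    groups = sorted({n["group"] for n in per_night})
    for group in groups + ["all"]:
        sel = [n for n in per_night if group in ("all", n["group"])]
        initial = sum(n["n_windows"] for n in sel)
        row = {"group": group, "initial_segments": initial}
        for thr in cfg.thresholds:
            kept = sum(
                n["thresholds"][thr]["device_segments_accepted"] for n in sel
            )
            row[f"retention_pct_{int(round(thr * 100))}"] = (
                100.0 * kept / initial if initial else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; deterministic under a fixed seed."""
    rejected: list[str] = []
    if config.input_mode == "synthetic":
        sim = config.sim
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        cohort = generate_cohort(sim)
    else:
        if not config.input_dir:
            raise ValueError("csv input mode needs input_dir")
        cohort, rejected = read_cohort(config.input_dir, collect_errors=True)
        for msg in rejected:
            logger.warning("rejected input: %s", msg)
    logger.info("cohort: %d paired nights", len(cohort))

    seg_tables, metric_tables, paired_rows, night_counts = [], [], [], []
    for night in cohort:
        try:
            frames = _night_frames(night, config)
        except ValueError as exc:
            rejected.append(f"{night.participant_id}: {exc}")
            logger.warning("rejected night %s: %s", night.participant_id, exc)
            continue
        seg_tables.append(
            segmentation.segment_table(
                night.device,
                frames["dev_assign"],
                frames["dev_ok"],
                frames["grid"],
                config.thresholds,
            )
        )
        seg_tables.append(
            segmentation.segment_table(
                night.reference,
                frames["ref_assign"],
                frames["ref_ok"],
                frames["grid"],
                config.thresholds,
            )
        )
        metric_tables.extend([frames["dev_metrics"], frames["ref_metrics"]])
        rows, counts = _paired_rows_for_night(night, frames, config)
        paired_rows.extend(rows)
        counts = {**frames["counts"], **counts}
        dc = counts["device"]
        assert dc["final_ok"] + (dc["n_intervals"] - dc["final_ok"]) == dc[
            "n_intervals"
        ], "count conservation violated"
        night_counts.append(counts)
        logger.info(
            "%s: %d device intervals (%d valid), %d reference (%d valid)",
            night.participant_id,
            dc["n_intervals"],
            dc["final_ok"],
            counts["reference"]["n_intervals"],
            counts["reference"]["final_ok"],
        )

    paired = pd.DataFrame(paired_rows, columns=agr.PAIRED_COLUMNS)
    if paired.empty:
        result = RunResult(
            status="empty",
            config=config,
            segments=pd.concat(seg_tables, ignore_index=True)
            if seg_tables
            else pd.DataFrame(),
            metrics_5min=pd.concat(metric_tables, ignore_index=True)
            if metric_tables
            else pd.DataFrame(),
            paired=paired,
            summary=pd.DataFrame(),
            errors=pd.DataFrame(),
            heatmap=pd.DataFrame(),
            retention=_retention_table(night_counts, config)
            if night_counts
            else pd.DataFrame(),
            counts={"nights": night_counts},
            rejected_files=rejected,
        )
        logger.warning("no nights survived quality control")
    else:
        errors = agr.participant_errors(paired)
        result = RunResult(
            status="ok",
            config=config,
            segments=pd.concat(seg_tables, ignore_index=True),
            metrics_5min=pd.concat(metric_tables, ignore_index=True),
            paired=paired,
            summary=agr.summarize(paired),
            errors=errors,
            heatmap=agr.mdape_heatmap(errors),
            retention=_retention_table(night_counts, config),
            counts={"nights": night_counts},
            rejected_files=rejected,
        )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.segments.to_csv(out / "segments.csv", index=False)
    result.metrics_5min.to_csv(out / "metrics_5min.csv", index=False)
    result.paired.to_csv(out / "paired.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    result.errors.to_csv(out / "participant_errors.csv", index=False)
    if not result.heatmap.empty:
        result.heatmap.to_csv(out / "mdape_heatmap.csv")
    result.retention.to_csv(out / "retention.csv", index=False)

    def _jsonable(obj):
        if isinstance(obj, dict):
            return {str(k): _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating, np.bool_)):
            return obj.item()
        return obj

    log = {
        "status": result.status,
        "rejected": result.rejected_files,
        "counts": _jsonable(result.counts),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
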