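"""End-to-end orchestration of the analysis stages from a configuration.

Each ``run_*`` function takes a plain configuration mapping (normally loaded
from YAML), executes the stage chain, optionally writes the intermediate
tables to an output directory, and returns the stage result.  Runs are
deterministic given the configuration and seed.  Stage failures are
re-raised as :class:`PipelineError` with the stage name attached.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, frap, imaging_io, puncta, segmentation, synthetic_data, tracking
from .imaging_io import Movie, logger

__all__ = ["PipelineError", "segment_movie", "run_mito", "run_frap", "run_puncta"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


def _out_dir(config: dict, out_dir) -> Path | None:
    d = out_dir or config.get("output_dir")
    if d is None:
        return None
    p = Path(d)
    p.mkdir(parents=True, exist_ok=True)
    return p


def segment_movie(movie: Movie, mode: str = "midgrey",
                  params: dict | None = None) -> list[list[segmentation.Centerline]]:
    """Per-frame centerlines via the configured segmentation route.

    ``mode`` is ``"midgrey"`` (adaptive local threshold + medial axis, for
    fragmented morphologies) or ``"ridge"`` (Hessian tubeness tracing, for
    tubular networks).
    """
    p = dict(params or {})
    out = []
    for f in range(movie.n_frames):
        frame = movie.frames[f]
        if mode == "midgrey":
            mask = segmentation.midgrey_threshold(
                frame, radius=p.get("radius", 15),
                offset=p.get("offset", 0.0),
                min_contrast=p.get("min_contrast", 40.0))
            mask = segmentation.clean_mask(mask, p.get("min_area_px", 9))
            cls = segmentation.medial_axis_centerlines(
                mask, intensity=frame, pixel_size_um=movie.pixel_size_um,
                frame=f, spur_length_px=p.get("spur_length_px", 4.0))
        elif mode == "ridge":
            cls = segmentation.ridge_centerlines(
                frame, tubule_sigma_px=p.get("tubule_sigma_px", 1.5),
                response_threshold=p.get("response_threshold", 0.08),
                min_area_px=p.get("min_area_px", 9),
                pixel_size_um=movie.pixel_size_um, frame=f,
                spur_length_px=p.get("spur_length_px", 4.0))
        else:
            raise PipelineError("segmentation", f"unknown mode {mode!r}")
        out.append(cls)
    return out


def _load_movie(config: dict, seed: int | None):
    inp = config.get("input", {})
    if "preset" in inp:
        preset = synthetic_data.MITO_PRESETS[inp["preset"]]
        s = seed if seed is not None else inp.get("seed", 0)
        movie, truth = synthetic_data.generate_mito_movie(
            preset, n_frames=inp.get("n_frames", 8), seed=s)
        return movie, truth
    if "path" in inp:
        movie = imaging_io.read_stack(inp["path"],
                                      pixel_size_um=inp.get("pixel_size_um"),
                                      time_step_s=inp.get("time_step_s"))
        return movie, None
    raise PipelineError("input", "config must give input.preset or input.path")


def run_mito(config: dict, seed: int | None = None, out_dir=None) -> dict:
    """Segmentation -> tracking -> dynamics on one movie.

    Returns ``{"summary": DynamicsSummary, "tracks": ..., "truth": ...}``;
    writes objects.csv, tracks.csv and summary.json when an output directory
    is configured.
    """
    movie, truth = _load_movie(config, seed)
    seg_cfg = config.get("segmentation", {})
    mode = seg_cfg.get("mode", "midgrey")
    per_frame = segment_movie(movie, mode=mode, params=seg_cfg)
    records = {f: tracking.centroids(cls) for f, cls in enumerate(per_frame)}
    n_objects = sum(len(v) for v in records.values())
    if n_objects == 0:
        raise PipelineError("segmentation", "no objects segmented")
    trk_cfg = config.get("tracking", {})
    tracks = tracking.link(records,
                           max_disp_px=trk_cfg.get("max_disp_px", 20.0),
                           memory_frames=trk_cfg.get("memory_frames", 2))
    dyn_cfg = config.get("dynamics", {})
    try:
        summary = dynamics.summarize(tracks, movie.pixel_size_um,
                                     min_track_len=dyn_cfg.get("min_track_len", 3))
    except ValueError as e:
        raise PipelineError("dynamics", str(e)) from e
    logger.info("mito pipeline: %d objects, %d tracks, median dynamic range %.1f%%",
                n_objects, len(tracks),
                summary.median("dynamic_range_pct"))
    d = _out_dir(config, out_dir)
    if d is not None:
        obj_rows = [(f, i, c.length_um, *c.centroid())
                    for f, cls in enumerate(per_frame)
                    for i, c in enumerate(cls)]
        pd.DataFrame(obj_rows, columns=["frame", "object", "length_um",
                                        "y", "x"]).to_csv(
            d / "objects.csv", index=False)
        tracking.tracks_to_table(tracks).to_csv(d / "tracks.csv", index=False)
        with open(d / "summary.json", "w") as fh:
            json.dump({"condition": summary.condition,
                       "n_tracks": len(tracks),
                       "n_excluded_short": summary.n_excluded_short,
                       "mode": mode}, fh, indent=2)
        summary.per_track.to_csv(d / "per_track.csv", index=False)
    return {"summary": summary, "tracks": tracks, "movie": movie, "truth": truth}


def run_frap(config: dict, seed: int | None = None, out_dir=None) -> pd.DataFrame:
    """Fit every configured FRAP curve; returns one row per series."""
    inp = config.get("input", {})
    t_eval = config.get("frap", {}).get("t_eval_s", 900.0)
    curves: list[tuple[str, frap.FrapCurve]] = []
    if "preset" in inp:
        preset = synthetic_data.FRAP_PRESETS[inp["preset"]]
        n = inp.get("n_series", 20)
        base = seed if seed is not None else inp.get("seed", 0)
        for i in range(n):
            c, _ = synthetic_data.generate_frap_series_from_preset(
                preset, seed=(base * 1000003 + i) % 2**31)
            curves.append((f"{preset.name}_{i}", c))
    elif "curves" in inp:
        for path in inp["curves"]:
            curves.append((Path(path).stem, frap.read_curve_csv(path)))
    else:
        raise PipelineError("input", "config must give input.preset or input.curves")
    rows = []
    for name, c in curves:
        try:
            c.bleach_index = frap.detect_bleach(c)
            fit = frap.fit_recovery(c)
            rec = frap.recovery_percent(c, t_eval)
        except ValueError as e:
            raise PipelineError("frap", f"{name}: {e}") from e
        rows.append({"series": name, **fit.as_dict(),
                     f"recovery_pct_at_{int(t_eval)}s": rec})
    df = pd.DataFrame(rows)
    d = _out_dir(config, out_dir)
    if d is not None:
        df.to_csv(d / "frap_fits.csv", index=False)
    return df


def run_puncta(config: dict, seed: int | None = None, out_dir=None) -> dict:
    """Score one or two puncta conditions; two conditions also yield the
    fold change of condition B over condition A."""
    from scipy import stats

    det = config.get("puncta", {})
    conditions = config.get("conditions")
    if conditions is None:
        raise PipelineError("input", "config must give a conditions mapping")
    results: dict[str, puncta.PunctaResult] = {}
    base = seed if seed is not None else config.get("seed", 0)
    for k, (name, spec) in enumerate(conditions.items()):
        if "preset_counts" in spec:
            cd = spec["preset_counts"]
            dist = cd if isinstance(cd, int) else stats.poisson(float(cd["poisson"]))
            image, labels, _ = synthetic_data.generate_puncta_field(
                n_cells=spec.get("n_cells", 200), count_distribution=dist,
                seed=(base * 1000003 + k) % 2**31)
        elif "image" in spec:
            image = imaging_io.read_stack(spec["image"]).frames[0]
            labels = imaging_io.read_stack(spec["labels"]).frames[0]
        else:
            raise PipelineError("input",
                                f"condition {name}: need preset_counts or image")
        results[name] = puncta.score_field(
            image, labels,
            sigma_min_px=det.get("sigma_min_px", 1.0),
            sigma_max_px=det.get("sigma_max_px", 3.0),
            k_background=det.get("k_background", 3.0),
            log_threshold=det.get("log_threshold", 10.0))
    out = {"results": results}
    names = list(results)
    if len(names) == 2:
        out["fold_change"] = puncta.fold_change(
            results[names[1]].autophagy_index, results[names[0]].autophagy_index)
    d = _out_dir(config, out_dir)
    if d is not None:
        for name, r in results.items():
            r.per_cell.to_csv(d / f"puncta_{name}.csv", index=False)
        summary = {name: {"n_cells": r.n_cells,
                          "autophagy_index": r.autophagy_index,
                          "fraction_positive_pct": r.fraction_positive_pct}
                   for name, r in results.items()}
        if "fold_change" in out:
            summary["fold_change"] = out["fold_change"]
        with open(d / "puncta_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return out
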