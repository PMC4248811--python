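"""File formats and reproducible pipeline runs.

Conventions: CSV is UTF-8, comma-separated with a header row and '.'
decimals; times are seconds, lengths um; movies are multi-page TIFF with
acquisition metadata in a JSON sidecar (``<stem>.json``); configs are
YAML or JSON.  Every run report carries the seed and a hash of the
resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .correlation import CorrelationCurve, IntensityTrace
from .frap import FrapTrace
from .geometry import distance_distribution
from .kinetics import fit_decay
from .pipeline import run_tirf_pipeline
from .synthetic import (ClathrinEventSpec, FusionEventSpec, MovieSimConfig,
                        simulate_tirf_movie)
from .tirf import EventRecord, TirfMovie

__all__ = [
    "write_trace_csv", "read_trace_csv", "write_curve_csv", "read_curve_csv",
    "write_frap_csv", "read_frap_csv", "write_movie", "read_movie",
    "events_to_frame", "write_events_csv", "load_config", "config_hash",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# traces and curves


def write_trace_csv(path, *traces: IntensityTrace) -> None:
    """One or two channels as columns time_s, counts[, counts_ch2]."""
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].values.size
    data = {"time_s": np.arange(n) * traces[0].dt, "counts": traces[0].values}
    if len(traces) == 2:
        if traces[1].values.size != n or traces[1].dt != traces[0].dt:
            raise ValueError("channels must share length and dt")
        data["counts_ch2"] = traces[1].values
    elif len(traces) > 2:
        raise ValueError("at most two channels per file")
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace_csv(path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    if "time_s" not in df or "counts" not in df:
        raise ValueError("trace CSV needs columns time_s, counts")
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    out = [IntensityTrace(df["counts"].to_numpy(), dt, "ch1")]
    if "counts_ch2" in df:
        out.append(IntensityTrace(df["counts_ch2"].to_numpy(), dt, "ch2"))
    return out


def write_curve_csv(path, curve: CorrelationCurve) -> None:
    data = {"lag_s": curve.lags, "g": curve.g}
    if curve.se is not None:
        data["se"] = curve.se
    pd.DataFrame(data).to_csv(path, index=False)


def read_curve_csv(path) -> CorrelationCurve:
    df = pd.read_csv(path)
    se = df["se"].to_numpy() if "se" in df else None
    return CorrelationCurve(lags=df["lag_s"].to_numpy(),
                            g=df["g"].to_numpy(), se=se)


def write_frap_csv(path, trace: FrapTrace) -> None:
    df = pd.DataFrame({"t_s": trace.t, "f": trace.f})
    if trace.prebleach_reference is not None:
        df["prebleach_reference"] = trace.prebleach_reference
    df.to_csv(path, index=False)


def read_frap_csv(path) -> FrapTrace:
    df = pd.read_csv(path)
    ref = (float(df["prebleach_reference"].iloc[0])
           if "prebleach_reference" in df else None)
    return FrapTrace(t=df["t_s"].to_numpy(), f=df["f"].to_numpy(),
                     prebleach_reference=ref)


# ---------------------------------------------------------------------------
# movies


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(path, movie: TirfMovie) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.stack.astype(np.float32))
    meta = {"frame_interval": movie.frame_interval,
            "pixel_size": movie.pixel_size,
            "stimulus_onset_frame": movie.stimulus_onset_frame,
            "stimulus_duration": movie.stimulus_duration}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_movie(path, **overrides) -> TirfMovie:
    """Load a multi-page TIFF plus its JSON metadata sidecar.

    Metadata fields may be overridden (or supplied when no sidecar
    exists) via keyword arguments; missing fields raise an error that
    names them.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    meta.update(overrides)
    required = ("frame_interval", "pixel_size", "stimulus_onset_frame",
                "stimulus_duration")
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"movie metadata missing fields: {missing}; supply a "
                         f"{_sidecar(path).name} sidecar or keyword overrides")
    if stack.shape[0] < 2:
        raise ValueError("single-frame stack: event analysis needs >= 2 frames")
    return TirfMovie(stack=np.asarray(stack, dtype=float),
                     frame_interval=float(meta["frame_interval"]),
                     pixel_size=float(meta["pixel_size"]),
                     stimulus_onset_frame=int(meta["stimulus_onset_frame"]),
                     stimulus_duration=float(meta["stimulus_duration"]))


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    rows = []
    for ev in events:
        d = dataclasses.asdict(ev)
        d["x_um"], d["y_um"] = d.pop("center")
        rows.append(d)
    return pd.DataFrame(rows)


def write_events_csv(path, events: list[EventRecord]) -> None:
    events_to_frame(events).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configs and the umbrella run


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_MOVIE_KEYS = {f.name for f in dataclasses.fields(MovieSimConfig)}
_ANALYSIS_KEYS = {"baseline_window", "window_s", "k_sd", "seg_threshold_sd",
                  "min_pixels"}


def _movie_config(block: dict, seed: int) -> MovieSimConfig:
    block = dict(block)
    unknown = set(block) - _MOVIE_KEYS
    if unknown:
        raise ValueError(f"unknown movie config keys: {sorted(unknown)}")
    if "shape" in block:
        block["shape"] = tuple(block["shape"])
    if "fusion" in block:
        block["fusion"] = FusionEventSpec(**block["fusion"])
    if "clathrin" in block:
        block["clathrin"] = ClathrinEventSpec(**block["clathrin"])
    block.setdefault("seed", seed)
    return MovieSimConfig(**block)


def run_pipeline(config: dict, out_dir) -> dict:
    """Simulate -> segment -> detect -> classify -> distances -> kinetics.

    ``config`` has top-level keys ``seed``, ``movie`` (MovieSimConfig
    fields) and ``analysis`` (pipeline thresholds); anything else is
    rejected by name.  All tables plus a JSON report (seed, config hash,
    package version, summary counts) are written into ``out_dir``.
    Deterministic stages are bit-identical across reruns of one config.
    """
    known = {"seed", "movie", "analysis"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    analysis = dict(config.get("analysis", {}))
    bad = set(analysis) - _ANALYSIS_KEYS
    if bad:
        raise ValueError(f"unknown analysis config keys: {sorted(bad)}")

    cfg = _movie_config(config.get("movie", {}), seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        movie, ribbons, truth = simulate_tirf_movie(cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    write_movie(out / "movie.tif", movie)
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)

    try:
        events, rois, traces = run_tirf_pipeline(movie, ribbons, **analysis)
    except Exception as exc:
        raise RuntimeError(f"stage 'events' failed: {exc}") from exc
    tifffile.imwrite(out / "roi_labels.tif",
                     rois.label_image.astype(np.int32))
    pd.DataFrame(traces.dff.T,
                 columns=[f"roi_{i}" for i in traces.ids]).assign(
        time_s=np.arange(movie.n_frames) * movie.frame_interval
    ).to_csv(out / "traces.csv", index=False)
    write_events_csv(out / "events.csv", events)

    dists = [ev.distance_to_ribbon for ev in events
             if ev.distance_to_ribbon is not None]
    if dists:
        dd = distance_distribution(dists, bin_width=0.1)
        pd.DataFrame({"bin_left_um": dd.bin_edges[:-1],
                      "bin_right_um": dd.bin_edges[1:],
                      "count": dd.counts}).to_csv(
            out / "distance_histogram.csv", index=False)

    taus = {}
    for ev in events:
        if ev.event_class != "accumulation" or ev.onset_frame is None:
            continue
        row = traces.trace(ev.roi_id)
        peak = int(np.argmax(row))
        seg = row[peak:]
        if seg.size >= 10 and seg[0] > 0:
            try:
                taus[int(ev.roi_id)] = fit_decay(
                    seg, movie.frame_interval, model="single").tau
            except (ValueError, RuntimeError):
                pass

    report = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "n_rois": int(len(rois)),
        "n_events": len([e for e in events if e.event_class != "none"]),
        "n_accumulation": len([e for e in events
                               if e.event_class == "accumulation"]),
        "n_loss": len([e for e in events if e.event_class == "loss"]),
        "recovery_tau_s": taus,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
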