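"""TIRF movie analysis: ROI segmentation, dF/F traces, responder selection.

The footprint of a synaptic terminal imaged by TIRF is segmented into
regions of interest on a Laplace-enhanced projection image; per-ROI
relative fluorescence changes (dF/F against a pre-stimulus baseline) are
extracted, responders are selected by a threshold-crossing rule (default
4x the baseline standard deviation), and responses within a fixed
classification window after stimulus onset are labelled as clathrin
*accumulation* (positive-going) or *loss* (negative-going).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .kinetics import fit_decay

__all__ = [
    "TirfMovie",
    "RoiSet",
    "TraceSet",
    "EventRecord",
    "laplace_enhance",
    "segment_rois",
    "extract_traces",
    "detect_responders",
    "classify_events",
]


@dataclass(frozen=True)
class TirfMovie:
    """An image stack with acquisition metadata.

    ``stack`` is (frames, H, W); ``frame_interval`` and ``stimulus_duration``
    in seconds, ``pixel_size`` in um.
    """

    stack: np.ndarray
    frame_interval: float
    pixel_size: float
    stimulus_onset_frame: int
    stimulus_duration: float

    def __post_init__(self) -> None:
        s = np.asarray(self.stack, dtype=float)
        if s.ndim != 3 or s.shape[0] < 2:
            raise ValueError("stack must be (frames, H, W) with >= 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if not (0 <= self.stimulus_onset_frame < s.shape[0]):
            raise ValueError("stimulus_onset_frame outside the movie")
        object.__setattr__(self, "stack", s)

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiSet:
    """Segmented regions: a label image plus per-ROI geometry.

    Labels are contiguous from 1 in raster order of each component's first
    pixel; 0 is background.  Centroids are (x, y) in um.
    """

    label_image: np.ndarray
    pixel_size: float
    ids: np.ndarray = field(default=None)          # type: ignore[assignment]
    pixel_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    centroids: np.ndarray = field(default=None)     # type: ignore[assignment]

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_image, dtype=int)
        if lab.ndim != 2:
            raise ValueError("label image must be 2-D")
        object.__setattr__(self, "label_image", lab)
        n = lab.max()
        ids = np.arange(1, n + 1)
        counts = np.array([(lab == i).sum() for i in ids], dtype=int)
        if np.any(counts == 0):
            raise ValueError("labels must be contiguous from 1")
        cents = []
        for i in ids:
            rows, cols = np.nonzero(lab == i)
            cents.append((cols.mean() * self.pixel_size,
                          rows.mean() * self.pixel_size))
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "pixel_counts", counts)
        object.__setattr__(self, "centroids",
                           np.asarray(cents, dtype=float).reshape(-1, 2))

    def __len__(self) -> int:
        return self.ids.size


@dataclass(frozen=True)
class TraceSet:
    """Per-ROI dF/F time series plus the whole-footprint trace."""

    ids: np.ndarray
    dff: np.ndarray              # (n_rois, frames)
    footprint_dff: np.ndarray    # (frames,)
    excluded_ids: np.ndarray     # ROIs dropped for zero baseline
    frame_interval: float

    def trace(self, roi_id: int) -> np.ndarray:
        idx = np.nonzero(self.ids == roi_id)[0]
        if idx.size == 0:
            raise KeyError(f"roi {roi_id} not in trace set")
        return self.dff[idx[0]]


@dataclass
class EventRecord:
    """One detected ROI response."""

    roi_id: int
    event_class: Literal["accumulation", "loss", "none"]
    onset_frame: int | None
    peak_dff: float
    center: tuple[float, float]          # (x, y) um
    recovery_tau: float | None = None
    distance_to_ribbon: float | None = None
    ribbon_index: int | None = None


def _robust_sd(image: np.ndarray) -> float:
    med = np.median(image)
    return 1.4826 * float(np.median(np.abs(image - med)))


def laplace_enhance(image: np.ndarray, presmooth_sigma: float = 0.0) -> np.ndarray:
    """Discrete Laplacian (5-point stencil), optionally after Gaussian smoothing.

    Note the raw Laplacian of a bright blob is negative at its core; blob
    segmentation thresholds the *negated* output (see ``segment_rois``
    callers in the pipeline).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if presmooth_sigma > 0:
        img = ndimage.gaussian_filter(img, presmooth_sigma)
    return ndimage.laplace(img)


def segment_rois(image: np.ndarray, pixel_size: float,
                 threshold_sd: float = 4.0, min_pixels: int = 4,
                 threshold: float | None = None) -> RoiSet:
    """Threshold an enhancement/projection image into labelled ROIs.

    The threshold defaults to ``median + threshold_sd * robust SD``
    (MAD-based) of the image; pass ``threshold`` to override with an
    absolute value.  Components use 8-connectivity, those below
    ``min_pixels`` are dropped, and surviving components are relabelled
    1..n in raster order of their first (top-left-most) pixel.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if threshold is None:
        threshold = float(np.median(img) + threshold_sd * _robust_sd(img))
    mask = img > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out = np.zeros_like(labels)
    next_id = 1
    # raster order: first occurrence of each label scanning row-major
    flat = labels.ravel()
    seen: dict[int, int] = {}
    order: list[int] = []
    for lab in flat:
        if lab > 0 and lab not in seen:
            seen[lab] = 1
            order.append(int(lab))
    for lab in order:
        sel = labels == lab
        if sel.sum() < min_pixels:
            continue
        out[sel] = next_id
        next_id += 1
    return RoiSet(label_image=out, pixel_size=pixel_size)


def extract_traces(movie: TirfMovie, rois: RoiSet, baseline_window: int = 20,
                   background_mask: np.ndarray | None = None) -> TraceSet:
    """Background-subtracted dF/F per ROI and for the whole footprint.

    ``F0`` is the mean over the first ``baseline_window`` frames (which
    must precede stimulus onset).  Background per frame is the mean over
    ``background_mask``, defaulting to the darkest decile of pixels in the
    baseline mean image.  ROIs whose baseline falls to <= 0 after
    background subtraction are excluded and reported.
    """
    if baseline_window < 1 or baseline_window > movie.stimulus_onset_frame:
        raise ValueError("baseline window must be >= 1 and precede stimulus onset")
    stack = movie.stack
    base_img = stack[:baseline_window].mean(axis=0)
    if background_mask is None:
        thr = np.quantile(base_img, 0.1)
        background_mask = base_img <= thr
    bg = stack[:, background_mask].mean(axis=1)

    dff_rows, kept, excluded = [], [], []
    for rid in rois.ids:
        sel = rois.label_image == rid
        f = stack[:, sel].mean(axis=1) - bg
        f0 = f[:baseline_window].mean()
        if f0 <= 0:
            excluded.append(rid)
            continue
        dff_rows.append((f - f0) / f0)
        kept.append(rid)

    fp_sel = base_img > np.quantile(base_img, 0.1)
    if not fp_sel.any():
        fp_sel = np.ones_like(fp_sel)
    fp = stack[:, fp_sel].mean(axis=1) - bg
    fp0 = fp[:baseline_window].mean()
    fp_dff = (fp - fp0) / fp0 if fp0 > 0 else np.zeros(movie.n_frames)

    return TraceSet(ids=np.asarray(kept, dtype=int),
                    dff=(np.asarray(dff_rows)
                         if dff_rows else np.empty((0, movie.n_frames))),
                    footprint_dff=fp_dff,
                    excluded_ids=np.asarray(excluded, dtype=int),
                    frame_interval=movie.frame_interval)


def baseline_sd(traces: TraceSet, baseline_window: int,
                per_roi: bool = False) -> np.ndarray:
    """Baseline noise level per ROI: the mean of per-ROI baseline SDs
    (scalar broadcast) by default, or each ROI's own SD."""
    if traces.dff.shape[0] == 0:
        return np.empty(0)
    sds = traces.dff[:, :baseline_window].std(axis=1, ddof=1)
    if per_roi:
        return sds
    return np.full_like(sds, sds.mean())


def detect_responders(traces: TraceSet, baseline_window: int,
                      onset_frame: int, k_sd: float = 4.0,
                      per_roi_sd: bool = False) -> list[tuple[int, int]]:
    """Select ROIs whose post-onset dF/F crosses +-k_sd x baseline SD.

    Returns (roi_id, sign) pairs; sign is that of the largest-magnitude
    crossing.  The noise scale is the average of per-ROI baseline SDs
    (set ``per_roi_sd=True`` for individual scales).
    """
    if baseline_window < 5:
        raise ValueError("baseline window must span >= 5 frames")
    if traces.dff.shape[0] == 0:
        return []
    sd = baseline_sd(traces, baseline_window, per_roi=per_roi_sd)
    out = []
    for row, rid, s in zip(traces.dff, traces.ids, sd):
        post = row[onset_frame:]
        hi, lo = post.max(), post.min()
        crossed_hi = hi > k_sd * s
        crossed_lo = lo < -k_sd * s
        if not (crossed_hi or crossed_lo):
            continue
        if crossed_hi and (not crossed_lo or hi >= -lo):
            out.append((int(rid), +1))
        else:
            out.append((int(rid), -1))
    return out


def _event_center(movie: TirfMovie, rois: RoiSet, roi_id: int,
                  sign: int, window: slice, baseline_window: int
                  ) -> tuple[float, float]:
    """Intensity-weighted centre of mass of the ROI's response."""
    sel = rois.label_image == roi_id
    base = movie.stack[:baseline_window].mean(axis=0)
    resp = movie.stack[window].mean(axis=0) - base
    w = np.clip(sign * resp, 0, None)[sel]
    rows, cols = np.nonzero(sel)
    if w.sum() <= 0:
        return (cols.mean() * movie.pixel_size, rows.mean() * movie.pixel_size)
    cx = (cols * w).sum() / w.sum() * movie.pixel_size
    cy = (rows * w).sum() / w.sum() * movie.pixel_size
    return (float(cx), float(cy))


def classify_events(movie: TirfMovie, rois: RoiSet, traces: TraceSet,
                    baseline_window: int = 20, window_s: float = 10.0,
                    k_sd: float = 4.0, per_roi_sd: bool = False
                    ) -> list[EventRecord]:
    """Classify responders as accumulation (rise) or loss (fall).

    The signed significant excursion is measured within ``window_s``
    seconds of stimulus onset.  Each event carries its onset frame (first
    threshold crossing), peak dF/F, response centre of mass, and a
    single-exponential recovery time fitted from the trace peak (left
    unset when the fit fails).
    """
    onset = movie.stimulus_onset_frame
    w_frames = int(round(window_s / movie.frame_interval))
    if onset + w_frames > movie.n_frames:
        raise ValueError("classification window extends past the movie")
    window = slice(onset, onset + w_frames)
    sd = baseline_sd(traces, baseline_window, per_roi=per_roi_sd)
    responders = dict(detect_responders(traces, baseline_window, onset,
                                        k_sd=k_sd, per_roi_sd=per_roi_sd))
    events: list[EventRecord] = []
    for row, rid, s in zip(traces.dff, traces.ids, sd):
        if rid not in responders:
            continue
        seg = row[window]
        hi, lo = seg.max(), seg.min()
        pos = hi > k_sd * s
        neg = lo < -k_sd * s
        if not (pos or neg):
            # crossed threshold only outside the classification window
            events.append(EventRecord(
                roi_id=int(rid), event_class="none", onset_frame=None,
                peak_dff=float(seg[np.argmax(np.abs(seg))]),
                center=_event_center(movie, rois, rid, responders[rid],
                                     window, baseline_window)))
            continue
        sign = +1 if (pos and (not neg or hi >= -lo)) else -1
        cls = "accumulation" if sign > 0 else "loss"
        signed = sign * row
        crossing = np.nonzero(signed[window] > k_sd * s)[0]
        onset_frame = onset + int(crossing[0])
        peak_rel = int(np.argmax(signed[window]))
        peak_frame = onset + peak_rel
        peak = float(row[peak_frame])
        tau = None
        decay = signed[peak_frame:]
        if decay.size >= 10 and decay[0] > 0:
            try:
                fit = fit_decay(decay, movie.frame_interval, model="single")
                if fit.converged:
                    tau = fit.tau
            except (ValueError, RuntimeError):
                tau = None
        events.append(EventRecord(
            roi_id=int(rid), event_class=cls, onset_frame=onset_frame,
            peak_dff=peak,
            center=_event_center(movie, rois, rid, sign, window,
                                 baseline_window),
            recovery_tau=tau))
    return events
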