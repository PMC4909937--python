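"""Functional-connectivity maps and evoked-response statistics.

Seed-pixel correlation maps (zero-lag Pearson r of every window pixel
against one seed trace), region-by-region correlation matrices, composite
thresholded connectivity overlays with remote "island" detection, and
stimulus/reward-triggered averages with paired pre/post statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .dff import DffStack
from .synthetic import RigGeometry, mm_to_px

__all__ = [
    "CorrelationMap",
    "EvokedResponse",
    "CompositeMap",
    "seed_map",
    "seed_from_mm",
    "region_matrix",
    "composite_threshold_map",
    "evoked_average",
    "concatenate_trials",
]


@dataclass
class CorrelationMap:
    """Per-pixel Pearson r against one seed pixel's trace."""

    r_image: np.ndarray
    seed_px: tuple[int, int]
    n_frames: int
    sessions_used: int = 1
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.r_image)


@dataclass
class EvokedResponse:
    """Event-locked mean ΔF/F₀ with per-event statistics.

    ``peak_amp`` is in % ΔF/F₀ (baseline-subtracted); ``p_value`` comes
    from a paired t-test of per-event post-window maxima against maxima of
    a matched-duration pre-event window (matched lengths keep the null
    distributions of the two maxima identical).
    """

    times: np.ndarray                      # peri-event time axis (s)
    mean_trace: np.ndarray
    sem_trace: np.ndarray | None
    n_events: int
    peak_amp: float
    peak_latency_s: float
    p_value: float | None
    n_dropped: int = 0
    event_traces: np.ndarray | None = None


@dataclass
class CompositeMap:
    """Thresholded multi-seed overlay with remote-island bookkeeping."""

    label_images: dict                     # map name -> boolean mask
    colors: dict
    islands: pd.DataFrame                  # map, island_id, area_px, centroid
    overlap: np.ndarray                    # pixels claimed by >1 map
    r_threshold: float


def _pearson_vs_trace(data: np.ndarray, trace: np.ndarray,
                      valid: np.ndarray) -> np.ndarray:
    t = data.shape[0]
    flat = data.reshape(t, -1)
    sc = trace - trace.mean()
    s_norm = np.sqrt(sc @ sc)
    fc = flat - flat.mean(axis=0)
    denom = np.sqrt((fc * fc).sum(axis=0)) * s_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ fc) / denom
    r = r.reshape(data.shape[1:])
    r[~valid] = np.nan
    return r


def seed_map(dff: DffStack, seed_px: tuple[int, int],
             min_frames: int = 900) -> CorrelationMap:
    """Zero-lag Pearson correlation of every valid pixel with the seed.

    ``min_frames`` defaults to one 30 s trial at 30 Hz, the smallest
    sample from which connectivity maps are stable.
    """
    r0, c0 = seed_px
    if not dff.valid_mask[r0, c0]:
        raise ValueError(f"seed {seed_px} lies outside the valid mask")
    if dff.n_frames < min_frames:
        raise ValueError(
            f"{dff.n_frames} frames < min_frames={min_frames}")
    seed_trace = dff.data[:, r0, c0]
    if seed_trace.std() == 0:
        raise ValueError("zero-variance seed trace: correlation undefined")
    r = _pearson_vs_trace(dff.data, seed_trace, dff.valid_mask)
    n_sessions = max(1, len(dff.session_boundaries))
    return CorrelationMap(r, (r0, c0), dff.n_frames, sessions_used=n_sessions)


def seed_from_mm(geom: RigGeometry, ap_mm: float, ml_mm: float,
                 ) -> tuple[int, int]:
    """Seed placement from bregma-relative mm (anatomical-landmark API)."""
    return mm_to_px(geom, ap_mm, ml_mm)


def region_matrix(dff: DffStack, atlas_rois: dict) -> pd.DataFrame:
    """Pearson correlation between ROI-mean traces; symmetric, unit diagonal."""
    if len(atlas_rois) < 2:
        raise ValueError("need at least two ROIs")
    traces = []
    names = []
    for name, mask in atlas_rois.items():
        m = np.asarray(mask, dtype=bool) & dff.valid_mask
        if not m.any():
            raise ValueError(f"ROI {name} is empty (or fully invalid)")
        traces.append(dff.data[:, m].mean(axis=1))
        names.append(name)
    corr = np.corrcoef(np.vstack(traces))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def composite_threshold_map(maps: dict, r_threshold: float,
                            colors: dict | None = None,
                            min_area: int = 5,
                            exclude_radius_px: int = 0) -> CompositeMap:
    """Overlay of thresholded correlation maps with island detection.

    ``maps`` maps a name (e.g. seed region) to a :class:`CorrelationMap`.
    Pixels with r >= threshold form each map's mask; connected components
    of at least ``min_area`` pixels are reported as islands with centroids
    (``remote`` marks components not containing the seed).  Components
    within ``exclude_radius_px`` of the seed can be suppressed entirely.
    """
    if not 0.0 < r_threshold <= 1.0:
        if r_threshold > 1.0:
            warnings.warn("r_threshold > 1 selects nothing")
        elif r_threshold <= 0:
            warnings.warn("r_threshold <= 0 selects the full valid map")
    colors = colors or {name: None for name in maps}
    label_images: dict[str, np.ndarray] = {}
    rows = []
    claimed = None
    overlap = None
    for name, cmap in maps.items():
        with np.errstate(invalid="ignore"):
            mask = np.nan_to_num(cmap.r_image, nan=-np.inf) >= r_threshold
        mask &= cmap.valid_mask
        label_images[name] = mask
        if claimed is None:
            claimed = np.zeros(mask.shape, dtype=int)
            overlap = np.zeros(mask.shape, dtype=bool)
        overlap |= (claimed > 0) & mask
        claimed += mask.astype(int)
        labelled = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labelled):
            if region.area < min_area:
                continue
            rr, cc = region.centroid
            contains_seed = labelled[cmap.seed_px] == region.label
            if exclude_radius_px and contains_seed:
                continue
            rows.append({"map": name, "island_id": region.label,
                         "area_px": int(region.area),
                         "centroid_row": rr, "centroid_col": cc,
                         "remote": not contains_seed})
    islands = pd.DataFrame(
        rows, columns=["map", "island_id", "area_px", "centroid_row",
                       "centroid_col", "remote"])
    return CompositeMap(label_images, colors, islands, overlap, r_threshold)


def evoked_average(dff: DffStack, event_times, window_s: float = 2.0,
                   baseline_s: float = 1.0,
                   roi: np.ndarray | tuple[int, int] | None = None,
                   ) -> EvokedResponse:
    """Stimulus/reward-triggered average with paired pre/post statistics.

    ``roi`` selects the analysed trace: a boolean mask (ROI mean), a pixel
    (row, col), or None for the whole valid-mask mean.  Each event
    contributes its peri-event trace, baseline-subtracted by the mean of
    the ``baseline_s`` window immediately pre-event.  Events lacking full
    window support are dropped with a warning and counted.

    ``peak_amp`` (in %) and ``peak_latency_s`` come from the post-event
    mean trace; the p-value from a paired t-test of per-event maxima in
    the post window against maxima in a pre-event window of the same
    length (so the two maxima share a null distribution).
    """
    if roi is None:
        trace = dff.data[:, dff.valid_mask].mean(axis=1)
    elif isinstance(roi, tuple):
        trace = dff.data[:, roi[0], roi[1]]
    else:
        m = np.asarray(roi, dtype=bool) & dff.valid_mask
        if not m.any():
            raise ValueError("evoked ROI is empty")
        trace = dff.data[:, m].mean(axis=1)

    fs = dff.frame_rate_hz
    n_post = int(round(window_s * fs))
    n_base = int(round(baseline_s * fs))
    n_pre = max(n_post, n_base)   # matched-length window for the paired test
    t_axis = np.arange(-n_pre, n_post + 1) / fs

    kept, pre_max, post_max = [], [], []
    n_dropped = 0
    for ev in np.atleast_1d(np.asarray(event_times, dtype=float)):
        i = int(round((ev - dff.t0) * fs))
        if i - n_pre < 0 or i + n_post >= dff.n_frames:
            n_dropped += 1
            continue
        seg = trace[i - n_pre:i + n_post + 1].copy()
        base = seg[n_pre - n_base:n_pre].mean()
        seg -= base
        kept.append(seg)
        # matched-length windows immediately before/after the event
        pre_max.append(seg[n_pre - n_post:n_pre].max())
        post_max.append(seg[n_pre + 1:].max())
    if n_dropped:
        warnings.warn(f"{n_dropped} event(s) too close to the trial edge "
                      "were dropped")
    if not kept:
        raise ValueError("no events with full window support")

    ev_traces = np.vstack(kept)
    mean_trace = ev_traces.mean(axis=0)
    n = len(kept)
    sem = ev_traces.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    post = mean_trace[n_pre + 1:]
    peak_idx = int(np.argmax(post))
    peak_amp = 100.0 * float(post[peak_idx])
    peak_latency = (peak_idx + 1) / fs
    if n > 1:
        p = float(stats.ttest_rel(post_max, pre_max).pvalue)
    else:
        p = None
    return EvokedResponse(times=t_axis, mean_trace=mean_trace, sem_trace=sem,
                          n_events=n, peak_amp=peak_amp,
                          peak_latency_s=peak_latency, p_value=p,
                          n_dropped=n_dropped, event_traces=ev_traces)


def concatenate_trials(trials: list[DffStack]) -> DffStack:
    """Time-concatenate aligned trials, recording session boundaries.

    All trials must share geometry, frame rate and provenance flags; a
    mismatch is refused with a diff of the flags.  Boundaries let lagged
    analyses exclude cross-boundary frame pairs (zero-lag correlations are
    unaffected).
    """
    if not trials:
        raise ValueError("no trials to concatenate")
    if len(trials) == 1:
        return trials[0]
    ref = trials[0]
    for i, tr in enumerate(trials[1:], start=1):
        if tr.data.shape[1:] != ref.data.shape[1:]:
            raise ValueError(f"trial {i}: shape {tr.data.shape[1:]} != "
                             f"{ref.data.shape[1:]}")
        if tr.frame_rate_hz != ref.frame_rate_hz:
            raise ValueError(f"trial {i}: fps {tr.frame_rate_hz} != "
                             f"{ref.frame_rate_hz}")
        a, b = ref.provenance, tr.provenance
        diff = {k: (a[k], b[k]) for k in ("band_hz", "global_regressed",
                                          "roi_corrected") if a[k] != b[k]}
        if diff:
            raise ValueError(f"trial {i}: provenance mismatch {diff}")
    boundaries = []
    offset = 0
    for tr in trials:
        boundaries.append(offset)
        offset += tr.n_frames
    data = np.concatenate([tr.data for tr in trials], axis=0)
    valid = np.logical_and.reduce([tr.valid_mask for tr in trials])
    out = DffStack(data, frame_rate_hz=ref.frame_rate_hz, t0=ref.t0,
                   band_hz=ref.band_hz, global_regressed=ref.global_regressed,
                   roi_corrected=ref.roi_corrected, valid_mask=valid,
                   session_boundaries=boundaries)
    return out
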