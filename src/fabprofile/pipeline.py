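"""End-to-end orchestration: mzML run -> clonal profile.

Runs the published processing order — slice, average, baseline-subtract,
smooth, deconvolute, pick peaks, merge across slices — and collects
per-stage timings and per-slice peak counts for the run manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .clones import ClonalProfile, merge_slices
from .deconvolve import MassPeak, deconvolute, pick_peaks
from .io import PipelineConfig, Run, config_hash
from .preprocess import make_slices, preprocess_slice

__all__ = ["ProfileStats", "profile_run"]

log = logging.getLogger("fabprofile")


@dataclass
class ProfileStats:
    """Bookkeeping for the run manifest."""

    n_scans: int = 0
    n_slices: int = 0
    n_empty_slices: int = 0
    n_peaks: int = 0
    n_clones: int = 0
    peaks_per_slice: dict[int, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""


def profile_run(run: Run, config: PipelineConfig,
                sample_id: str | None = None) -> tuple[ClonalProfile, ProfileStats]:
    """Convert a run into its clonal profile.

    Empty slices (no scans, or all-zero average) are skipped.  Returns the
    profile sorted by descending intensity plus processing statistics.
    """
    config.validate()
    stats = ProfileStats(n_scans=len(run.scans), config_hash=config_hash(config))
    windows = make_slices(config.roi_start, config.roi_end,
                          config.slice_width, config.slice_overlap)
    stats.n_slices = len(windows)
    peaks: list[MassPeak] = []
    t0 = time.perf_counter()
    for window in windows:
        prepped = preprocess_slice(run, window, config)
        if prepped is None:
            stats.n_empty_slices += 1
            continue
        ms = deconvolute(prepped, config, slice_index=window.index)
        slice_peaks = pick_peaks(ms, config.peak_resolving_power,
                                 config.peak_intensity_threshold)
        stats.peaks_per_slice[window.index] = len(slice_peaks)
        log.info("slice %d [%.2f-%.2f min]: %d peaks",
                 window.index, window.rt_start, window.rt_end, len(slice_peaks))
        peaks.extend(slice_peaks)
    stats.timings["slices_s"] = time.perf_counter() - t0
    stats.n_peaks = len(peaks)
    if stats.n_empty_slices == stats.n_slices:
        log.warning("no scans found in the %.1f-%.1f min region of interest",
                    config.roi_start, config.roi_end)
    t0 = time.perf_counter()
    profile = merge_slices(peaks, config.merge_ppm, config.merge_max_rt_gap,
                           sample_id=sample_id or run.run_id)
    stats.timings["merge_s"] = time.perf_counter() - t0
    stats.n_clones = len(profile)
    profile.provenance = {"config_hash": stats.config_hash, "source_run": run.run_id}
    log.info("merged %d peaks from %d slices into %d clones",
             stats.n_peaks, stats.n_slices - stats.n_empty_slices, stats.n_clones)
    return profile, stats
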