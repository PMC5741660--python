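"""Area time courses of waves and growth cones, and the GC wave response.

Manual outlining in the original workflow is replaced by seeded threshold
segmentation: per sampled frame an Otsu threshold is computed inside a window
around the (propagated) seed and the connected above-threshold region holding
the seed is measured.  The seed file is the supervision hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.segmentation import flood

from .errors import SeedError, ValidationError
from .imageproc import CalibratedStack

__all__ = ["AreaSeries", "region_area_timecourse", "gc_wave_response"]


@dataclass
class AreaSeries:
    """Areas of one labelled region over time, with event markers."""

    times_s: np.ndarray
    areas_um2: np.ndarray
    label: str = "GC"  # "AW" | "GC"
    event_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    gap: np.ndarray | None = None  # True where the seed was lost

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("times_s: must be strictly increasing")
        if np.nanmin(self.areas_um2, initial=0.0) < 0:
            raise ValidationError("areas_um2: must be >= 0")
        if self.gap is None:
            self.gap = np.zeros(self.times_s.shape, dtype=bool)

    def mean_area(self, t0_s: float, t1_s: float) -> float:
        """Arithmetic mean of sampled areas inside [t0, t1]; NaN if empty."""
        sel = (self.times_s >= t0_s) & (self.times_s <= t1_s) & ~self.gap
        return float(self.areas_um2[sel].mean()) if sel.any() else math.nan


def region_area_timecourse(
    stack: CalibratedStack,
    seed: tuple[int, int],
    *,
    frames: np.ndarray | None = None,
    window_px: int = 40,
    label: str = "GC",
    threshold: float | None = None,
) -> AreaSeries:
    """Seeded-threshold area of one region per sampled frame.

    Area = pixel count of the thresholded connected region containing the
    seed x pixel_size^2.  The seed propagates: each sampled frame re-centres
    on the previous region centroid.  A frame where the seed falls below
    threshold is a flagged gap (area NaN), not an error.
    """
    if frames is None:
        frames = np.arange(stack.n_frames)
    frames = np.asarray(frames, dtype=int)
    h, w = stack.shape
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < h and 0 <= c < w):
        raise SeedError(f"seed ({r}, {c}) outside image")

    areas = np.full(frames.size, np.nan)
    gap = np.zeros(frames.size, dtype=bool)
    px2 = stack.pixel_size_um**2
    for i, f in enumerate(frames):
        img = stack.frames[f]
        r0, r1 = max(r - window_px, 0), min(r + window_px + 1, h)
        c0, c1 = max(c - window_px, 0), min(c + window_px + 1, w)
        win = img[r0:r1, c0:c1]
        thr = threshold_otsu(win) if threshold is None else threshold
        fg = win >= thr
        rr, cc = r - r0, c - c0
        if not fg[rr, cc]:
            gap[i] = True
            continue
        mask = flood(fg, (rr, cc), connectivity=2)
        areas[i] = mask.sum() * px2
        ys, xs = np.nonzero(mask)
        r = int(round(ys.mean())) + r0
        c = int(round(xs.mean())) + c0
    if np.all(gap):
        # Empty region below threshold everywhere: a zero-area, fully
        # flagged series is a legal result.
        areas = np.zeros(frames.size)
    return AreaSeries(
        times_s=frames * stack.frame_interval_s, areas_um2=areas, label=label, gap=gap)


def gc_wave_response(
    areas: AreaSeries,
    arrival_times_s: np.ndarray,
    *,
    window_min: float = 10.0,
    peak_search_min: float = 15.0,
    loss_window_min: tuple[float, float] = (30.0, 60.0),
):
    """Fold change at wave arrival and % area loss over the post-merge window.

    Per arrival: fold = mean area in the ``window_min`` after arrival divided
    by the mean in an equal window before; loss = (peak - mean area in the
    ``loss_window_min`` interval after arrival) / peak x 100.  Events missing
    a pre- or post-window are flagged NaN.  Returns a list of
    ``(fold_change, percent_loss)`` pairs, one per arrival.
    """
    out = []
    w_s = window_min * 60.0
    for t_a in np.atleast_1d(np.asarray(arrival_times_s, dtype=float)):
        pre = areas.mean_area(t_a - w_s, t_a - 1e-9)
        post = areas.mean_area(t_a, t_a + w_s)
        fold = post / pre if (np.isfinite(pre) and pre > 0 and np.isfinite(post)) else math.nan
        sel = (areas.times_s >= t_a) & (areas.times_s <= t_a + peak_search_min * 60.0) \
            & ~areas.gap
        if sel.any():
            peak = float(np.nanmax(areas.areas_um2[sel]))
            late = areas.mean_area(t_a + loss_window_min[0] * 60.0,
                                   t_a + loss_window_min[1] * 60.0)
            loss = (peak - late) / peak * 100.0 if (peak > 0 and np.isfinite(late)) else math.nan
        else:
            loss = math.nan
        out.append((fold, loss))
    return out
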