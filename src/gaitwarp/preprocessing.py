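"""Data-quality chain for raw coordinate trajectories.

The fixed order is: confidence gate -> bounded gap interpolation -> outlier
replacement -> zero-phase low-pass filtering; the filter refuses input that
still carries missing samples.  Pixel-to-metric scaling and cross-system
synchronisation (via left-ankle ground-contact events) live here too.

1-D signals are plain float arrays in which NaN marks a missing sample;
the keypoint containers carry explicit masks and are converted at the edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .pose_io import KeypointSeries

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "mask_low_confidence",
    "fill_gaps",
    "replace_outliers",
    "lowpass",
    "pixels_to_height_units",
    "detect_ground_contact",
    "synchronize",
    "clean_signal",
]

logger = logging.getLogger(__name__)


@dataclass
class CleaningConfig:
    """Thresholds for the cleaning chain.

    The gap bound is stated in frames at 60 frames/s; at other rates the
    equivalent 0.2 s bound governs, rounded to the nearest frame.
    """

    confidence_threshold: float = 0.45
    max_gap_frames: int = 12
    max_gap_seconds: float = 0.2
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    dual_pass: bool = True
    outlier_window: int = 11
    outlier_nsigma: float = 3.0
    contact_prominence_fraction: float = 0.3
    contact_min_separation_s: float = 0.4

    def max_gap_for(self, fs: float) -> int:
        """Gap bound in frames at sampling rate ``fs``."""
        if abs(fs - 60.0) < 1e-9:
            return self.max_gap_frames
        return max(1, round(self.max_gap_seconds * fs))

    def validate(self, fs: float) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.filter_cutoff_hz >= fs / 2:
            raise ValueError("filter cutoff must be below the Nyquist rate")


@dataclass
class CleaningReport:
    """Book-keeping for one cleaned signal."""

    n_masked: int = 0
    n_interpolated: int = 0
    n_outliers_replaced: int = 0
    longest_gap: int = 0
    excluded: bool = False
    exclusion_reason: str = ""
    first_valid: int = 0
    last_valid: int = -1  # inclusive; -1 until set

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------


def mask_low_confidence(series: KeypointSeries, threshold: float = 0.45
                        ) -> tuple[KeypointSeries, int]:
    """Flag every keypoint with confidence strictly below ``threshold`` missing.

    Returns the gated series and the count of newly masked samples.  All
    other samples are untouched.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = series.copy()
    newly = (out.confidence < threshold) & ~out.missing
    out.missing |= newly
    out.x[out.missing] = np.nan
    out.y[out.missing] = np.nan
    return out, int(np.count_nonzero(newly))


def _nan_runs(isnan: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    runs = []
    n = isnan.size
    i = 0
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(signal: np.ndarray, max_gap: int, trim: bool = True
              ) -> tuple[np.ndarray, CleaningReport]:
    """Linearly interpolate interior missing runs of length <= ``max_gap``.

    A longer interior run marks the signal excluded and leaves it unfilled.
    Leading/trailing missing runs have no second anchor and are never
    extrapolated: with ``trim=True`` they are cut off, otherwise kept as NaN
    with the valid span recorded in the report.
    """
    x = np.asarray(signal, dtype=float).copy()
    report = CleaningReport()
    isnan = ~np.isfinite(x)
    finite_idx = np.flatnonzero(~isnan)
    if finite_idx.size == 0:
        report.excluded = True
        report.exclusion_reason = "signal is fully missing"
        report.longest_gap = x.size
        return x, report
    lo, hi = int(finite_idx[0]), int(finite_idx[-1])
    report.first_valid, report.last_valid = lo, hi

    interior = isnan.copy()
    interior[:lo] = False
    interior[hi + 1:] = False
    runs = _nan_runs(interior)
    report.longest_gap = max((b - a for a, b in runs), default=0)
    too_long = [(a, b) for a, b in runs if b - a > max_gap]
    if too_long:
        a, b = too_long[0]
        report.excluded = True
        report.exclusion_reason = (
            f"gap of {b - a} frames at [{a}, {b}) exceeds the "
            f"{max_gap}-frame interpolation bound"
        )
        return (x[lo:hi + 1] if trim else x), report

    if runs:
        idx = np.arange(x.size)
        x[interior] = np.interp(idx[interior], idx[~isnan], x[~isnan])
        report.n_interpolated = int(sum(b - a for a, b in runs))
    return (x[lo:hi + 1] if trim else x), report


def replace_outliers(signal: np.ndarray, window: int = 11, nsigma: float = 3.0
                     ) -> np.ndarray:
    """Hampel-style despiking: samples deviating from the rolling median by
    more than ``nsigma x 1.4826 x rolling MAD`` are replaced by linear
    interpolation between their neighbours.

    A small absolute floor on the scale estimate keeps constant signals from
    producing false positives (MAD = 0).  Deterministic for fixed input.
    """
    x = np.asarray(signal, dtype=float).copy()
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > x.size:
        logger.info("outlier window (%d) exceeds signal length (%d); skipped",
                    window, x.size)
        return x
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    med = np.median(view, axis=-1)
    mad = np.median(np.abs(view - med[:, None]), axis=-1)
    scale = 1.4826 * mad
    floor = max(1e-9, 1e-9 * float(np.nanmax(np.abs(x), initial=0.0)))
    scale = np.maximum(scale, floor)
    bad = np.abs(x - med) > nsigma * scale
    if not np.any(bad):
        return x
    good_idx = np.flatnonzero(~bad)
    if good_idx.size < 2:
        logger.info("outlier gate flagged nearly all samples; skipped")
        return x
    idx = np.arange(x.size)
    # interior gaps: linear; edge outliers: held at the nearest inlier
    x[bad] = np.interp(idx[bad], good_idx, x[good_idx])
    return x


def lowpass(signal: np.ndarray, fs: float, cutoff: float = 6.0,
            order: int = 4, dual_pass: bool = True) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward by default).

    Must run after gap filling: missing samples are a contract violation.
    Output length equals input length; a constant signal is a fixed point
    (unity DC gain).
    """
    x = np.asarray(signal, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("lowpass requires a gap-free signal; fill gaps first")
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist rate fs/2")
    if x.size <= 3 * order:
        raise ValueError(f"signal too short ({x.size}) for order-{order} filtering")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    if dual_pass:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def clean_signal(signal: np.ndarray, fs: float, config: CleaningConfig | None = None,
                 trim: bool = True) -> tuple[np.ndarray, CleaningReport]:
    """Run fill -> outlier-replace -> filter on one 1-D trajectory.

    Returns the cleaned signal (trimmed of unfillable edges) and the report;
    an excluded signal is returned unfiltered.
    """
    config = config or CleaningConfig()
    config.validate(fs)
    filled, report = fill_gaps(signal, config.max_gap_for(fs), trim=trim)
    if report.excluded:
        return filled, report
    despiked = replace_outliers(filled, config.outlier_window, config.outlier_nsigma)
    report.n_outliers_replaced = int(np.count_nonzero(despiked != filled))
    if despiked.size <= 3 * config.filter_order:
        report.excluded = True
        report.exclusion_reason = "too few valid samples to filter"
        return despiked, report
    out = lowpass(despiked, fs, config.filter_cutoff_hz, config.filter_order,
                  config.dual_pass)
    return out, report


# ---------------------------------------------------------------------------
# Scaling and synchronisation


def pixels_to_height_units(
    series: KeypointSeries,
    subject_height: float,
    calibration_frame: int | None = None,
    head_points: tuple[str, ...] = ("Nose", "REye", "LEye", "REar", "LEar"),
    foot_points: tuple[str, ...] = ("LHeel", "RHeel", "LAnkle", "RAnkle"),
) -> KeypointSeries:
    """Convert pixel coordinates to metres via the subject's known height.

    The scale is ``s = subject_height / height_in_pixels`` where the pixel
    height is the vertical extent between a head-top proxy (highest of the
    face points) and the heels on a calibration frame.  If no frame index is
    given, the first frame with a finite head proxy and heel is used.
    """
    if subject_height <= 0:
        raise ValueError("subject height must be positive")

    def extent(t: int) -> float | None:
        top, bottom = -np.inf, np.inf
        for name in head_points:
            _, y, miss = series.point(name)
            if not miss[t]:
                top = max(top, y[t])
        for name in foot_points:
            _, y, miss = series.point(name)
            if not miss[t]:
                bottom = min(bottom, y[t])
        if not np.isfinite(top) or not np.isfinite(bottom) or top <= bottom:
            return None
        return top - bottom

    if calibration_frame is not None:
        candidates = [calibration_frame]
    else:
        candidates = range(series.n_frames)
    height_px = None
    for t in candidates:
        height_px = extent(t)
        if height_px is not None:
            break
    if height_px is None:
        raise ValueError(
            "no usable calibration frame (head and heel points never finite "
            "together); supply a manual scale instead"
        )
    s = subject_height / height_px
    out = series.copy()
    out.x = out.x * s
    out.y = out.y * s
    out.units = "m"
    out.scale = s
    out.subject_height = subject_height
    return out


def detect_ground_contact(
    ankle_y: np.ndarray,
    fs: float,
    prominence_fraction: float = 0.3,
    min_separation_s: float = 0.4,
) -> np.ndarray:
    """Ground-contact (heel-strike) frames from the vertical ankle trajectory.

    Contacts are local minima of the cleaned, filtered vertical coordinate
    whose prominence exceeds ``prominence_fraction`` of the signal range,
    separated by at least ``min_separation_s``.  Returns sorted frame indices.
    """
    y = np.asarray(ankle_y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("ankle trajectory must be cleaned (no missing samples)")
    rng = float(np.ptp(y))
    if rng <= 0:
        raise ValueError("constant ankle trajectory: no ground-contact events")
    distance = max(1, round(min_separation_s * fs))
    peaks, _ = sps.find_peaks(-y, prominence=prominence_fraction * rng,
                              distance=distance)
    if peaks.size < 1:
        raise ValueError("no ground-contact events detected; trial unusable "
                         "for synchronisation")
    return np.sort(peaks)


def synchronize(events_a: np.ndarray, fs_a: float,
                events_b: np.ndarray, fs_b: float) -> float:
    """Time offset (seconds) aligning the first contact events of two systems.

    ``offset = t_first(A) - t_first(B)``; subtracting it from system A's
    clock makes the first events coincide to within one frame of the coarser
    system.
    """
    events_a = np.asarray(events_a)
    events_b = np.asarray(events_b)
    if events_a.size == 0 or events_b.size == 0:
        raise ValueError("both event sequences must be non-empty")
    return float(events_a[0] / fs_a - events_b[0] / fs_b)
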