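"""End-to-end orchestration: read -> clean -> synchronise -> angles -> DTW ->
agreement statistics -> report.

The stage order is fixed (gate, fill, outlier replacement, filter — then
angles), mirroring a coordinate-level preprocessing design: filtering acts
on landmark trajectories, not on the derived angle series.  Exclusions are
per joint and side, not per trial: an unfillable gap in one landmark only
drops the rows that need that landmark, and every excluded row carries its
reason in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .agreement import bland_altman, bonferroni
from .dtw_similarity import align_pairs, dtw
from .kinematics import (
    DEFAULT_ROM_DEG, JOINTS, KEYPOINT_LANDMARKS, MARKER_LANDMARKS, SIDES,
    _JOINT_ROLES, AngleSeries, ankle_angle, hip_angle, infer_walking_direction,
    knee_angle,
)
from .pose_io import KeypointSeries, MarkerSeries, read_keypoint_json_dir, read_marker_table
from .preprocessing import (
    CleaningConfig, CleaningReport, detect_ground_contact, fill_gaps, lowpass,
    mask_low_confidence, pixels_to_height_units, replace_outliers, synchronize,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

#: Plausibility bounds for cleaned sagittal joint angles, degrees.
PHYSIO_BOUNDS_DEG = (-60.0, 180.0)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the evaluation pipeline in one place."""

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    sigma: float = 10.0               # Gaussian-kernel width, deg/step
    band: int | None = None           # optional Sakoe-Chiba half-width
    rom_fraction: float = 0.30        # tolerance band fraction of ROM
    rom_table: dict = field(default_factory=lambda: dict(DEFAULT_ROM_DEG))
    joints: tuple[str, ...] = JOINTS
    sides: tuple[str, ...] = SIDES
    pairing: str = "dtw"              # "dtw" (warping-path pairs) or "grid"
    alpha: float = 0.05
    m_comparisons: int = 6            # three joints x two sides
    person_index: int = 0
    image_height: float = 1080.0
    fs_keypoints: float = 60.0
    direction: float | None = None    # None: infer from hip displacement
    subject_height: float | None = None
    forward_axis: int = 0             # marker lab axes
    vertical_axis: int = 1

    @property
    def corrected_alpha(self) -> float:
        return bonferroni(self.alpha, self.m_comparisons)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["cleaning"] = asdict(self.cleaning)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML (or flat ``key = value`` lines).

    Keys matching CleaningConfig fields are routed there; the rest go to the
    pipeline level.  Unknown keys raise, catching typos early.
    """
    import yaml

    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if not isinstance(data, Mapping):
        data = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, sep, val = line.partition("=")
            if not sep:
                raise ValueError(f"cannot parse config line: {line!r}")
            data[key.strip()] = yaml.safe_load(val.strip())

    cleaning_fields = set(CleaningConfig.__dataclass_fields__)
    pipe_fields = set(PipelineConfig.__dataclass_fields__) - {"cleaning"}
    ckw, pkw = {}, {}
    for key, val in dict(data).items():
        if key in cleaning_fields:
            ckw[key] = val
        elif key in pipe_fields:
            pkw[key] = val
        elif key == "cleaning" and isinstance(val, Mapping):
            ckw.update(val)
        else:
            raise ValueError(f"unknown config key: {key!r}")
    if "joints" in pkw:
        pkw["joints"] = tuple(pkw["joints"])
    if "sides" in pkw:
        pkw["sides"] = tuple(pkw["sides"])
    return PipelineConfig(cleaning=CleaningConfig(**ckw), **pkw)


# ---------------------------------------------------------------------------
# Landmark-track cleaning


@dataclass
class _Track:
    """One cleaned landmark trajectory, full-length with NaN outside its span."""

    x: np.ndarray
    y: np.ndarray
    report: CleaningReport


def _clean_track(x: np.ndarray, y: np.ndarray, missing: np.ndarray,
                 fs: float, config: CleaningConfig) -> _Track:
    xs = np.where(missing, np.nan, x)
    ys = np.where(missing, np.nan, y)
    max_gap = config.max_gap_for(fs)
    xf, rep_x = fill_gaps(xs, max_gap, trim=False)
    yf, rep_y = fill_gaps(ys, max_gap, trim=False)
    rep = rep_x if rep_x.longest_gap >= rep_y.longest_gap else rep_y
    report = CleaningReport(
        n_masked=int(np.count_nonzero(missing)),
        n_interpolated=rep_x.n_interpolated + rep_y.n_interpolated,
        longest_gap=max(rep_x.longest_gap, rep_y.longest_gap),
        excluded=rep_x.excluded or rep_y.excluded,
        exclusion_reason=rep.exclusion_reason,
        first_valid=max(rep_x.first_valid, rep_y.first_valid),
        last_valid=min(rep_x.last_valid, rep_y.last_valid),
    )
    return _Track(x=xf, y=yf, report=report)


def _filter_span(track: _Track, lo: int, hi: int, fs: float,
                 config: CleaningConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Outlier-replace and low-pass one track on the inclusive span [lo, hi]."""
    x = track.x[lo:hi + 1]
    y = track.y[lo:hi + 1]
    x1 = replace_outliers(x, config.outlier_window, config.outlier_nsigma)
    y1 = replace_outliers(y, config.outlier_window, config.outlier_nsigma)
    n_out = int(np.count_nonzero(x1 != x)) + int(np.count_nonzero(y1 != y))
    x2 = lowpass(x1, fs, config.filter_cutoff_hz, config.filter_order,
                 config.dual_pass)
    y2 = lowpass(y1, fs, config.filter_cutoff_hz, config.filter_order,
                 config.dual_pass)
    return x2, y2, n_out


class _Source:
    """A cleaned measurement stream (markerless or reference) ready for angles."""

    def __init__(self, tracks: dict[tuple[str, str], _Track], fs: float,
                 hip_x: np.ndarray, label: str):
        self.tracks = tracks
        self.fs = fs
        self.hip_x = hip_x
        self.label = label
        self.sync_frame = 0  # absolute frame of the first ground-contact event

    def span(self, side: str, roles: tuple[str, ...]) -> tuple[int, int] | str:
        """Common valid span for the given roles, or an exclusion reason."""
        lo, hi = self.sync_frame, np.inf
        for role in roles:
            tr = self.tracks[(side, role)]
            if tr.report.excluded:
                return (f"{self.label} {side} {role}: {tr.report.exclusion_reason}")
            lo = max(lo, tr.report.first_valid)
            hi = min(hi, tr.report.last_valid)
        if hi - lo < 1:
            return f"{self.label} {side}: no overlapping valid samples"
        return int(lo), int(hi)


def _prepare_keypoints(series: KeypointSeries, cfg: PipelineConfig) -> tuple[_Source, int]:
    gated, n_masked = mask_low_confidence(series, cfg.cleaning.confidence_threshold)
    if cfg.subject_height is not None:
        try:
            gated = pixels_to_height_units(gated, cfg.subject_height)
        except ValueError as exc:
            logger.warning("height calibration skipped: %s", exc)
    tracks = {}
    for side in cfg.sides:
        table = KEYPOINT_LANDMARKS[side]
        for role in ("hip", "knee", "ankle", "heel", "toe"):
            x, y, miss = gated.point(table[role])
            tracks[(side, role)] = _clean_track(x, y, miss, gated.fs, cfg.cleaning)
    hx, _, hmiss = gated.point("MidHip")
    hip_x = np.where(hmiss, np.nan, hx)
    if np.all(~np.isfinite(hip_x)):
        hip_x = tracks[(cfg.sides[0], "hip")].x
    return _Source(tracks, gated.fs, hip_x, "markerless"), n_masked


def _prepare_markers(series: MarkerSeries, cfg: PipelineConfig) -> _Source:
    tracks = {}
    for side in cfg.sides:
        table = MARKER_LANDMARKS[side]
        series.require([table[r] for r in ("hip", "knee", "ankle", "heel", "toe")])
        for role in ("hip", "knee", "ankle", "heel", "toe"):
            xyz, miss = series.marker(table[role])
            tracks[(side, role)] = _clean_track(
                xyz[:, cfg.forward_axis], xyz[:, cfg.vertical_axis], miss,
                series.fs, cfg.cleaning)
    hip_x = tracks[(cfg.sides[0], "hip")].x
    return _Source(tracks, series.fs, hip_x, "reference")


def _detect_sync(source: _Source, cfg: PipelineConfig) -> np.ndarray | None:
    """Ground-contact frames (absolute) from the cleaned left-ankle height."""
    try:
        tr = source.tracks[("left", "ankle")]
        if tr.report.excluded:
            raise ValueError(tr.report.exclusion_reason)
        lo, hi = tr.report.first_valid, tr.report.last_valid
        _, y, _ = _filter_span(tr, lo, hi, source.fs, cfg.cleaning)
        events = detect_ground_contact(
            y, source.fs, cfg.cleaning.contact_prominence_fraction,
            cfg.cleaning.contact_min_separation_s)
        return events + lo
    except (ValueError, KeyError) as exc:
        logger.warning("%s: ground-contact detection failed (%s); "
                       "proceeding without event synchronisation",
                       source.label, exc)
        return None


def _joint_angles(source: _Source, joint: str, side: str, lo: int, hi: int,
                  cfg: PipelineConfig, direction: float) -> tuple[np.ndarray, dict]:
    roles = _JOINT_ROLES[joint]
    pts = []
    n_out = 0
    for role in roles:
        x, y, k = _filter_span(source.tracks[(side, role)], lo, hi,
                               source.fs, cfg.cleaning)
        n_out += k
        pts.append(np.stack([x, y], axis=-1))
    if joint == "hip":
        vals = hip_angle(pts[0], pts[1], direction=direction)
    elif joint == "knee":
        vals = knee_angle(pts[0], pts[1], pts[2])
    else:
        vals = ankle_angle(pts[0], pts[1], pts[2])
    low, high = PHYSIO_BOUNDS_DEG
    vals = np.where((vals < low) | (vals > high), np.nan, vals)
    info = {"n_outliers_replaced": n_out}
    return vals, info


def run_pipeline(
    markerless: KeypointSeries | str | Path,
    reference: MarkerSeries | str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Evaluate one markerless trial against its reference recording.

    Returns a report dict with one row per joint and side (similarity,
    normalised DTW distance, Bland-Altman bias and limits of agreement,
    Pearson r, t-test) plus a manifest holding the config snapshot, the
    synchronisation offset and per-track cleaning reports.  Rows that cannot
    be computed are marked excluded with a reason; the run always completes.
    """
    cfg = config or PipelineConfig()
    if not isinstance(markerless, KeypointSeries):
        markerless = read_keypoint_json_dir(
            markerless, person_index=cfg.person_index,
            fs=cfg.fs_keypoints, image_height=cfg.image_height)
    if not isinstance(reference, MarkerSeries):
        reference = read_marker_table(reference)

    ml, n_masked = _prepare_keypoints(markerless, cfg)
    ref = _prepare_markers(reference, cfg)

    ev_ml = _detect_sync(ml, cfg)
    ev_ref = _detect_sync(ref, cfg)
    offset_s = None
    if ev_ml is not None and ev_ref is not None:
        offset_s = synchronize(ev_ml, ml.fs, ev_ref, ref.fs)
        ml.sync_frame = int(ev_ml[0])
        ref.sync_frame = int(ev_ref[0])

    direction = cfg.direction
    if direction is None:
        direction = infer_walking_direction(ml.hip_x)

    rows = []
    for joint in cfg.joints:
        for side in cfg.sides:
            roles = _JOINT_ROLES[joint]
            span_ml = ml.span(side, roles)
            span_ref = ref.span(side, roles)
            reason = None
            if isinstance(span_ml, str):
                reason = span_ml
            elif isinstance(span_ref, str):
                reason = span_ref
            if reason is not None:
                rows.append({"joint": joint, "side": side, "excluded": True,
                             "exclusion_reason": reason})
                continue
            try:
                row = _compare_joint(ml, ref, joint, side, span_ml, span_ref,
                                     cfg, direction)
            except ValueError as exc:
                row = {"joint": joint, "side": side, "excluded": True,
                       "exclusion_reason": str(exc)}
            rows.append(row)

    manifest = {
        "version": __version__,
        "config": cfg.as_dict(),
        "direction": direction,
        "sync_offset_s": offset_s,
        "n_low_confidence_masked": n_masked,
        "pairing": cfg.pairing,
        "cleaning": {
            f"{label}/{side}/{role}": src.tracks[(side, role)].report.as_dict()
            for label, src in (("markerless", ml), ("reference", ref))
            for (side, role) in src.tracks
        },
        "excluded": [
            {"joint": r["joint"], "side": r["side"],
             "reason": r["exclusion_reason"]}
            for r in rows if r.get("excluded")
        ],
    }
    return {"results": rows, "manifest": manifest}


def _compare_joint(ml: _Source, ref: _Source, joint: str, side: str,
                   span_ml: tuple[int, int], span_ref: tuple[int, int],
                   cfg: PipelineConfig, direction: float) -> dict:
    vals_ml, info_ml = _joint_angles(ml, joint, side, *span_ml, cfg, direction)
    vals_ref, info_ref = _joint_angles(ref, joint, side, *span_ref, cfg, direction)

    max_gap_ml = cfg.cleaning.max_gap_for(ml.fs)
    max_gap_ref = cfg.cleaning.max_gap_for(ref.fs)
    vals_ml, rep_ml = fill_gaps(vals_ml, max_gap_ml, trim=True)
    vals_ref, rep_ref = fill_gaps(vals_ref, max_gap_ref, trim=True)
    for rep, label in ((rep_ml, "markerless"), (rep_ref, "reference")):
        if rep.excluded:
            raise ValueError(f"{label} {side} {joint} angle series: "
                             f"{rep.exclusion_reason}")

    res = dtw(vals_ref, vals_ml, sigma=cfg.sigma, band=cfg.band)
    if cfg.pairing == "dtw":
        ref_ml_pairs = align_pairs(vals_ref, vals_ml, res.path)
        pairs = ref_ml_pairs[:, ::-1]  # (markerless, reference)
    elif cfg.pairing == "grid":
        t_ml = np.arange(vals_ml.size) / ml.fs
        t_ref = np.arange(vals_ref.size) / ref.fs
        t_end = min(t_ml[-1], t_ref[-1])
        keep = t_ml <= t_end
        interp = np.interp(t_ml[keep], t_ref, vals_ref)
        pairs = np.column_stack([vals_ml[keep], interp])
    else:
        raise ValueError(f"unknown pairing mode {cfg.pairing!r}")

    stats = bland_altman(pairs, alpha=cfg.corrected_alpha)
    half_width = cfg.rom_fraction * cfg.rom_table[joint]
    inside = np.abs(pairs[:, 0] - pairs[:, 1]) <= half_width
    row = {
        "joint": joint,
        "side": side,
        "excluded": False,
        "exclusion_reason": "",
        "similarity": res.similarity,
        "dtw_dist": res.dtw_dist,
        "normalized_dist": res.normalized_dist,
        "path_length": res.path_length,
        "n_frames_markerless": int(vals_ml.size),
        "n_frames_reference": int(vals_ref.size),
        "band_half_width_deg": half_width,
        "band_coverage_pct": 100.0 * float(np.mean(inside)),
        "n_outliers_replaced": info_ml["n_outliers_replaced"] + info_ref["n_outliers_replaced"],
    }
    row.update(stats.as_dict())
    return row
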