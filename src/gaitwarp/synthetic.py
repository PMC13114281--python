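"""Synthetic gait: ground-truth joint waveforms, a lateral-view skeleton
projection, and controlled corruption of the resulting keypoints.

The generator exists so that every pipeline stage can be tested against an
exact ground truth without motion recordings.  Joint waveforms are truncated
Fourier series over the gait cycle (band-limited below 5 Hz at default
cadence, like real gait); the skeleton projection is the forward kinematics
of a planar thigh-shank-foot chain built to be *exactly* inverted by the
angle formulas in :mod:`gaitwarp.kinematics`.  The right leg runs half a
cycle out of phase with the left.

Cycle phase is aligned so that the left ankle point reaches its per-cycle
height minimum exactly at integer phase — i.e. the emitted heel-strike truth
times coincide with the ground-contact definition used by the event
detector.  Trials start half a cycle before the first heel strike so no
truth event sits on the series boundary.

Corruption models the error sources of 2-D pose estimation: isotropic
Gaussian keypoint jitter, per-frame confidence dropouts (below the 0.45
gate), bursty gaps, and an optional constant angular bias injected by
rotating the shank (with the foot) about the knee — which shifts the knee
flexion series by exactly the requested amount, so bias-recovery tests have
an exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .kinematics import AngleSeries
from .pose_io import BODY25_NAMES, KeypointSeries, MarkerSeries

__all__ = [
    "GaitConfig",
    "CorruptionConfig",
    "GroundTruth",
    "generate_waveforms",
    "project_skeleton",
    "project_markers",
    "corrupt",
    "resample_pair",
]

#: Default Fourier coefficients per joint: (offset_deg, [(amp_deg, phase_rad), ...])
#: with angle(phi) = offset + sum_k amp_k * sin(2*pi*k*phi + phase_k).
#: Two-harmonic least-squares fits to normative adult sagittal gait curves
#: (phase 0 = heel strike): hip ~ -11..31 deg, knee ~ 2..59 deg flexion with
#: the stance/swing double bump, ankle ~ -12..13 deg.
DEFAULT_HARMONICS: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {
    "hip": (12.9, ((20.6, 2.012), (3.9, -1.164))),
    "knee": (23.0, ((20.7, -2.934), (15.8, -0.927))),
    "ankle": (-0.1, ((7.1, -0.095), (7.0, -2.984))),
}


@dataclass
class GaitConfig:
    """Study conditions for one synthetic walking trial.

    Defaults emulate the validation protocol: a ~1.1 s gait cycle walked at
    1.2 m/s, sampled at 60 frames/s (markerless) — the reference system runs
    at 240 frames/s via :func:`resample_pair`.  Segment lengths are typical
    adult values for a 1.70 m subject.
    """

    cadence: float = 0.9              # gait cycles per second
    n_cycles: int = 5
    fs: float = 60.0                  # frames per second
    harmonics: Mapping[str, tuple[float, tuple[tuple[float, float], ...]]] = field(
        default_factory=lambda: dict(DEFAULT_HARMONICS))
    thigh_m: float = 0.42
    shank_m: float = 0.42
    foot_m: float = 0.25
    heel_drop_m: float = 0.07         # heel below the ankle, along the shank line
    hip_height_m: float = 0.90
    trunk_m: float = 0.72             # hip to head-top proxy (nose)
    walking_speed: float = 1.2        # m/s
    subject_height: float = 1.70      # m
    direction: int = 1                # +1 walks toward +x
    px_per_m: float = 500.0
    start_x_m: float = 0.5
    ground_y_px: float = 80.0         # pixel y of the lab floor (y-up)
    seed: int = 0

    def validate(self) -> None:
        if self.cadence <= 0 or self.n_cycles < 1 or self.fs <= 0:
            raise ValueError("cadence, n_cycles and fs must be positive")
        kmax = max((len(h[1]) for h in self.harmonics.values()), default=1)
        if self.fs <= 2.0 * self.cadence * kmax:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for cadence {self.cadence} "
                f"with {kmax} harmonics"
            )
        for name in ("thigh_m", "shank_m", "foot_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return round(self.n_cycles / self.cadence * self.fs)

    @property
    def start_phase(self) -> float:
        # trials open half a cycle before the first heel strike
        return -0.5


@dataclass
class CorruptionConfig:
    """Observation-noise model for synthetic keypoints.

    ``bias_deg`` rotates the shank (ankle, heel and toes) about the knee so
    the measured knee flexion shifts by exactly that many degrees while hip
    and ankle angles are untouched.
    """

    jitter_sd_px: float = 0.0
    dropout_prob: float = 0.0
    gap_prob: float = 0.0             # per-frame probability a gap burst starts
    gap_mean_frames: float = 5.0      # geometric mean burst length
    base_confidence: float = 0.95
    corrupt_confidence: float = 0.2   # below the 0.45 gate
    bias_deg: float = 0.0
    forced_gaps: tuple[tuple[int, int], ...] = ()  # (start, length) pairs
    seed: int = 0

    def validate(self) -> None:
        for p in (self.dropout_prob, self.gap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.jitter_sd_px < 0:
            raise ValueError("jitter_sd_px must be non-negative")


@dataclass
class GroundTruth:
    """Noise-free trial truth: waveforms, heel-strike times, configuration."""

    waveforms: dict[tuple[str, str], AngleSeries]
    events_s: np.ndarray              # left heel-strike times, seconds
    config: GaitConfig

    def angle(self, joint: str, side: str) -> AngleSeries:
        return self.waveforms[(joint, side)]

    @property
    def event_frames(self) -> np.ndarray:
        return np.round(self.events_s * self.config.fs).astype(int)


# ---------------------------------------------------------------------------
# Waveforms


def _eval_fourier(coeffs, phi: np.ndarray) -> np.ndarray:
    offset, harmonics = coeffs
    out = np.full_like(phi, float(offset))
    for k, (amp, phase) in enumerate(harmonics, start=1):
        out = out + amp * np.sin(2.0 * np.pi * k * phi + phase)
    return out


def _ankle_y_of_phase(config: GaitConfig, phi: np.ndarray) -> np.ndarray:
    """Vertical ankle-point coordinate (m) as a function of cycle phase."""
    hip = np.radians(_eval_fourier(config.harmonics["hip"], phi))
    knee = np.radians(_eval_fourier(config.harmonics["knee"], phi))
    phi_s = hip - knee
    return config.hip_height_m - config.thigh_m * np.cos(hip) \
        - config.shank_m * np.cos(phi_s)


def _phase_offset(config: GaitConfig) -> float:
    """Cycle phase at which the left ankle point is lowest (ground contact)."""
    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
    return float(grid[np.argmin(_ankle_y_of_phase(config, grid))])


def generate_waveforms(config: GaitConfig) -> GroundTruth:
    """Ground-truth angle series for all joints and sides plus event times.

    Each series is a truncated Fourier series over the gait cycle, evaluated
    at ``config.fs``; the right side lags the left by half a cycle.  Phase is
    shifted so heel strikes (integer phase) fall on the left ankle's height
    minima.  Deterministic for a fixed config.
    """
    config.validate()
    t = np.arange(config.n_frames) / config.fs
    phi_left = config.cadence * t + config.start_phase
    offset = _phase_offset(config)
    truth: dict[tuple[str, str], AngleSeries] = {}
    for joint, coeffs in config.harmonics.items():
        for side, lag in (("left", 0.0), ("right", 0.5)):
            vals = _eval_fourier(coeffs, phi_left + lag + offset)
            truth[(joint, side)] = AngleSeries(
                joint=joint, side=side, values=vals,
                mask=np.zeros(vals.size, dtype=bool),
                fs=config.fs, source="truth",
            )
    events = (np.arange(config.n_cycles) - config.start_phase) / config.cadence
    events = events[events < t[-1] + 0.5 / config.fs]
    return GroundTruth(waveforms=truth, events_s=events, config=config)


# ---------------------------------------------------------------------------
# Forward kinematics


def _rot(v: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rotate (..., 2) vectors counter-clockwise by ``angle`` radians."""
    c, s = np.cos(angle), np.sin(angle)
    return np.stack([c * v[..., 0] - s * v[..., 1],
                     s * v[..., 0] + c * v[..., 1]], axis=-1)


def _leg_points(truth: GroundTruth, side: str) -> dict[str, np.ndarray]:
    """Planar landmark trajectories (metres, y-up) for one leg."""
    cfg = truth.config
    d = float(np.sign(cfg.direction) or 1.0)
    t = np.arange(cfg.n_frames) / cfg.fs
    hip_xy = np.stack([cfg.start_x_m + d * cfg.walking_speed * t,
                       np.full_like(t, cfg.hip_height_m)], axis=-1)
    phi_t = np.radians(truth.angle("hip", side).values)
    phi_s = phi_t - np.radians(truth.angle("knee", side).values)
    a = np.radians(truth.angle("ankle", side).values)

    def seg(phi):
        return np.stack([d * np.sin(phi), -np.cos(phi)], axis=-1)

    u_sh = seg(phi_s)
    knee = hip_xy + cfg.thigh_m * seg(phi_t)
    ankle = knee + cfg.shank_m * u_sh
    heel = knee + (cfg.shank_m + cfg.heel_drop_m) * u_sh
    # foot line makes (90 - ankle_angle) deg with the upward shank line,
    # rotated toward the walking direction
    psi = np.pi / 2.0 - a
    toe = heel + cfg.foot_m * _rot(-u_sh, -d * psi)
    return {"hip": hip_xy, "knee": knee, "ankle": ankle, "heel": heel, "toe": toe}


_SIDE_KEYPOINTS = {
    "left": {"hip": "LHip", "knee": "LKnee", "ankle": "LAnkle",
             "heel": "LHeel", "toe": "LBigToe"},
    "right": {"hip": "RHip", "knee": "RKnee", "ankle": "RAnkle",
              "heel": "RHeel", "toe": "RBigToe"},
}

_SIDE_MARKERS = {
    "left": {"hip": "LHIP", "knee": "LKNE", "ankle": "LANK",
             "heel": "LHEE", "toe": "LTOE"},
    "right": {"hip": "RHIP", "knee": "RKNE", "ankle": "RANK",
              "heel": "RHEE", "toe": "RTOE"},
}


def project_skeleton(truth: GroundTruth) -> KeypointSeries:
    """Noise-free lateral-view keypoint series (pixels, y-up, confidence 1).

    Emits hip, knee, ankle, heel and big-toe points for both legs plus nose,
    neck and mid-hip (for height calibration); the remaining BODY_25 points
    are flagged missing.  Built so that the angle formulas recover the truth
    waveforms exactly.
    """
    cfg = truth.config
    n = cfg.n_frames
    npts = len(BODY25_NAMES)
    x = np.full((n, npts), np.nan)
    y = np.full((n, npts), np.nan)
    conf = np.zeros((n, npts))
    missing = np.ones((n, npts), dtype=bool)

    def put(name: str, xy_m: np.ndarray) -> None:
        j = BODY25_NAMES.index(name)
        x[:, j] = xy_m[:, 0] * cfg.px_per_m
        y[:, j] = xy_m[:, 1] * cfg.px_per_m + cfg.ground_y_px
        conf[:, j] = 1.0
        missing[:, j] = False

    for side in ("left", "right"):
        pts = _leg_points(truth, side)
        names = _SIDE_KEYPOINTS[side]
        for role, name in names.items():
            put(name, pts[role])
    hip_xy = _leg_points(truth, "left")["hip"]
    put("MidHip", hip_xy)
    put("Neck", hip_xy + np.array([0.0, 0.75 * cfg.trunk_m]))
    put("Nose", hip_xy + np.array([0.0, cfg.trunk_m]))
    return KeypointSeries(x=x, y=y, confidence=conf, missing=missing,
                          fs=cfg.fs, subject_height=cfg.subject_height)


def project_markers(truth: GroundTruth) -> MarkerSeries:
    """Noise-free 3-D marker trajectories (metres) for the reference system.

    Landmarks sit in the sagittal plane (x forward, y up); the mediolateral
    z coordinate is +/- half the pelvic width per side.
    """
    cfg = truth.config
    names: list[str] = []
    cols: list[np.ndarray] = []
    for side, z in (("left", 0.1), ("right", -0.1)):
        pts = _leg_points(truth, side)
        for role, name in _SIDE_MARKERS[side].items():
            names.append(name)
            xy = pts[role]
            cols.append(np.column_stack([xy[:, 0], xy[:, 1],
                                         np.full(xy.shape[0], z)]))
    data = np.stack(cols, axis=1)
    missing = np.zeros(data.shape[:2], dtype=bool)
    return MarkerSeries(data=data, missing=missing, marker_names=tuple(names),
                        fs=cfg.fs)


# ---------------------------------------------------------------------------
# Corruption


def corrupt(series: KeypointSeries, config: CorruptionConfig) -> KeypointSeries:
    """Apply the observation-noise model to a clean keypoint series.

    Seeded and reproducible; with all noise terms zero this is the identity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = series.copy()
    n = out.n_frames
    present = ~out.missing

    if config.bias_deg != 0.0:
        _inject_shank_bias(out, config.bias_deg)

    if config.jitter_sd_px > 0:
        out.x[present] += rng.normal(0.0, config.jitter_sd_px,
                                     np.count_nonzero(present))
        out.y[present] += rng.normal(0.0, config.jitter_sd_px,
                                     np.count_nonzero(present))

    conf = np.where(present, np.minimum(out.confidence, config.base_confidence),
                    out.confidence)
    corrupted = np.zeros(n, dtype=bool)
    if config.dropout_prob > 0:
        corrupted |= rng.random(n) < config.dropout_prob
    if config.gap_prob > 0:
        starts = np.flatnonzero(rng.random(n) < config.gap_prob)
        for s in starts:
            length = rng.geometric(1.0 / max(config.gap_mean_frames, 1.0))
            corrupted[s:s + length] = True
    for s, length in config.forced_gaps:
        corrupted[s:s + length] = True
    conf[corrupted] = np.minimum(conf[corrupted], config.corrupt_confidence)
    out.confidence = conf
    return out


def _inject_shank_bias(series: KeypointSeries, bias_deg: float) -> None:
    """Rotate ankle/heel/toe about the knee so knee flexion gains ``bias_deg``."""
    from .kinematics import infer_walking_direction

    hx, _, _ = series.point("MidHip")
    d = infer_walking_direction(hx)
    delta = -d * np.radians(bias_deg)  # CCW rotation achieving +bias flexion
    for side in ("left", "right"):
        names = _SIDE_KEYPOINTS[side]
        jk = series.index(names["knee"])
        kx, ky = series.x[:, jk], series.y[:, jk]
        for role in ("ankle", "heel", "toe"):
            jj = series.index(names[role])
            vx = series.x[:, jj] - kx
            vy = series.y[:, jj] - ky
            c, s = np.cos(delta), np.sin(delta)
            series.x[:, jj] = kx + c * vx - s * vy
            series.y[:, jj] = ky + s * vx + c * vy


def resample_pair(config: GaitConfig, fs_a: float = 240.0, fs_b: float = 60.0
                  ) -> tuple[MarkerSeries, KeypointSeries, GroundTruth, GroundTruth]:
    """One motion sampled at two rates: reference markers at ``fs_a`` and
    markerless keypoints at ``fs_b``.

    Both series derive from the same Fourier coefficients evaluated exactly
    at each rate (no interpolation), so a one-second trial yields 240 and 60
    frames and DTW is exercised with N != M as in a real two-system setup.
    """
    truth_a = generate_waveforms(replace(config, fs=fs_a))
    truth_b = generate_waveforms(replace(config, fs=fs_b))
    return project_markers(truth_a), project_skeleton(truth_b), truth_a, truth_b
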