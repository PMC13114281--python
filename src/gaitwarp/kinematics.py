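"""Sagittal-plane hip, knee and ankle angles from keypoints or markers.

Angle conventions (lateral view, y-up coordinates, walking direction known):

* **Hip** — the reference axis is the vertical line dropping from the hip
  centre; the thigh aligned with it reads 0 deg. The thigh advanced toward
  the walking direction (flexion) is positive.
* **Knee** — full extension (thigh and shank collinear) reads 0 deg; bending
  of the knee (shank rotated posteriorly relative to the thigh line) is
  positive flexion.
* **Ankle** — defined on the lines joining knee, heel and toe: shank and foot
  at a right angle reads 0 deg; toes lifted toward the knee (dorsiflexion)
  are positive, plantarflexion negative.

All three are invariant under translation and uniform scaling of the
coordinates; knee and ankle are additionally rotation invariant, while the
hip angle is referenced to gravity-vertical and therefore rotates with the
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .pose_io import KeypointSeries, MarkerSeries

__all__ = [
    "AngleSeries",
    "ToleranceBand",
    "JOINTS",
    "SIDES",
    "DEFAULT_ROM_DEG",
    "hip_angle",
    "knee_angle",
    "ankle_angle",
    "angle_series",
    "infer_walking_direction",
    "tolerance_band",
]

JOINTS = ("hip", "knee", "ankle")
SIDES = ("left", "right")

#: Maximum physiological range of motion per joint (degrees).  These scale
#: the tolerance band; only the band *fraction* is protocol-fixed.
DEFAULT_ROM_DEG: dict[str, float] = {"hip": 120.0, "knee": 140.0, "ankle": 70.0}

#: BODY_25 point names providing each landmark role, per side.
KEYPOINT_LANDMARKS: dict[str, dict[str, str]] = {
    "left": {"hip": "LHip", "knee": "LKnee", "ankle": "LAnkle",
             "heel": "LHeel", "toe": "LBigToe"},
    "right": {"hip": "RHip", "knee": "RKnee", "ankle": "RAnkle",
              "heel": "RHeel", "toe": "RBigToe"},
}

#: Default marker names providing each landmark role, per side (joint-centre
#: style naming; override via the ``landmarks`` argument for other marker sets).
MARKER_LANDMARKS: dict[str, dict[str, str]] = {
    "left": {"hip": "LHIP", "knee": "LKNE", "ankle": "LANK",
             "heel": "LHEE", "toe": "LTOE"},
    "right": {"hip": "RHIP", "knee": "RKNE", "ankle": "RANK",
              "heel": "RHEE", "toe": "RTOE"},
}

_JOINT_ROLES: dict[str, tuple[str, ...]] = {
    "hip": ("hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "heel", "toe"),
}


@dataclass
class AngleSeries:
    """A uniformly sampled joint-angle waveform in degrees.

    ``mask`` flags samples whose defining landmarks were missing; ``values``
    are NaN exactly where masked.
    """

    joint: str
    side: str
    values: np.ndarray
    mask: np.ndarray | None = None
    fs: float = 60.0
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.mask.shape != self.values.shape:
            raise ValueError("values and mask must have the same length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def finite_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy(self) -> "AngleSeries":
        return replace(self, values=self.values.copy(), mask=self.mask.copy())


@dataclass(frozen=True)
class ToleranceBand:
    """A constant-width envelope around a reference waveform.

    ``half_width = fraction x ROM(joint)``; with the protocol fraction of 0.30
    and the default knee ROM of 140 deg the band is +/-42 deg.
    """

    center: AngleSeries
    half_width: float
    fraction: float

    def coverage(self, comparison: AngleSeries | np.ndarray) -> float:
        """Percent of comparison samples inside the band (pairwise by index)."""
        vals = comparison.values if isinstance(comparison, AngleSeries) else np.asarray(comparison, float)
        n = min(vals.size, self.center.n_samples)
        c = self.center.values[:n]
        v = vals[:n]
        ok = np.isfinite(c) & np.isfinite(v)
        if not np.any(ok):
            raise ValueError("no overlapping finite samples to compare")
        inside = np.abs(v[ok] - c[ok]) <= self.half_width
        return 100.0 * float(np.mean(inside))


# ---------------------------------------------------------------------------
# Point-level angle formulas (vectorised; points are (..., 2) arrays, y-up)


def _as_pts(p) -> np.ndarray:
    return np.asarray(p, dtype=float)


def _coincident(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.all(np.isclose(a, b, rtol=0.0, atol=1e-12), axis=-1)


def hip_angle(hip_pt, knee_pt, direction: float = 1.0) -> np.ndarray:
    """Signed thigh angle from the downward vertical through the hip, degrees.

    ``direction`` is +1 when the subject walks toward +x, -1 toward -x;
    anterior displacement of the knee is positive (flexion).  Coincident
    points yield NaN.
    """
    hip, knee = _as_pts(hip_pt), _as_pts(knee_pt)
    v = knee - hip
    ang = np.degrees(np.arctan2(np.sign(direction) * v[..., 0], -v[..., 1]))
    return np.where(_coincident(hip, knee), np.nan, ang)


def knee_angle(hip_pt, knee_pt, ankle_pt) -> np.ndarray:
    """Knee flexion in degrees: 180 minus the interior angle at the knee.

    Collinear thigh and shank (full extension) read 0; bending of the knee
    reads positive, whichever side the shank rotates to — symmetric in
    swapping the hip and ankle points.
    """
    hip, knee, ankle = _as_pts(hip_pt), _as_pts(knee_pt), _as_pts(ankle_pt)
    t = knee - hip          # thigh extension direction at the knee
    w = ankle - knee        # shank direction
    cross = t[..., 0] * w[..., 1] - t[..., 1] * w[..., 0]
    dot = t[..., 0] * w[..., 0] + t[..., 1] * w[..., 1]
    ang = np.abs(np.degrees(np.arctan2(cross, dot)))
    bad = _coincident(hip, knee) | _coincident(knee, ankle) | _coincident(hip, ankle)
    return np.where(bad, np.nan, ang)


def ankle_angle(knee_pt, heel_pt, toe_pt) -> np.ndarray:
    """Ankle dorsi(+)/plantar(-)flexion in degrees.

    90 deg between the shank line (heel->knee) and the foot line (heel->toe)
    is the neutral 0; smaller interior angles (toes toward the knee) are
    positive dorsiflexion.
    """
    knee, heel, toe = _as_pts(knee_pt), _as_pts(heel_pt), _as_pts(toe_pt)
    s = knee - heel
    f = toe - heel
    denom = np.linalg.norm(s, axis=-1) * np.linalg.norm(f, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (s[..., 0] * f[..., 0] + s[..., 1] * f[..., 1]) / denom
    interior = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bad = _coincident(knee, heel) | _coincident(heel, toe) | _coincident(knee, toe)
    return np.where(bad, np.nan, 90.0 - interior)


# ---------------------------------------------------------------------------
# Series-level computation


def infer_walking_direction(x: np.ndarray) -> float:
    """+1 if the net horizontal displacement is toward +x, else -1.

    Falls back to +1 when the trajectory has no net displacement (static
    poses); pass ``direction`` explicitly in that case if it matters.
    """
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        return 1.0
    net = finite[-1] - finite[0]
    return -1.0 if net < 0 else 1.0


def _sagittal_projection(series: MarkerSeries, name: str,
                         forward_axis: int, vertical_axis: int):
    xyz, miss = series.marker(name)
    pts = np.stack([xyz[:, forward_axis], xyz[:, vertical_axis]], axis=-1)
    return pts, miss


def angle_series(
    series: KeypointSeries | MarkerSeries,
    joint: str,
    side: str,
    direction: float | None = None,
    landmarks: Mapping[str, Mapping[str, str]] | None = None,
    forward_axis: int = 0,
    vertical_axis: int = 1,
) -> AngleSeries:
    """Per-frame sagittal angle series for one joint and side.

    For 3-D marker input, coordinates are first projected onto the sagittal
    plane by keeping the forward and vertical lab axes (the mediolateral axis
    is dropped).  Missing input landmarks propagate into the output mask.
    Walking direction is inferred from the net horizontal hip displacement
    unless given.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")

    if isinstance(series, KeypointSeries):
        table = (landmarks or KEYPOINT_LANDMARKS)[side]
        def get(role):
            name = table[role]
            x, y, miss = series.point(name)
            return np.stack([x, y], axis=-1), miss
        hip_x = series.point(table["hip"])[0]
        fs = series.fs
        source = "markerless"
    elif isinstance(series, MarkerSeries):
        table = (landmarks or MARKER_LANDMARKS)[side]
        series.require([table[r] for r in _JOINT_ROLES[joint]])
        def get(role):
            return _sagittal_projection(series, table[role], forward_axis, vertical_axis)
        hip_name = table["hip"]
        if hip_name in series.marker_names:
            hip_x = series.marker(hip_name)[0][:, forward_axis]
        else:
            hip_x = get(_JOINT_ROLES[joint][0])[0][:, 0]
        fs = series.fs
        source = "reference"
    else:
        raise TypeError(f"unsupported series type {type(series)!r}")

    roles = _JOINT_ROLES[joint]
    pts, masks = zip(*(get(r) for r in roles))
    mask = np.zeros(pts[0].shape[0], dtype=bool)
    for m in masks:
        mask |= m

    if direction is None:
        direction = infer_walking_direction(hip_x)

    with np.errstate(invalid="ignore"):
        if joint == "hip":
            vals = hip_angle(pts[0], pts[1], direction=direction)
        elif joint == "knee":
            vals = knee_angle(pts[0], pts[1], pts[2])
        else:
            vals = ankle_angle(pts[0], pts[1], pts[2])
    mask |= ~np.isfinite(vals)
    vals = np.where(mask, np.nan, vals)
    return AngleSeries(joint=joint, side=side, values=vals, mask=mask,
                       fs=fs, source=source)


def tolerance_band(
    reference: AngleSeries,
    fraction: float = 0.30,
    rom_table: Mapping[str, float] | None = None,
) -> ToleranceBand:
    """Constant tolerance envelope: half-width = fraction x physiological ROM."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rom_table = dict(DEFAULT_ROM_DEG if rom_table is None else rom_table)
    if reference.joint not in rom_table:
        raise KeyError(
            f"joint {reference.joint!r} has no entry in the ROM table "
            f"(known: {sorted(rom_table)})"
        )
    return ToleranceBand(center=reference,
                         half_width=fraction * float(rom_table[reference.joint]),
                         fraction=fraction)
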