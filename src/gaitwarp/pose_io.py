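"""Readers and writers for pose keypoints, marker trajectories and angle tables.

This module fixes the coordinate and indexing conventions used by the rest
of the pipeline:

* Image coordinates are converted to a y-up convention at read time
  (``y_up = image_height - y_image``), so every downstream angle formula can
  treat "up" as positive without sign gymnastics.
* Frame indexing is 0-based and time is ``frame_index / fs``.
* Missing samples are carried in explicit boolean masks, never as sentinel
  coordinates — (0, 0) is a legal pixel.

Supported on-disk formats:

* BODY_25 keypoint JSON — one file per frame (the standard per-frame dialect
  with a flat ``pose_keypoints_2d`` array of 75 values), or a single
  concatenated JSON file holding a list of frame objects.
* Marker trajectories — TRC (tab-delimited, two header blocks) or plain CSV
  with ``NAME_X/NAME_Y/NAME_Z`` columns.
* Angle series — CSV with ``# key: value`` metadata lines.
* Agreement reports — JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BODY25_NAMES",
    "FormatError",
    "Keypoint",
    "KeypointFrame",
    "KeypointSeries",
    "MarkerSeries",
    "flip_y",
    "read_keypoint_json_dir",
    "write_keypoint_json_dir",
    "read_marker_table",
    "write_marker_trc",
    "write_marker_csv",
    "read_angle_table",
    "write_angle_table",
    "write_report",
]

#: The 25-point skeleton vocabulary emitted by BODY_25-style pose estimators,
#: in estimator output order (triplet i of the flat array is point i).
BODY25_NAMES: tuple[str, ...] = (
    "Nose", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "MidHip",
    "RHip", "RKnee", "RAnkle",
    "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
    "LBigToe", "LSmallToe", "LHeel",
    "RBigToe", "RSmallToe", "RHeel",
)


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class Keypoint(NamedTuple):
    """One detected 2-D point: coordinates in pixels, confidence in [0, 1]."""

    x: float
    y: float
    confidence: float
    missing: bool = False


@dataclass(frozen=True)
class KeypointFrame:
    """A single frame's view of a :class:`KeypointSeries`."""

    frame_index: int
    points: Mapping[str, Keypoint]


@dataclass
class KeypointSeries:
    """Per-frame 2-D keypoints with confidences for one tracked person.

    Arrays are shaped ``(n_frames, n_points)``; ``missing`` flags samples
    that carry no usable coordinate (undetected point, gated confidence,
    absent person).  Coordinates are y-up.
    """

    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    fs: float
    point_names: tuple[str, ...] = BODY25_NAMES
    frame_indices: np.ndarray | None = None
    subject_height: float | None = None
    units: str = "px"
    scale: float | None = None  # metres per pixel once calibrated

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.x.shape == self.y.shape == self.confidence.shape == self.missing.shape):
            raise ValueError("x, y, confidence and missing must share one shape")
        if self.x.ndim != 2 or self.x.shape[1] != len(self.point_names):
            raise ValueError(
                f"expected (n_frames, {len(self.point_names)}) arrays, got {self.x.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.n_frames)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if np.any(np.diff(self.frame_indices) <= 0):
                raise ValueError("frame indices must be strictly increasing")
        finite = np.isfinite(self.x) & np.isfinite(self.y)
        if np.any(~finite & ~self.missing):
            raise ValueError("non-finite coordinates must be flagged missing")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.frame_indices / self.fs

    def index(self, name: str) -> int:
        try:
            return self.point_names.index(name)
        except ValueError:
            raise KeyError(f"unknown skeleton point {name!r}") from None

    def point(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(x, y, missing)`` trajectories for one named point."""
        j = self.index(name)
        return self.x[:, j], self.y[:, j], self.missing[:, j]

    def frame(self, t: int) -> KeypointFrame:
        pts = {
            name: Keypoint(
                float(self.x[t, j]), float(self.y[t, j]),
                float(self.confidence[t, j]), bool(self.missing[t, j]),
            )
            for j, name in enumerate(self.point_names)
        }
        return KeypointFrame(int(self.frame_indices[t]), pts)

    def frames(self) -> Iterator[KeypointFrame]:
        for t in range(self.n_frames):
            yield self.frame(t)

    def copy(self) -> "KeypointSeries":
        return replace(
            self,
            x=self.x.copy(), y=self.y.copy(),
            confidence=self.confidence.copy(), missing=self.missing.copy(),
            frame_indices=np.asarray(self.frame_indices).copy(),
        )


@dataclass
class MarkerSeries:
    """Per-frame 3-D marker (or joint-centre) trajectories in metres.

    ``data`` is shaped ``(n_frames, n_markers, 3)``; ``missing`` flags whole
    marker samples whose coordinates could not be reconstructed.
    """

    data: np.ndarray
    missing: np.ndarray
    marker_names: tuple[str, ...]
    fs: float
    frame_indices: np.ndarray | None = None
    units: str = "m"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("data must be (n_frames, n_markers, 3)")
        if self.missing.shape != self.data.shape[:2]:
            raise ValueError("missing must be (n_frames, n_markers)")
        if len(self.marker_names) != self.data.shape[1]:
            raise ValueError("marker_names length must match data")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.n_frames)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.frame_indices / self.fs

    def index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def marker(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(xyz, missing)`` for one marker; xyz is (n_frames, 3)."""
        j = self.index(name)
        return self.data[:, j, :], self.missing[:, j]

    def require(self, names: Sequence[str]) -> None:
        absent = [n for n in names if n not in self.marker_names]
        if absent:
            raise KeyError(
                "marker table is missing required markers: " + ", ".join(absent)
            )


def flip_y(y: np.ndarray | float, image_height: float) -> np.ndarray | float:
    """Convert image-down y to y-up (or back; the flip is an involution)."""
    return image_height - np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# BODY_25 keypoint JSON


def _frame_from_person(arr: Sequence[float], image_height: float, n_points: int):
    vals = np.asarray(arr, dtype=float)
    if vals.size % 3 != 0:
        raise FormatError("pose_keypoints_2d length is not a multiple of 3")
    trip = vals.reshape(-1, 3)[:n_points]
    x = np.full(n_points, np.nan)
    y = np.full(n_points, np.nan)
    c = np.zeros(n_points)
    k = trip.shape[0]
    x[:k], y[:k], c[:k] = trip[:, 0], flip_y(trip[:, 1], image_height), trip[:, 2]
    missing = (c <= 0.0) | ~np.isfinite(x) | ~np.isfinite(y)
    x[missing] = np.nan
    y[missing] = np.nan
    return x, y, c, missing


def _empty_frame(n_points: int):
    nan = np.full(n_points, np.nan)
    return nan, nan.copy(), np.zeros(n_points), np.ones(n_points, dtype=bool)


def read_keypoint_json_dir(
    directory: str | Path,
    person_index: int = 0,
    fs: float = 60.0,
    image_height: float = 1080.0,
) -> KeypointSeries:
    """Read a directory of per-frame BODY_25 JSON files (one file per frame).

    Files are taken in lexicographic order, which matches frame order for the
    zero-padded names the estimator writes.  A frame with no detected person
    (or fewer people than ``person_index + 1``) yields an all-missing frame,
    not an error.  A single concatenated JSON file (a list of frame objects,
    or ``{"frames": [...]}``) is accepted through the same entry point.

    Image y (downward-positive) is flipped to y-up here, once, for the whole
    pipeline.
    """
    directory = Path(directory)
    n_pts = len(BODY25_NAMES)
    if directory.is_file():
        payloads = _load_concatenated(directory)
        sources = [directory.name] * len(payloads)
    else:
        files = sorted(p for p in directory.iterdir() if p.suffix == ".json")
        if not files:
            raise FormatError(f"no JSON files found in {directory}")
        payloads, sources = [], []
        for p in files:
            try:
                payloads.append(json.loads(p.read_text()))
            except json.JSONDecodeError as exc:
                raise FormatError(f"{p.name}: malformed JSON ({exc})") from exc
            sources.append(p.name)

    xs, ys, cs, ms = [], [], [], []
    for payload, src in zip(payloads, sources):
        people = payload.get("people", [])
        if person_index < len(people):
            try:
                row = _frame_from_person(
                    people[person_index]["pose_keypoints_2d"], image_height, n_pts
                )
            except FormatError as exc:
                raise FormatError(f"{src}: {exc}") from exc
        else:
            row = _empty_frame(n_pts)
        xs.append(row[0]); ys.append(row[1]); cs.append(row[2]); ms.append(row[3])

    return KeypointSeries(
        x=np.vstack(xs), y=np.vstack(ys), confidence=np.vstack(cs),
        missing=np.vstack(ms), fs=fs,
    )


def _load_concatenated(path: Path) -> list[dict]:
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: malformed JSON ({exc})") from exc
    if isinstance(obj, dict) and "frames" in obj:
        obj = obj["frames"]
    if not isinstance(obj, list):
        raise FormatError(f"{path.name}: expected a list of frame objects")
    return obj


def write_keypoint_json_dir(
    series: KeypointSeries,
    directory: str | Path,
    image_height: float = 1080.0,
) -> None:
    """Write one BODY_25 JSON file per frame (inverse of the reader's y-flip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(series.n_frames):
        x = series.x[t].copy()
        y = flip_y(series.y[t], image_height)
        c = series.confidence[t].copy()
        m = series.missing[t]
        x[m] = 0.0
        y = np.asarray(y)
        y[m] = 0.0
        c = np.where(m & (c > 0), 0.0, c)
        flat = np.column_stack([x, y, c]).ravel().tolist()
        payload = {"version": 1.3, "people": [{"pose_keypoints_2d": flat}]}
        name = f"frame_{int(series.frame_indices[t]):012d}_keypoints.json"
        (directory / name).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Marker tables (TRC and CSV)


def read_marker_table(
    path: str | Path,
    fs: float | None = None,
    required: Sequence[str] | None = None,
) -> MarkerSeries:
    """Read a TRC or plain-CSV marker trajectory table.

    TRC carries its sampling rate in the header; for CSV, ``fs`` must be given
    or a ``time`` column present.  Blank cells become flagged-missing samples.
    ``required`` markers, if given, are checked and reported by name.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if path.suffix.lower() == ".trc" or first.startswith("PathFileType"):
        series = _read_trc(path)
    else:
        series = _read_marker_csv(path, fs)
    if required is not None:
        series.require(required)
    return series


def _read_trc(path: Path) -> MarkerSeries:
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise FormatError(f"{path.name}: truncated TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        fs = float(header["DataRate"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path.name}: missing or invalid DataRate header") from exc
    name_row = lines[3].split("\t")
    marker_names = tuple(n for n in name_row[2:] if n.strip())

    frames, rows, missing_rows = [], [], []
    for line in lines[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        frames.append(int(float(cells[0])))
        vals = np.full((len(marker_names), 3), np.nan)
        for j in range(len(marker_names)):
            for k in range(3):
                idx = 2 + 3 * j + k
                if idx < len(cells) and cells[idx].strip():
                    vals[j, k] = float(cells[idx])
        rows.append(vals)
        missing_rows.append(~np.all(np.isfinite(vals), axis=1))
    if not rows:
        raise FormatError(f"{path.name}: TRC file has no data rows")
    data = np.stack(rows)
    missing = np.stack(missing_rows)
    data[missing] = np.nan
    return MarkerSeries(
        data=data, missing=missing, marker_names=marker_names, fs=fs,
        frame_indices=np.asarray(frames) - frames[0],
    )


def _read_marker_csv(path: Path, fs: float | None) -> MarkerSeries:
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    time_col = lower.get("time") or lower.get("time_s")
    if fs is None:
        if time_col is None or len(df) < 2:
            raise FormatError(f"{path.name}: no sampling rate and no time column")
        dt = np.diff(df[time_col].to_numpy())
        if np.any(dt <= 0):
            raise FormatError(f"{path.name}: time column not strictly increasing")
        fs = 1.0 / float(np.mean(dt))
    names: list[str] = []
    for c in df.columns:
        if c.upper().endswith("_X"):
            base = c[:-2]
            if f"{base}_Y" in df.columns and f"{base}_Z" in df.columns:
                names.append(base)
    if not names:
        raise FormatError(f"{path.name}: no NAME_X/NAME_Y/NAME_Z marker columns found")
    data = np.stack(
        [df[[f"{n}_X", f"{n}_Y", f"{n}_Z"]].to_numpy(dtype=float) for n in names],
        axis=1,
    )
    missing = ~np.all(np.isfinite(data), axis=2)
    data[missing] = np.nan
    return MarkerSeries(data=data, missing=missing, marker_names=tuple(names), fs=fs)


def write_marker_trc(series: MarkerSeries, path: str | Path) -> None:
    """Write a MarkerSeries as a TRC file (blank cells for missing samples)."""
    path = Path(path)
    n, k = series.n_frames, len(series.marker_names)
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{series.fs:g}\t{series.fs:g}\t{n}\t{k}\t{series.units}\t{series.fs:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(series.marker_names) + "\t\t",
        "\t\t" + "\t".join(f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(k)),
    ]
    for t in range(n):
        cells = [str(int(series.frame_indices[t]) + 1), f"{series.times[t]:.9f}"]
        for j in range(k):
            if series.missing[t, j]:
                cells.extend(["", "", ""])
            else:
                cells.extend(f"{v:.9f}" for v in series.data[t, j])
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")


def write_marker_csv(series: MarkerSeries, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {
        "frame": np.asarray(series.frame_indices),
        "time": series.times,
    }
    for j, name in enumerate(series.marker_names):
        for k, ax in enumerate("XYZ"):
            col = series.data[:, j, k].copy()
            col[series.missing[:, j]] = np.nan
            cols[f"{name}_{ax}"] = col
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Angle tables


def read_angle_table(path: str | Path):
    """Read an angle-series CSV (two columns ``time_s, angle_deg`` plus
    ``# key: value`` metadata lines carrying joint, side, fs and source)."""
    from .kinematics import AngleSeries  # late import; kinematics depends on us

    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
        elif line.strip():
            break
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "angle_deg"}.issubset(df.columns):
        raise FormatError(f"{path.name}: expected columns time_s, angle_deg")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path.name}: time column is not strictly increasing")
    try:
        fs = float(meta["fs"])
    except KeyError:
        if len(t) < 2:
            raise FormatError(f"{path.name}: cannot infer fs from a single row")
        fs = 1.0 / float(np.mean(np.diff(t)))
    values = df["angle_deg"].to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    return AngleSeries(
        joint=meta.get("joint", "unknown"),
        side=meta.get("side", "unknown"),
        values=values,
        mask=mask,
        fs=fs,
        source=meta.get("source", "unknown"),
    )


def write_angle_table(series, path: str | Path) -> None:
    """Write an angle series; finite values round-trip losslessly."""
    path = Path(path)
    if series.n_samples == 0:
        raise ValueError("refusing to write an empty angle series")
    lines = [
        f"# joint: {series.joint}",
        f"# side: {series.side}",
        f"# fs: {series.fs!r}",
        f"# source: {series.source}",
        "time_s,angle_deg",
    ]
    t = series.times
    for i in range(series.n_samples):
        val = "" if series.mask[i] else repr(float(series.values[i]))
        lines.append(f"{float(t[i])!r},{val}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reports

_REPORT_KEYS = ("joint", "side", "similarity", "bias", "sd_diff",
                "loa_low", "loa_high", "r", "n")


def write_report(results: Sequence[Mapping] | Mapping, path: str | Path,
                 meta: Mapping | None = None) -> None:
    """Write a machine-readable agreement report (JSON).

    ``results`` is one row or a sequence of rows, one per joint/side; each
    non-excluded row must carry at least similarity, bias, sd_diff, loa_low,
    loa_high, r and n.
    """
    if isinstance(results, Mapping):
        results = [results]
    rows = []
    for row in results:
        row = dict(row)
        if not row.get("excluded", False):
            missing = [k for k in _REPORT_KEYS if k not in row]
            if missing:
                raise ValueError(f"report row missing keys: {missing}")
        rows.append(row)
    payload = {"meta": dict(meta or {}), "results": rows}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
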