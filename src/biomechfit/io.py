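"""File I/O for marker and force data plus plate-to-foot assignment.

Supported formats are plain-text motion-capture standards: TRC for marker
trajectories and tab-delimited MOT for ground-reaction-force data and for
joint angle / torque output.  Angles cross the I/O boundary in degrees
(``inDegrees=yes``); everything is radians and SI internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .skeleton import Skeleton

FORCE_THRESHOLD_N = 10.0
FOOT_HEIGHT_THRESHOLD_M = 0.05


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrial:
    """Labeled marker trajectories with per-frame visibility."""

    labels: List[str]
    positions: np.ndarray  # (T, M, 3), meters; NaN where invisible
    visible: np.ndarray    # (T, M) bool
    frame_rate: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.visible = np.asarray(self.visible, bool)
        T, M, _ = self.positions.shape
        if T < 2:
            raise ParseError("marker trial needs at least 2 frames")
        if len(set(self.labels)) != len(self.labels):
            raise ParseError("duplicate marker labels")
        if self.visible.shape != (T, M):
            raise ParseError("visibility mask shape mismatch")
        if not np.all(np.isfinite(self.positions[self.visible])):
            raise ParseError("non-finite marker positions flagged visible")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def reordered(self, labels: Sequence[str]) -> "MarkerTrial":
        """Restrict/reorder columns to the given labels; missing labels become
        fully-occluded columns."""
        T = self.n_frames
        pos = np.full((T, len(labels), 3), np.nan)
        vis = np.zeros((T, len(labels)), bool)
        index = {l: i for i, l in enumerate(self.labels)}
        for k, lab in enumerate(labels):
            if lab in index:
                pos[:, k] = self.positions[:, index[lab]]
                vis[:, k] = self.visible[:, index[lab]]
        return MarkerTrial(list(labels), pos, vis, self.frame_rate)


@dataclass
class ForcePlate:
    force: np.ndarray   # (T, 3) N
    cop: np.ndarray     # (T, 3) m
    torque: np.ndarray  # (T, 3) N*m, free moment at the CoP
    corners: Optional[np.ndarray] = None  # (4, 3) world rectangle corners

    def __post_init__(self):
        self.force = np.asarray(self.force, float)
        self.cop = np.asarray(self.cop, float)
        self.torque = np.asarray(self.torque, float)
        if not np.all(np.isfinite(self.force)):
            raise ParseError("non-finite plate forces")

    def active(self, threshold: float = FORCE_THRESHOLD_N) -> np.ndarray:
        return np.linalg.norm(self.force, axis=1) > threshold

    def rectangle_xz(self) -> np.ndarray:
        """Horizontal bounding rectangle [[xmin, zmin], [xmax, zmax]]."""
        if self.corners is not None:
            pts = self.corners[:, [0, 2]]
            return np.array([pts.min(axis=0), pts.max(axis=0)])
        act = self.active()
        if not act.any():
            return np.array([[np.inf, np.inf], [-np.inf, -np.inf]])
        pts = self.cop[act][:, [0, 2]]
        return np.array([pts.min(axis=0) - 0.2, pts.max(axis=0) + 0.2])


@dataclass
class GrfTrial:
    plates: List[ForcePlate]
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.plates[0].force.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def total_force(self) -> np.ndarray:
        return sum(p.force for p in self.plates)

    def resampled(self, times: np.ndarray) -> "GrfTrial":
        """Linear interpolation of plate channels at the given timestamps."""
        own = self.times
        rate = 1.0 / np.mean(np.diff(times)) if len(times) > 1 else self.frame_rate
        plates = []
        for p in self.plates:
            def interp(arr):
                return np.column_stack(
                    [np.interp(times, own, arr[:, k]) for k in range(arr.shape[1])]
                )
            plates.append(ForcePlate(interp(p.force), interp(p.cop), interp(p.torque),
                                     corners=p.corners))
        return GrfTrial(plates, rate)


@dataclass
class FootAssignment:
    """Per frame, per plate: assigned foot segment name or None."""
    assignment: List[List[Optional[str]]]  # (T)(n_plates)

    def plate_feet(self, plate: int) -> List[Optional[str]]:
        return [row[plate] for row in self.assignment]

    def as_array(self) -> np.ndarray:
        return np.array(self.assignment, object)


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(path) -> MarkerTrial:
    """Read a TRC marker file; blank cells become invisible frames."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise ParseError(f"{path}: truncated TRC file")
    if not lines[0].startswith("PathFileType"):
        raise ParseError(f"{path}:1: expected PathFileType header")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    hdr = dict(zip(keys, vals))
    try:
        rate = float(hdr["DataRate"])
        n_frames = int(hdr["NumFrames"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr["Units"].strip().lower()
    except (KeyError, ValueError) as e:
        raise ParseError(f"{path}:3: malformed TRC header ({e})") from e
    label_row = lines[3].split("\t")
    labels = [l for l in label_row[2:] if l.strip()]
    if len(labels) != n_markers:
        raise ParseError(f"{path}:4: {len(labels)} labels, header says {n_markers}")
    scale = 0.001 if units == "mm" else 1.0

    data_lines = [l for l in lines[5:] if l.strip()]
    if len(data_lines) != n_frames:
        warnings.warn(f"{path}: NumFrames={n_frames} but {len(data_lines)} data rows")
        n_frames = len(data_lines)
    pos = np.full((n_frames, n_markers, 3), np.nan)
    for t, line in enumerate(data_lines):
        cells = line.split("\t")
        expected = 2 + 3 * n_markers
        if len(cells) > expected:
            raise ParseError(f"{path}:{6 + t}: {len(cells)} columns, expected {expected}")
        cells += [""] * (expected - len(cells))
        for m in range(n_markers):
            triplet = cells[2 + 3 * m: 5 + 3 * m]
            if all(c.strip() for c in triplet):
                try:
                    pos[t, m] = [float(c) for c in triplet]
                except ValueError as e:
                    raise ParseError(f"{path}:{6 + t}: bad number ({e})") from e
    pos *= scale
    visible = np.all(np.isfinite(pos), axis=2)
    return MarkerTrial(labels, pos, visible, rate)


def write_trc(trial: MarkerTrial, path, units: str = "m"):
    scale = 1000.0 if units == "mm" else 1.0
    T, M = trial.n_frames, trial.n_markers
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{trial.frame_rate:g}\t{trial.frame_rate:g}\t{T}\t{M}\t{units}\t"
                 f"{trial.frame_rate:g}\t1\t{T}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(trial.labels) + "\t\t\n")
        comps = "\t".join(f"X{m + 1}\tY{m + 1}\tZ{m + 1}" for m in range(M))
        fh.write(f"\t\t{comps}\n")
        for t in range(T):
            cells = [str(t + 1), f"{t / trial.frame_rate:.8f}"]
            for m in range(M):
                if trial.visible[t, m]:
                    cells += [f"{v * scale:.8f}" for v in trial.positions[t, m]]
                else:
                    cells += ["", "", ""]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# MOT
# ---------------------------------------------------------------------------

def _read_mot_table(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    hdr: Dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            body_start = i + 1
            break
        if "=" in line:
            k, v = line.split("=", 1)
            hdr[k.strip()] = v.strip()
    if body_start is None:
        raise ParseError(f"{path}: missing endheader")
    cols = lines[body_start].split("\t")
    df = pd.read_csv(path, sep="\t", skiprows=body_start, header=0)
    df.columns = [c.strip() for c in cols]
    if "nRows" in hdr and int(hdr["nRows"]) != len(df):
        warnings.warn(f"{path}: nRows={hdr['nRows']} but {len(df)} rows")
    if "nColumns" in hdr and int(hdr["nColumns"]) != len(df.columns):
        raise ParseError(f"{path}: nColumns={hdr['nColumns']} but {len(df.columns)} columns")
    return hdr, df


def _write_mot(path, name: str, df: pd.DataFrame, in_degrees: bool):
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={len(df)}\nnColumns={len(df.columns)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("\t".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(), fmt="%.10g", delimiter="\t")


def read_grf_mot(path, plate_corners: Optional[Sequence[np.ndarray]] = None) -> GrfTrial:
    """Read GRF data: per plate, columns ``p<k>_force_[xyz]``, ``p<k>_cop_[xyz]``
    and ``p<k>_torque_[xyz]`` plus a leading ``time`` column."""
    hdr, df = _read_mot_table(path)
    t = df["time"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 frames")
    rate = 1.0 / np.mean(np.diff(t))
    plates = []
    k = 1
    while f"p{k}_force_x" in df.columns:
        def block(stem):
            return df[[f"p{k}_{stem}_{ax}" for ax in "xyz"]].to_numpy()
        corners = None
        if plate_corners is not None and k - 1 < len(plate_corners):
            corners = np.asarray(plate_corners[k - 1], float)
        plates.append(ForcePlate(block("force"), block("cop"), block("torque"), corners))
        k += 1
    if not plates:
        raise ParseError(f"{path}: no force plate columns found")
    return GrfTrial(plates, rate)


def write_grf_mot(grf: GrfTrial, path):
    data = {"time": grf.times}
    for k, p in enumerate(grf.plates, start=1):
        for stem, arr in (("force", p.force), ("cop", p.cop), ("torque", p.torque)):
            for j, ax in enumerate("xyz"):
                data[f"p{k}_{stem}_{ax}"] = arr[:, j]
    _write_mot(path, "ground reaction forces", pd.DataFrame(data), in_degrees=False)


def write_motion_mot(q_traj: np.ndarray, coordinate_names: Sequence[str],
                     frame_rate: float, path,
                     rotational: Optional[np.ndarray] = None):
    """Write a joint-coordinate trajectory; rotational coordinates are
    converted to degrees (``inDegrees=yes``)."""
    q_traj = np.asarray(q_traj, float)
    out = q_traj.copy()
    if rotational is not None:
        out[:, rotational] = np.degrees(out[:, rotational])
    data = {"time": np.arange(len(out)) / frame_rate}
    for i, name in enumerate(coordinate_names):
        data[name] = out[:, i]
    _write_mot(path, "coordinates", pd.DataFrame(data), in_degrees=True)


def read_motion_mot(path, rotational: Optional[np.ndarray] = None):
    """Read a joint-coordinate MOT; returns (names, q_traj, frame_rate)."""
    hdr, df = _read_mot_table(path)
    t = df["time"].to_numpy()
    rate = 1.0 / np.mean(np.diff(t)) if len(t) > 1 else 0.0
    names = [c for c in df.columns if c != "time"]
    q = df[names].to_numpy()
    if hdr.get("inDegrees", "no").lower() == "yes" and rotational is not None:
        q[:, rotational] = np.radians(q[:, rotational])
    return names, q, rate


# ---------------------------------------------------------------------------
# Plate-to-foot assignment
# ---------------------------------------------------------------------------

def assign_plates_to_feet(
    skel: Skeleton,
    q_traj: np.ndarray,
    grf: GrfTrial,
    foot_segments: Sequence[str] = ("foot_r", "foot_l"),
    force_threshold: float = FORCE_THRESHOLD_N,
    height_threshold: float = FOOT_HEIGHT_THRESHOLD_M,
) -> FootAssignment:
    """Assign each active force plate to the foot standing on it.

    A plate is assigned to a foot when the foot origin is horizontally inside
    the plate rectangle and its sole is below the height threshold while the
    plate force magnitude exceeds the force threshold.  If both feet qualify,
    the foot closer to the plate's center of pressure wins (with a warning).
    """
    from .models import foot_sole_drop

    T = len(q_traj)
    foot_idx = [skel.segment_index(f) for f in foot_segments]
    drops = [foot_sole_drop(skel, f) for f in foot_segments]
    origins = np.zeros((T, len(foot_idx), 3))
    for t in range(T):
        st = skel.fk_state(q_traj[t])
        origins[t] = st.o[foot_idx]

    rects = [p.rectangle_xz() for p in grf.plates]
    actives = [p.active(force_threshold) for p in grf.plates]
    rows: List[List[Optional[str]]] = []
    warned = False
    for t in range(T):
        row: List[Optional[str]] = []
        for pi, plate in enumerate(grf.plates):
            if not actives[pi][t]:
                row.append(None)
                continue
            lo, hi = rects[pi]
            candidates = []
            for fi, fname in enumerate(foot_segments):
                x, y, z = origins[t, fi]
                sole = y - drops[fi]
                inside = lo[0] <= x <= hi[0] and lo[1] <= z <= hi[1]
                if inside and sole < height_threshold:
                    d = np.linalg.norm(origins[t, fi][[0, 2]] - plate.cop[t][[0, 2]])
                    candidates.append((d, fname))
            if len(candidates) > 1 and not warned:
                warnings.warn("both feet plausibly on one plate; assigning nearer foot")
                warned = True
            row.append(min(candidates)[1] if candidates else None)
        rows.append(row)
    return FootAssignment(rows)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(solution, path):
    """Serialize a solution's summary metrics to JSON."""
    with open(path, "w") as fh:
        json.dump(solution.report_dict(), fh, indent=1, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
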