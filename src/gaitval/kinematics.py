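"""Per-cycle gait variables, joint angles and cycle-normalised traces.

The scalar variable set (one row per cycle, 12 columns) mirrors standard
treadmill gait analysis of the cat hindlimb:

* step length — horizontal distance between the two hindpaw toes at the
  analyzed limb's contact;
* stride length — toe displacement during stance plus belt travel during
  swing (swing duration x belt speed), since on a treadmill the animal
  itself covers no ground;
* toe–hip horizontal distance at contact (positive: toe rostral of hip)
  and at liftoff (generally negative);
* hip, knee, ankle and MTP joint angles at contact and at liftoff.

Joint angles are the included angle at the vertex of two adjacent
segments, in degrees; a decreasing angle means flexion (hip, knee) or
dorsiflexion (ankle, MTP).  Angle traces over a cycle are resampled onto
256 bins for across-cycle averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DegenerateGeometryError,
    TooShortCycleError,
    UnreachablePoseError,
)
from .gait_events import CycleSet
from .pose_io import PoseTrack, TrialConfig

#: Joint name -> (proximal, vertex, distal) marker roles.
JOINT_DEFINITIONS: dict[str, tuple[str, str, str]] = {
    "hip": ("crest", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "mtp"),
    "mtp": ("ankle", "mtp", "toe"),
}

#: Column order of the per-cycle variable table.
VARIABLE_COLUMNS = (
    "step_length",
    "stride_length",
    "toe_hip_distance_contact",
    "toe_hip_distance_liftoff",
    "hip_angle_contact",
    "hip_angle_liftoff",
    "knee_angle_contact",
    "knee_angle_liftoff",
    "ankle_angle_contact",
    "ankle_angle_liftoff",
    "mtp_angle_contact",
    "mtp_angle_liftoff",
)

N_BINS = 256


@dataclass(frozen=True)
class CycleSeries:
    """Across-cycle summary of one joint's 256-bin angle traces.

    ``traces`` has one row per cycle; ``mean`` and ``sd`` are bin-wise
    over cycles (sample SD, n-1 denominator; zero for a single cycle).
    Bin 0 corresponds to the contact frame.
    """

    joint: str
    traces: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.traces.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "joint": self.joint,
                "bin": np.arange(N_BINS),
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n_cycles,
            }
        )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def joint_angle(p_prox, p_vertex, p_dist) -> float:
    """Included angle (degrees, in (0, 180]) at the vertex of two segments.

    Computed from the dot product of the vertex-to-endpoint vectors, which
    is algebraically the law of cosines on the three segment lengths.
    """
    p_prox = np.asarray(p_prox, float)
    p_vertex = np.asarray(p_vertex, float)
    p_dist = np.asarray(p_dist, float)
    u = p_prox - p_vertex
    v = p_dist - p_vertex
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("coincident points: angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def extrapolate_knee(p_hip, p_ankle, femur_len: float, shank_len: float):
    """Locate the knee from hip and ankle via circle-circle intersection.

    The knee lies at distance ``femur_len`` from the hip and ``shank_len``
    from the ankle.  Of the two intersection points the anterior one —
    greater rostral (x) coordinate relative to the hip–ankle line — is
    returned, since the cat's knee points forward.
    """
    p_hip = np.asarray(p_hip, float)
    p_ankle = np.asarray(p_ankle, float)
    d = float(np.hypot(*(p_ankle - p_hip)))
    if d == 0:
        raise DegenerateGeometryError("hip and ankle coincide")
    if not abs(femur_len - shank_len) <= d <= femur_len + shank_len:
        raise UnreachablePoseError(
            f"hip-ankle distance {d:.4g} unreachable with femur "
            f"{femur_len:.4g} + shank {shank_len:.4g}"
        )
    a = (femur_len**2 - shank_len**2 + d**2) / (2 * d)
    h2 = femur_len**2 - a**2
    h = float(np.sqrt(max(h2, 0.0)))
    axis = (p_ankle - p_hip) / d
    base = p_hip + a * axis
    perp = np.array([-axis[1], axis[0]])
    cand1, cand2 = base + h * perp, base - h * perp
    return cand1 if cand1[0] >= cand2[0] else cand2


# ---------------------------------------------------------------------------
# marker access with knee-mode handling
# ---------------------------------------------------------------------------

def _segment_lengths(track: PoseTrack, config: TrialConfig) -> tuple[float, float]:
    """Femur and shank lengths: config values, else per-trial medians of
    the tracked hip-knee and knee-ankle distances."""
    femur, shank = config.femur_length, config.shank_length
    if femur is None or shank is None:
        hip = track.coords(config.marker("hip"))
        knee = track.coords(config.marker("knee"))
        ankle = track.coords(config.marker("ankle"))
        if femur is None:
            femur = float(np.median(np.hypot(*(knee - hip).T)))
        if shank is None:
            shank = float(np.median(np.hypot(*(ankle - knee).T)))
    return femur, shank


def marker_positions(
    track: PoseTrack, frame: int, config: TrialConfig,
    roles: tuple[str, ...] = ("crest", "hip", "knee", "ankle", "mtp", "toe"),
) -> dict[str, np.ndarray]:
    """Role -> 2D point at one frame, honouring ``knee_source``.

    In ``extrapolated`` mode the knee is reconstructed from hip and ankle
    with fixed segment lengths, the reference tracker's convention.
    """
    pos = {
        role: track.xy[frame, track.marker_index(config.marker(role)), :].copy()
        for role in roles if role != "knee"
    }
    if "knee" in roles:
        if config.knee_source == "tracked":
            pos["knee"] = track.xy[
                frame, track.marker_index(config.marker("knee")), :
            ].copy()
        else:
            femur, shank = _segment_lengths(track, config)
            pos["knee"] = extrapolate_knee(pos["hip"], pos["ankle"], femur, shank)
    return pos


# ---------------------------------------------------------------------------
# scalar variables
# ---------------------------------------------------------------------------

def toe_hip_distance(track: PoseTrack, frame: int, config: TrialConfig) -> float:
    """Signed horizontal toe-to-hip distance at one frame.

    ``x(toe) - x(hip)``: positive when the toe is rostral to the hip (the
    usual configuration at contact), negative when caudal (liftoff).
    """
    _require_kinematic(track)
    toe = track.coords(config.marker("toe"))[frame]
    hip = track.coords(config.marker("hip"))[frame]
    return float(toe[0] - hip[0])


def step_length(track: PoseTrack, contact_frame: int, config: TrialConfig) -> float:
    """Horizontal distance between the two hindpaw toes at contact [cm]."""
    _require_kinematic(track)
    toe = track.coords(config.marker("toe"))[contact_frame]
    other = track.coords(config.marker("contralateral_toe"))[contact_frame]
    return float(abs(toe[0] - other[0]))


def stride_length(
    track: PoseTrack, cycle: tuple[int, int, int], config: TrialConfig,
    frame_rate: float | None = None,
) -> float:
    """Stance toe displacement plus belt travel during swing [cm].

    ``|x_toe(contact) - x_toe(liftoff)| + swing_duration * belt_speed``,
    the belt term converting m/s to cm.  On a treadmill the stance foot is
    carried caudally by the belt, so both terms are non-trivial.
    """
    _require_kinematic(track)
    speed = config.analyzed_belt_speed
    if speed is None or speed < 0:
        raise ConfigError("belt speed of the analyzed side is unknown")
    rate = frame_rate if frame_rate is not None else config.frame_rate
    contact, liftoff, next_contact = cycle
    x = track.coords(config.marker("toe"))[:, 0]
    stance_disp = abs(float(x[contact] - x[liftoff]))
    swing_s = (next_contact - liftoff) / rate
    return stance_disp + swing_s * speed * 100.0


def variables_at_events(
    track: PoseTrack, cycles: CycleSet, config: TrialConfig,
    method: str = "",
) -> pd.DataFrame:
    """One row per cycle with the 12 scalar gait variables.

    The track must be calibrated (cm) and anatomically oriented.  Angles
    are evaluated at the contact and liftoff frames of each cycle.  The
    ``method`` label tags which tracker produced the coordinates.
    """
    _require_kinematic(track)
    rows = []
    for i, (contact, liftoff, next_contact) in enumerate(cycles.cycles):
        row: dict[str, object] = {"cycle": i}
        row["step_length"] = step_length(track, contact, config)
        row["stride_length"] = stride_length(
            track, (contact, liftoff, next_contact), config, cycles.frame_rate
        )
        row["toe_hip_distance_contact"] = toe_hip_distance(track, contact, config)
        row["toe_hip_distance_liftoff"] = toe_hip_distance(track, liftoff, config)
        for event_name, frame in (("contact", contact), ("liftoff", liftoff)):
            pos = marker_positions(track, frame, config)
            for joint, (prox, vertex, dist) in JOINT_DEFINITIONS.items():
                try:
                    ang = joint_angle(pos[prox], pos[vertex], pos[dist])
                except DegenerateGeometryError as exc:
                    raise DegenerateGeometryError(
                        f"cycle {i}, {joint} at {event_name}: {exc}"
                    ) from exc
                row[f"{joint}_angle_{event_name}"] = ang
        rows.append(row)
    df = pd.DataFrame(rows, columns=["cycle", *VARIABLE_COLUMNS])
    df["method"] = method
    return df


# ---------------------------------------------------------------------------
# cycle-normalised traces
# ---------------------------------------------------------------------------

def angle_trace(track: PoseTrack, config: TrialConfig, joint: str) -> np.ndarray:
    """Frame-by-frame angle (degrees) of one joint over the whole track."""
    prox, vertex, dist = JOINT_DEFINITIONS[joint]
    out = np.empty(track.n_frames)
    for f in range(track.n_frames):
        pos = marker_positions(track, f, config)
        out[f] = joint_angle(pos[prox], pos[vertex], pos[dist])
    return out


def normalize_cycle(values: np.ndarray) -> np.ndarray:
    """Resample one cycle's frame samples onto 256 equally spaced bins.

    ``values`` holds the frame-by-frame samples of the cycle, first sample
    at contact and excluding the next cycle's contact frame (half-open
    cycle, so consecutive cycles never double-count the shared frame).
    Linear interpolation; bin 0 equals the contact value.
    """
    values = np.asarray(values, float)
    if values.ndim != 1 or len(values) < 2:
        raise TooShortCycleError(
            f"cycle has {values.size} frame(s); at least 2 required"
        )
    src = np.arange(len(values), dtype=float)
    dst = np.linspace(0.0, len(values) - 1.0, N_BINS)
    return np.interp(dst, src, values)


def cycle_traces(
    track: PoseTrack, cycles: CycleSet, config: TrialConfig, joint: str,
) -> np.ndarray:
    """(n_cycles, 256) matrix of normalised angle traces for one joint."""
    full = angle_trace(track, config, joint)
    return np.vstack([
        normalize_cycle(full[contact:next_contact])
        for contact, _liftoff, next_contact in cycles.cycles
    ])


def average_cycles(traces: np.ndarray, joint: str = "") -> CycleSeries:
    """Bin-wise mean and sample SD across cycles.

    A single cycle yields SD 0 by convention (no dispersion observed).
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    if traces.shape[0] < 1:
        raise ValueError("need at least one trace")
    mean = traces.mean(axis=0)
    if traces.shape[0] == 1:
        sd = np.zeros(traces.shape[1])
    else:
        sd = traces.std(axis=0, ddof=1)
    return CycleSeries(joint=joint, traces=traces, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def variables_to_tidy(df: pd.DataFrame) -> pd.DataFrame:
    """Long format: cycle, variable, value, method."""
    return df.melt(
        id_vars=["cycle", "method"], value_vars=list(VARIABLE_COLUMNS),
        var_name="variable", value_name="value",
    )[["cycle", "variable", "value", "method"]]


def write_variables(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def _require_kinematic(track: PoseTrack) -> None:
    if track.units != "cm" or track.orientation != "kinematic":
        raise ValueError(
            "track must be calibrated (cm) and kinematically oriented; "
            f"got units={track.units!r}, orientation={track.orientation!r}"
        )
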