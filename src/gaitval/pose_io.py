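"""Reading, calibrating and orienting 2D pose tracks.

Two dialects are supported:

* DLC-style CSV — three header rows (scorer / bodyparts / coords), one data
  row per video frame, and an ``x, y, likelihood`` triplet per body part.
  Coordinates are in pixels with the image convention (y grows downward).
* Reference-tracker CSV set — a long-format coordinate table in cm
  (``frame, marker, x_cm, y_cm``), a joint-angle table
  (``frame, joint, angle_deg``) and an event list
  (``frame, event`` with ``event`` in {contact, liftoff}).  These files
  carry no likelihood column.

Both converge on :class:`PoseTrack`, the common in-memory currency of the
pipeline.  Downstream kinematics assume a calibrated (cm), anatomically
oriented (y up, x rostral) track; :func:`calibrate` and :func:`orient`
perform those two normalisations explicitly so that the provenance of every
coordinate is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    FormatError,
    MissingMarkerError,
    ParseError,
    UnusableMarkerError,
)

logger = logging.getLogger(__name__)

#: Roles a trial configuration may map to concrete marker names.
MARKER_ROLES = (
    "crest", "hip", "knee", "ankle", "mtp", "toe",
    "contralateral_toe", "cal_a", "cal_b",
)


@dataclass(frozen=True)
class PoseTrack:
    """Per-frame, per-marker 2D positions with optional confidence.

    Attributes
    ----------
    frame_rate : float
        Acquisition rate in Hz; must be positive.
    markers : tuple of str
        Ordered marker names; every frame carries the same set.
    xy : ndarray, shape (n_frames, n_markers, 2)
        Coordinates in ``units`` (px or cm).
    likelihood : ndarray of shape (n_frames, n_markers), or None
        Tracker confidence in [0, 1]; absent for reference trackers.
    units : {"px", "cm"}
    orientation : {"image", "kinematic"}
        ``image`` means y grows downward (raw video convention);
        ``kinematic`` means y up and x rostral.
    """

    frame_rate: float
    markers: tuple[str, ...]
    xy: np.ndarray
    likelihood: np.ndarray | None = None
    units: str = "px"
    orientation: str = "image"

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        object.__setattr__(self, "xy", xy)
        if xy.ndim != 3 or xy.shape[1] != len(self.markers) or xy.shape[2] != 2:
            raise ValueError(
                f"xy must have shape (n_frames, {len(self.markers)}, 2); got {xy.shape}"
            )
        if self.likelihood is not None:
            lk = np.asarray(self.likelihood, dtype=float)
            object.__setattr__(self, "likelihood", lk)
            if lk.shape != xy.shape[:2]:
                raise ValueError("likelihood shape must match (n_frames, n_markers)")
            if np.any((lk < 0) | (lk > 1)):
                raise ValueError("likelihood values must lie in [0, 1]")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.units not in ("px", "cm"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.orientation not in ("image", "kinematic"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def marker_index(self, name: str) -> int:
        try:
            return self.markers.index(name)
        except ValueError:
            raise MissingMarkerError(
                f"marker {name!r} not in track (has {list(self.markers)})"
            ) from None

    def coords(self, name: str) -> np.ndarray:
        """(n_frames, 2) view of one marker's trajectory."""
        return self.xy[:, self.marker_index(name), :]

    def to_dataframe(self) -> pd.DataFrame:
        """Wide frame with (marker, coord) column MultiIndex."""
        cols, data = [], []
        for j, m in enumerate(self.markers):
            cols += [(m, "x"), (m, "y")]
            data += [self.xy[:, j, 0], self.xy[:, j, 1]]
            if self.likelihood is not None:
                cols.append((m, "likelihood"))
                data.append(self.likelihood[:, j])
        return pd.DataFrame(
            np.column_stack(data), columns=pd.MultiIndex.from_tuples(cols)
        )


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel-to-cm conversion derived from two static markers.

    ``cm_per_px`` is the known physical separation divided by the mean
    pixel distance between the two calibration markers over all frames;
    the mean suppresses frame-to-frame tracking jitter on markers that are
    physically static.
    """

    cm_per_px: float
    marker_a: str
    marker_b: str
    known_separation: float

    def __post_init__(self) -> None:
        if not self.cm_per_px > 0:
            raise ValueError("cm_per_px must be positive")

    @classmethod
    def from_track(
        cls, track: PoseTrack, marker_a: str, marker_b: str,
        known_separation: float = 10.0,
    ) -> "CalibrationScale":
        pa = track.coords(marker_a)
        pb = track.coords(marker_b)
        mean_px = float(np.mean(np.hypot(*(pa - pb).T)))
        if mean_px <= 0:
            raise ValueError("calibration markers coincide; scale undefined")
        return cls(known_separation / mean_px, marker_a, marker_b, known_separation)


@dataclass
class TrialConfig:
    """Everything about a trial the pose files themselves do not carry.

    Belt speeds are in m/s, one per belt; a tied-belt trial has equal
    speeds.  ``marker_map`` translates anatomical roles (crest, hip, knee,
    ankle, mtp, toe, contralateral_toe, cal_a, cal_b) into the marker names
    actually present in the files.  ``rostral_direction`` states which image
    x direction the animal faces, so the track can be reflected into the
    anatomical frame.  ``knee_source`` selects between the tracked knee
    marker and extrapolation from hip + ankle with fixed segment lengths
    (the reference tracker's convention).
    """

    belt_speed_left: float = 0.4
    belt_speed_right: float = 0.4
    frame_rate: float = 60.0
    analyzed_side: str = "right"
    rostral_direction: str = "+x"
    marker_map: dict[str, str] = field(default_factory=dict)
    likelihood_threshold: float = 0.9
    events_one_based: bool = False
    knee_source: str = "tracked"
    femur_length: float | None = None
    shank_length: float | None = None
    calibration_separation: float = 10.0
    # event-detector tuning
    contact_baseline_tolerance: float = 0.1   # fraction of vertical toe excursion
    min_cycle_duration: float = 0.2           # s

    def __post_init__(self) -> None:
        if self.belt_speed_left < 0 or self.belt_speed_right < 0:
            raise ConfigError("belt speeds must be >= 0")
        if self.analyzed_side not in ("left", "right"):
            raise ConfigError("analyzed_side must be 'left' or 'right'")
        if self.rostral_direction not in ("+x", "-x"):
            raise ConfigError("rostral_direction must be '+x' or '-x'")
        if not 0 <= self.likelihood_threshold <= 1:
            raise ConfigError("likelihood_threshold must lie in [0, 1]")
        if self.knee_source not in ("tracked", "extrapolated"):
            raise ConfigError("knee_source must be 'tracked' or 'extrapolated'")

    @property
    def tied_belt(self) -> bool:
        return self.belt_speed_left == self.belt_speed_right

    @property
    def analyzed_belt_speed(self) -> float:
        return (self.belt_speed_right if self.analyzed_side == "right"
                else self.belt_speed_left)

    def marker(self, role: str) -> str:
        if role not in MARKER_ROLES:
            raise ConfigError(f"unknown marker role {role!r}")
        try:
            return self.marker_map[role]
        except KeyError:
            raise ConfigError(f"marker role {role!r} is not mapped") from None

    # -- flat key:value (YAML) serialisation ------------------------------

    def to_yaml(self, path: str | Path) -> None:
        flat: dict[str, object] = {}
        for k, v in self.__dict__.items():
            if k == "marker_map":
                for role, name in v.items():
                    flat[f"marker.{role}"] = name
            else:
                flat[k] = v
        Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} is not a flat key:value map")
        marker_map: dict[str, str] = {}
        kwargs: dict[str, object] = {}
        for k, v in raw.items():
            if k.startswith("marker."):
                marker_map[k.split(".", 1)[1]] = str(v)
            else:
                kwargs[k] = v
        known = set(cls.__dataclass_fields__) - {"marker_map"}
        unknown = set(kwargs) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(marker_map=marker_map, **kwargs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_dlc_table(path: str | Path, frame_rate: float = 60.0) -> PoseTrack:
    """Read a DLC-style CSV into a pixel-space :class:`PoseTrack`.

    The file must carry the standard three header rows (scorer, bodyparts,
    coords) and an x/y/likelihood triplet for every body part.  Frame
    indices are taken from the first column and must be 0-based and
    contiguous.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a three-header-row DLC table ({exc})") from exc
    if df.columns.nlevels != 3:
        raise FormatError(f"{path}: expected 3 header rows, got {df.columns.nlevels}")

    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    for bp in bodyparts:
        sub = df.xs(bp, axis=1, level=1)
        coords = list(sub.columns.get_level_values(-1))
        if sorted(coords) != ["likelihood", "x", "y"]:
            raise FormatError(
                f"{path}: body part {bp!r} has coords {coords}, "
                "expected x, y, likelihood"
            )

    n = len(df)
    idx = df.index.to_numpy()
    if not np.array_equal(idx, np.arange(n)):
        raise FormatError(f"{path}: frame indices must be 0-based and contiguous")

    xy = np.empty((n, len(bodyparts), 2))
    lk = np.empty((n, len(bodyparts)))
    for j, bp in enumerate(bodyparts):
        sub = df.xs(bp, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        for coord, target in (("x", 0), ("y", 1)):
            col = pd.to_numeric(sub[coord], errors="coerce").to_numpy()
            bad = np.flatnonzero(np.isnan(col) & sub[coord].notna() | sub[coord].isna())
            if bad.size:
                raise ParseError(
                    f"{path}: non-numeric {coord} for marker {bp!r} "
                    f"at frame {int(bad[0])}"
                )
            xy[:, j, target] = col
        likecol = pd.to_numeric(sub["likelihood"], errors="coerce").to_numpy()
        if np.any(np.isnan(likecol)):
            bad = int(np.flatnonzero(np.isnan(likecol))[0])
            raise ParseError(
                f"{path}: non-numeric likelihood for marker {bp!r} at frame {bad}"
            )
        lk[:, j] = likecol
    if np.any((lk < 0) | (lk > 1)):
        raise FormatError(f"{path}: likelihood values outside [0, 1]")
    return PoseTrack(frame_rate, tuple(bodyparts), xy, lk, units="px",
                     orientation="image")


def read_reference_export(
    coords_path: str | Path,
    angles_path: str | Path | None,
    events_path: str | Path,
    frame_rate: float = 60.0,
    one_based_events: bool = False,
):
    """Read a reference-tracker export (coords in cm, angles, event list).

    Returns ``(PoseTrack, angles DataFrame or None, GaitEvents)``.  The
    coordinate dialect is already metric and anatomically oriented (y up),
    so the returned track is flagged cm/kinematic and carries no
    likelihood.  The event list must alternate contact/liftoff; a violation
    raises :class:`~gaitval.errors.EventOrderError`.
    """
    from .gait_events import read_events_csv  # cycle-free import

    coords = pd.read_csv(coords_path)
    required = {"frame", "marker", "x_cm", "y_cm"}
    if not required.issubset(coords.columns):
        raise FormatError(
            f"{coords_path}: needs columns {sorted(required)}, "
            f"has {list(coords.columns)}"
        )
    markers = tuple(dict.fromkeys(coords["marker"]))
    frames = np.sort(coords["frame"].unique())
    n = len(frames)
    if not np.array_equal(frames, np.arange(n)):
        raise FormatError(f"{coords_path}: frame indices must be 0-based contiguous")
    wide = coords.pivot(index="frame", columns="marker", values=["x_cm", "y_cm"])
    if wide.isna().any().any():
        raise FormatError(f"{coords_path}: every frame must list every marker")
    xy = np.empty((n, len(markers), 2))
    for j, m in enumerate(markers):
        xy[:, j, 0] = wide[("x_cm", m)].to_numpy(float)
        xy[:, j, 1] = wide[("y_cm", m)].to_numpy(float)
    track = PoseTrack(frame_rate, markers, xy, None, units="cm",
                      orientation="kinematic")

    angles = None
    if angles_path is not None:
        angles = pd.read_csv(angles_path)
        if not {"frame", "joint", "angle_deg"}.issubset(angles.columns):
            raise FormatError(
                f"{angles_path}: needs columns frame, joint, angle_deg"
            )

    events = read_events_csv(events_path, one_based=one_based_events)
    return track, angles, events


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def calibrate(track: PoseTrack, scale: CalibrationScale) -> PoseTrack:
    """Convert a pixel-space track to cm by uniform scaling.

    Every coordinate is multiplied by ``scale.cm_per_px``; likelihoods are
    untouched.  Distances therefore obey the exact scaling law
    ``d_cm = d_px * cm_per_px``.
    """
    if track.units != "px":
        raise ValueError("calibrate expects a pixel-space track")
    return replace(track, xy=track.xy * scale.cm_per_px, units="cm")


def orient(track: PoseTrack, config: TrialConfig) -> PoseTrack:
    """Map image coordinates (y down) into the anatomical frame (y up,
    x rostral).

    y is negated; x is additionally negated when the animal faces the -x
    image direction.  Both operations are isometries, so all pairwise
    distances and three-point angles are preserved; applying the transform
    twice returns the original coordinates.
    """
    if track.units != "cm":
        raise ValueError("orient expects a calibrated (cm) track")
    xy = track.xy.copy()
    xy[:, :, 1] = -xy[:, :, 1]
    if config.rostral_direction == "-x":
        xy[:, :, 0] = -xy[:, :, 0]
    new_orientation = "kinematic" if track.orientation == "image" else "image"
    return replace(track, xy=xy, orientation=new_orientation)


def fill_low_confidence(
    track: PoseTrack, threshold: float | None = None,
    config: TrialConfig | None = None,
) -> tuple[PoseTrack, dict[str, int]]:
    """Replace sub-threshold points by linear interpolation in time.

    Frames whose likelihood falls below ``threshold`` are interpolated
    between the nearest flanking confident frames; leading/trailing gaps
    are held at the nearest confident value.  Returns the repaired track
    and a per-marker count of replaced frames.  A marker with no confident
    frame at all cannot be repaired and raises
    :class:`~gaitval.errors.UnusableMarkerError`.
    """
    if track.likelihood is None:
        raise ValueError("track carries no likelihood; nothing to fill")
    if threshold is None:
        threshold = config.likelihood_threshold if config else 0.9
    xy = track.xy.copy()
    counts: dict[str, int] = {}
    t = np.arange(track.n_frames, dtype=float)
    for j, m in enumerate(track.markers):
        good = track.likelihood[:, j] >= threshold
        n_bad = int((~good).sum())
        counts[m] = n_bad
        if n_bad == 0:
            continue
        if not good.any():
            raise UnusableMarkerError(
                f"marker {m!r} has no frames with likelihood >= {threshold}"
            )
        for d in range(2):
            xy[~good, j, d] = np.interp(t[~good], t[good], xy[good, j, d])
    filled = sum(counts.values())
    if filled:
        logger.info("fill_low_confidence: replaced %d points (%s)", filled, counts)
    return replace(track, xy=xy), counts
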