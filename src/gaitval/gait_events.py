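"""Contact/liftoff events and the cycle structure they induce.

A gait cycle of the analyzed hindlimb runs from one paw contact to the
next.  Contact opens the stance phase (paw on the belt); liftoff — the
frame of the paw's most caudal position — opens the swing phase.  Events
are primarily *imported* from a manually annotated event list; the
automatic detector here is a convenience for synthetic or exploratory data
and exposes its thresholds in :class:`~gaitval.pose_io.TrialConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    EventOrderError,
    FormatError,
    InsufficientEventsError,
    NoGaitDetectedError,
)
from .pose_io import PoseTrack, TrialConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitEvents:
    """Ordered contact and liftoff frame indices for one limb.

    A well-formed sequence alternates ``contact(i) < liftoff(i) <
    contact(i+1)``; construction does not enforce this so that
    :func:`validate_events` can report on raw imports — readers and
    :func:`build_cycles` are the enforcement points.
    """

    contacts: np.ndarray
    liftoffs: np.ndarray
    source: str = "manual"

    def __post_init__(self) -> None:
        object.__setattr__(self, "contacts", np.asarray(self.contacts, dtype=int))
        object.__setattr__(self, "liftoffs", np.asarray(self.liftoffs, dtype=int))

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def n_liftoffs(self) -> int:
        return len(self.liftoffs)


@dataclass(frozen=True)
class CycleSet:
    """Per-cycle (contact, liftoff, next contact) triples and durations.

    Durations derive exactly from frame arithmetic:
    stance = (liftoff - contact) / rate, swing = (next contact - liftoff)
    / rate, and cycle = stance + swing, so the total of all cycle
    durations equals (last contact - first contact) / rate.
    """

    cycles: tuple[tuple[int, int, int], ...]
    frame_rate: float
    stance_s: np.ndarray = field(init=False)
    swing_s: np.ndarray = field(init=False)
    cycle_s: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.cycles, dtype=int).reshape(-1, 3)
        stance = (arr[:, 1] - arr[:, 0]) / self.frame_rate
        swing = (arr[:, 2] - arr[:, 1]) / self.frame_rate
        object.__setattr__(self, "stance_s", stance)
        object.__setattr__(self, "swing_s", swing)
        object.__setattr__(self, "cycle_s", stance + swing)
        if np.any(stance <= 0) or np.any(swing <= 0):
            raise ValueError("all stance and swing durations must be positive")

    def __len__(self) -> int:
        return len(self.cycles)


def validate_events(events: GaitEvents) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    Checks strict monotonicity within each list and the contact/liftoff
    alternation contact(i) < liftoff(i) < contact(i+1).  Purely diagnostic;
    never raises.
    """
    v: list[str] = []
    c, l = events.contacts, events.liftoffs
    for name, arr in (("contacts", c), ("liftoffs", l)):
        for i in np.flatnonzero(np.diff(arr) <= 0):
            v.append(
                f"{name} not strictly increasing at frames "
                f"{int(arr[i])}, {int(arr[i + 1])}"
            )
    merged = sorted(
        [(int(f), "contact") for f in c] + [(int(f), "liftoff") for f in l]
    )
    if merged and merged[0][1] == "liftoff":
        v.append(f"liftoff at frame {merged[0][0]} precedes any contact")
    for (f1, k1), (f2, k2) in zip(merged, merged[1:]):
        if k1 == k2:
            v.append(f"two {k1}s in a row at frames {f1}, {f2}")
        elif f1 == f2:
            v.append(f"contact and liftoff share frame {f1}")
    return v


def read_events_csv(
    path, one_based: bool = False, source: str = "imported",
) -> GaitEvents:
    """Read an event list CSV (columns ``frame``, ``event``).

    ``event`` must be ``contact`` or ``liftoff``.  With ``one_based`` the
    frame indices are converted to the package's 0-based convention.  The
    sequence must alternate; violations raise
    :class:`~gaitval.errors.EventOrderError`.
    """
    ev = pd.read_csv(path)
    if not {"frame", "event"}.issubset(ev.columns):
        raise FormatError(f"{path}: needs columns frame, event")
    bad = set(ev["event"]) - {"contact", "liftoff"}
    if bad:
        raise FormatError(f"{path}: unknown event labels {sorted(bad)}")
    offset = 1 if one_based else 0
    events = GaitEvents(
        contacts=ev.loc[ev["event"] == "contact", "frame"].to_numpy(int) - offset,
        liftoffs=ev.loc[ev["event"] == "liftoff", "frame"].to_numpy(int) - offset,
        source=source,
    )
    violations = validate_events(events)
    if violations:
        raise EventOrderError(
            f"{path}: event sequence invalid: " + "; ".join(violations)
        )
    return events


def build_cycles(events: GaitEvents, frame_rate: float) -> CycleSet:
    """Assemble cycles from consecutive contact pairs with the liftoff
    between them.

    Trailing events that cannot complete a cycle (a liftoff after the last
    contact, or a final contact with no successor) are dropped with a
    logged count.  Fewer than two contacts cannot define any cycle.
    """
    bad = validate_events(events)
    if bad:
        raise EventOrderError("; ".join(bad))
    c, l = events.contacts, events.liftoffs
    if len(c) < 2:
        raise InsufficientEventsError(
            f"need at least 2 contacts to build a cycle, got {len(c)}"
        )
    n_cycles = len(c) - 1
    dropped = (len(c) + len(l)) - (2 * n_cycles + 1)
    if dropped > 0:
        logger.info("build_cycles: dropped %d trailing unmatched event(s)", dropped)
    cycles = tuple(
        (int(c[i]), int(l[i]), int(c[i + 1])) for i in range(n_cycles)
    )
    return CycleSet(cycles=cycles, frame_rate=frame_rate)


def detect_events(track: PoseTrack, config: TrialConfig) -> GaitEvents:
    """Detect contacts and liftoffs from the toe trajectory.

    Liftoff is operationalised as the frame of minimum rostral (x) toe
    position within each cycle — the most caudal excursion — taking the
    *earliest* frame on ties.  Contact is the first frame, after the swing
    apex, where the toe's height drops back within a tolerance band above
    the stance baseline; the band is ``contact_baseline_tolerance`` times
    the vertical toe excursion.  Candidate liftoffs closer together than
    ``min_cycle_duration`` are suppressed.

    Requires a calibrated, anatomically oriented track (y up, x rostral).
    """
    if track.orientation != "kinematic":
        raise ValueError("detect_events requires kinematic orientation")
    toe = track.coords(config.marker("toe"))
    x, y = toe[:, 0], toe[:, 1]
    x_range = float(np.ptp(x))
    if x_range < 0.5:  # cm; no rostro-caudal excursion worth calling gait
        raise NoGaitDetectedError(
            f"toe x range {x_range:.3g} cm shows no periodic motion"
        )
    min_dist = max(1, int(round(config.min_cycle_duration * track.frame_rate)))
    # find_peaks on -x marks caudal extrema; left_edges honours the
    # earliest-frame tie rule on plateaus
    peaks, props = find_peaks(-x, distance=min_dist,
                              prominence=0.05 * x_range, plateau_size=1)
    liftoffs = props["left_edges"]
    if len(liftoffs) == 0:
        raise NoGaitDetectedError("no caudal toe extrema found (no cycling)")

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    threshold = y_lo + config.contact_baseline_tolerance * (y_hi - y_lo)
    contacts: list[int] = []
    bounds = np.concatenate([liftoffs, [track.n_frames]])
    for lo, nxt in zip(bounds[:-1], bounds[1:]):
        seg = y[lo:nxt]
        if len(seg) < 2:
            continue
        apex = lo + int(np.argmax(seg))
        below = np.flatnonzero(y[apex:nxt] < threshold)
        if below.size:
            contacts.append(apex + int(below[0]))
    # leading contact before the first liftoff, if the trace starts mid-stance
    first_lo = int(liftoffs[0])
    lead = np.flatnonzero(y[:first_lo] < threshold)
    if lead.size and (not contacts or lead[0] < contacts[0]):
        contacts.insert(0, int(lead[0]))

    contacts_a = np.asarray(sorted(set(contacts)), dtype=int)
    events = _trim_to_alternation(contacts_a, np.asarray(liftoffs, dtype=int))
    if events.n_contacts < 2:
        raise NoGaitDetectedError(
            f"only {events.n_contacts} contact(s) detected; no cycle"
        )
    return events


def _trim_to_alternation(contacts: np.ndarray, liftoffs: np.ndarray) -> GaitEvents:
    """Greedily keep the longest alternating contact/liftoff subsequence."""
    kept_c: list[int] = []
    kept_l: list[int] = []
    ci = li = 0
    while ci < len(contacts):
        c = contacts[ci]
        if kept_l and c <= kept_l[-1]:
            ci += 1
            continue
        kept_c.append(int(c))
        ci += 1
        while li < len(liftoffs) and liftoffs[li] <= c:
            li += 1
        nxt_c = contacts[ci] if ci < len(contacts) else None
        if li < len(liftoffs) and (nxt_c is None or liftoffs[li] < nxt_c):
            kept_l.append(int(liftoffs[li]))
            li += 1
    return GaitEvents(np.array(kept_c), np.array(kept_l), source="detected")
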