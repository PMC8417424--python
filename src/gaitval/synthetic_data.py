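"""Ground-truthed synthetic inputs for the gait pipeline.

Two generators live here:

* :class:`MeasurementModel` / :func:`simulate_pairs` — the additive-error
  model behind paired method-comparison statistics: both methods observe
  the same latent per-cycle truth plus method-specific bias and noise.
  Its closed forms (e.g. the analytic CCC) make agreement estimators
  testable against known expectations.

* :class:`GaitModel` / :func:`simulate_gait` — a planar hindlimb
  trajectory simulator.  A forward chain crest -> hip -> knee -> ankle ->
  MTP -> toe is driven by periodic templates at 60 Hz on a treadmill
  whose belt carries the stance foot caudally at belt speed, so the
  stride-length formula's two terms (stance displacement, belt travel
  during swing) are independently non-trivial.  Cycle period, swing
  height and joint-template amplitudes vary cycle-to-cycle (seeded), so
  per-cycle variables have genuine across-cycle variance.  Contacts and
  liftoffs are known exactly by construction: stance toe x decreases
  monotonically to its caudal extreme at liftoff and recovers
  monotonically during swing.

:func:`render_trackers` turns one truth trajectory into the two tracker
renderings the analysis compares: a pixel-space, image-oriented table
with confidence values and occasional dropouts (markerless-pose style),
and a metric table with static per-marker placement offsets plus jitter
(reflective-marker style).  :func:`write_fixture` serialises everything
in exactly the dialects ``pose_io`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics
from .errors import InvalidTemplateError, UnreachablePoseError
from .gait_events import CycleSet, GaitEvents
from .pose_io import PoseTrack, TrialConfig

TRUTH_MARKERS = ("crest", "hip", "knee", "ankle", "mtp", "toe", "toe_left")


# ---------------------------------------------------------------------------
# additive-error measurement model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementModel:
    """Paired observations of a latent truth with per-method bias/noise.

    ``x = t + bias_a + eps_a`` and ``y = t + bias_b + eps_b`` with
    ``t ~ N(true_mean, true_sd^2)``.  The population concordance is

    ``CCC = 2 sigma_t^2 / (2 sigma_t^2 + sigma_a^2 + sigma_b^2 +
    (bias_a - bias_b)^2)``,

    which equals the population ICC when the biases and noises are
    symmetric.
    """

    n: int = 2500
    true_mean: float = 0.0
    true_sd: float = 5.0
    bias_a: float = 0.0
    bias_b: float = 0.0
    noise_a: float = 1.0
    noise_b: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if min(self.true_sd, self.noise_a, self.noise_b) < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def analytic_ccc(self) -> float:
        st2 = self.true_sd**2
        return 2 * st2 / (
            2 * st2 + self.noise_a**2 + self.noise_b**2
            + (self.bias_a - self.bias_b) ** 2
        )


def simulate_pairs(model: MeasurementModel):
    """Draw a :class:`~gaitval.agreement.PairedSeries` from the model."""
    from .agreement import PairedSeries

    rng = np.random.default_rng(model.seed)
    t = rng.normal(model.true_mean, model.true_sd, model.n)
    x = t + model.bias_a + rng.normal(0.0, model.noise_a, model.n)
    y = t + model.bias_b + rng.normal(0.0, model.noise_b, model.n)
    return PairedSeries("simulated", x, y)


# ---------------------------------------------------------------------------
# planar hindlimb gait model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitModel:
    """Parameters of the treadmill trajectory simulator.

    Defaults emulate an adult cat on a tied-belt treadmill at 0.4 m/s
    recorded at 60 Hz: about 15 cycles per trial, hindlimb segment lengths
    of a 3.5-4.5 kg cat, and a 10 cm calibration-marker pair in the image
    plane.  Stance timing follows from the belt: the stance foot is
    carried through a roughly speed-invariant rostro-caudal sweep
    (``stance_sweep_cm``) at belt speed, while swing duration stays near
    0.3 s — so at 0.4 m/s a cycle lasts ~0.9 s with a ~65% stance
    fraction, and faster belts shorten stance, as in real cats.
    Cycle-to-cycle variability (timing, swing height, template
    amplitudes) is the animal's own, shared by both tracker renderings;
    tracker noise and placement offsets are per-rendering.
    """

    frame_rate: float = 60.0
    belt_speed_left: float = 0.4          # m/s
    belt_speed_right: float = 0.4         # m/s
    n_cycles: int = 15
    stance_sweep_cm: float = 23.5         # rostro-caudal toe travel in stance
    swing_duration_s: float = 0.30
    cycle_variability: float = 0.06       # fractional SD of stance/swing timing
    swing_height_cm: float = 3.0
    swing_height_variability: float = 0.10
    hip_height_cm: float = 25.3
    hip_osc_cm: float = 0.5
    hip_x_fraction: float = 0.45          # hip position along the stance sweep
    femur_cm: float = 13.2
    shank_cm: float = 14.8
    tarsus_cm: float = 6.5
    foot_cm: float = 3.0
    crest_offset_cm: tuple[float, float] = (3.0, 3.0)
    # foot pitch: angle of the toe->MTP segment above the caudal horizontal;
    # ~0.2 rad at contact (paw flat) rising to ~1.1 rad at liftoff (heel up)
    foot_pitch_rad: float = 0.61
    foot_pitch_amp: float = 0.51
    foot_pitch_phase: float = -2.2
    # the MTP->ankle segment leads the foot by a small gap, keeping the MTP
    # joint near 150 deg with a few degrees of within-cycle motion
    mtp_gap_rad: float = 0.50
    mtp_gap_amp: float = 0.06
    mtp_gap_phase: float = 1.0
    template_variability: float = 0.08    # per-cycle amplitude jitter
    template_offset_sd_rad: float = 0.04  # per-cycle posture scatter
    toe_x_contact_cm: float = 52.0        # rostral-most toe position
    contact_position_sd_cm: float = 1.0   # per-cycle scatter of the landing spot
    # tracker rendering
    cm_per_px: float = 0.1
    image_height_px: float = 480.0
    calibration_xy_cm: tuple[float, float] = (5.0, 2.0)
    calibration_separation_cm: float = 10.0
    noise_dlc_px: float = 0.5
    noise_ref_cm: float = 0.05
    ref_offset_cm: float = 0.10           # static per-marker placement offset SD
    dropout_prob: float = 0.02
    dropout_noise_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 2:
            raise ValueError("need at least 2 cycles")
        if self.stance_sweep_cm <= 0 or self.swing_duration_s <= 0:
            raise ValueError("stance sweep and swing duration must be positive")
        if self.analyzed_belt_speed <= 0:
            raise ValueError("analyzed belt speed must be positive")

    @property
    def analyzed_belt_speed(self) -> float:
        return self.belt_speed_right

    def trial_config(self) -> TrialConfig:
        """A TrialConfig matching this model's rendered fixtures."""
        return TrialConfig(
            belt_speed_left=self.belt_speed_left,
            belt_speed_right=self.belt_speed_right,
            frame_rate=self.frame_rate,
            analyzed_side="right",
            rostral_direction="+x",
            marker_map={
                "crest": "crest", "hip": "hip", "knee": "knee",
                "ankle": "ankle", "mtp": "mtp", "toe": "toe",
                "contralateral_toe": "toe_left",
                "cal_a": "cal_a", "cal_b": "cal_b",
            },
            calibration_separation=self.calibration_separation_cm,
        )


@dataclass(frozen=True)
class _CycleParams:
    """Frozen per-cycle randomness (the animal's own variability)."""

    period: int
    stance: int
    swing_height: float
    foot_amp: float
    gap_amp: float
    x_contact: float
    foot_offset: float = 0.0      # per-cycle shift of the foot-pitch template
    gap_offset: float = 0.0       # per-cycle shift of the MTP gap
    x_land: float = float("nan")  # next cycle's landing spot (swing target)


def _draw_cycle_params(model: GaitModel, rng: np.random.Generator) -> list[_CycleParams]:
    """Per-cycle timing: stance lasts as long as the belt needs to carry
    the toe through the stance sweep, swing duration is roughly
    speed-invariant; both are jittered cycle to cycle."""
    v_cm_s = model.analyzed_belt_speed * 100.0

    def draw(sd: float) -> float:
        # spatial scatter truncated at 2 SD: the limb cannot overstride
        # beyond its reach, so Gaussian tails are unphysiological
        return float(np.clip(sd * rng.standard_normal(), -2 * sd, 2 * sd))

    params = []
    for _ in range(model.n_cycles):
        sweep = model.stance_sweep_cm * (1 + draw(model.cycle_variability))
        stance = int(round(model.frame_rate * sweep / v_cm_s))
        stance = max(stance, 2)
        swing = int(round(
            model.frame_rate * model.swing_duration_s
            * (1 + model.cycle_variability * rng.standard_normal())
        ))
        swing = max(swing, 3)
        period = stance + swing
        params.append(_CycleParams(
            period=period,
            stance=stance,
            swing_height=model.swing_height_cm
            * max(1 + model.swing_height_variability * rng.standard_normal(), 0.3),
            foot_amp=model.foot_pitch_amp
            * max(1 + model.template_variability * rng.standard_normal(), 0.3),
            gap_amp=model.mtp_gap_amp
            * max(1 + model.template_variability * rng.standard_normal(), 0.3),
            x_contact=model.toe_x_contact_cm + draw(model.contact_position_sd_cm),
            foot_offset=draw(model.template_offset_sd_rad),
            gap_offset=draw(model.template_offset_sd_rad),
        ))
    # each swing aims at the following cycle's landing spot so the toe
    # trajectory is continuous across the shared contact frame
    landings = [p.x_contact for p in params[1:]] + [model.toe_x_contact_cm]
    return [replace(p, x_land=x) for p, x in zip(params, landings)]


def _smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    return u * u * (3.0 - 2.0 * u)


def _toe_xy(model: GaitModel, p: _CycleParams, s: float) -> tuple[float, float]:
    """Analyzed-limb toe position at local frame ``s`` within one cycle."""
    v = model.analyzed_belt_speed * 100.0 / model.frame_rate  # cm per frame
    x_contact = p.x_contact
    if s <= p.stance:
        return x_contact - v * s, 0.0
    x_lift = x_contact - v * p.stance
    u = (s - p.stance) / (p.period - p.stance)
    target = p.x_land if np.isfinite(p.x_land) else x_contact
    x = x_lift + (target - x_lift) * _smoothstep(u)
    y = p.swing_height * np.sin(np.pi * u)
    return float(x), float(y)


def _hip_x(model: GaitModel) -> float:
    return model.toe_x_contact_cm - model.hip_x_fraction * model.stance_sweep_cm


def _chain_positions(model: GaitModel, p: _CycleParams, s: float) -> dict[str, np.ndarray]:
    """All marker positions (cm, y up) at local frame ``s`` of one cycle."""
    phi = 2 * np.pi * s / p.period
    toe = np.array(_toe_xy(model, p, s))
    toe_left = np.array(_toe_xy(model, p, (s + p.period / 2.0) % p.period))
    hip = np.array([
        _hip_x(model),
        model.hip_height_cm + model.hip_osc_cm * np.sin(phi + np.pi),
    ])
    crest = hip + np.asarray(model.crest_offset_cm)
    psi = (model.foot_pitch_rad + p.foot_offset
           + p.foot_amp * np.sin(phi + model.foot_pitch_phase))
    mtp = toe + model.foot_cm * np.array([-np.cos(psi), np.sin(psi)])
    chi = (psi + model.mtp_gap_rad + p.gap_offset
           + p.gap_amp * np.sin(phi + model.mtp_gap_phase))
    ankle = mtp + model.tarsus_cm * np.array([-np.cos(chi), np.sin(chi)])
    try:
        knee = kinematics.extrapolate_knee(hip, ankle, model.femur_cm, model.shank_cm)
    except UnreachablePoseError as exc:
        raise InvalidTemplateError(
            f"joint templates put the ankle out of reach of the thigh chain: {exc}"
        ) from exc
    return {
        "crest": crest, "hip": hip, "knee": knee, "ankle": ankle,
        "mtp": mtp, "toe": toe, "toe_left": toe_left,
    }


def simulate_gait(model: GaitModel):
    """Simulate one trial.

    Returns ``(truth_track, events, truth_variables)``: the noiseless
    marker trajectory in cm (kinematic orientation), the exact contact and
    liftoff frames, and the per-cycle variable table evaluated directly
    from the generator's closed-form trajectory at the event frames.
    """
    rng = np.random.default_rng(model.seed)
    cycle_params = _draw_cycle_params(model, rng)

    contacts = np.concatenate([[0], np.cumsum([p.period for p in cycle_params])])
    liftoffs = np.array([c + p.stance for c, p in zip(contacts[:-1], cycle_params)])
    n_frames = int(contacts[-1]) + 1

    xy = np.empty((n_frames, len(TRUTH_MARKERS), 2))
    for k, p in enumerate(cycle_params):
        start, stop = int(contacts[k]), int(contacts[k + 1])
        stop_excl = stop if k < model.n_cycles - 1 else stop + 1
        for n in range(start, stop_excl):
            pos = _chain_positions(model, p, n - start)
            for j, m in enumerate(TRUTH_MARKERS):
                xy[n, j] = pos[m]
    track = PoseTrack(model.frame_rate, TRUTH_MARKERS, xy, None,
                      units="cm", orientation="kinematic")
    events = GaitEvents(contacts=contacts, liftoffs=liftoffs, source="manual")

    truth = _truth_variables(model, cycle_params, contacts)
    return track, events, truth


def _truth_variables(model: GaitModel, cycle_params, contacts) -> pd.DataFrame:
    """Per-cycle variable table straight from the closed-form trajectory."""
    hip_x = _hip_x(model)
    rows = []
    for k, p in enumerate(cycle_params):
        at_contact = _chain_positions(model, p, 0)
        at_liftoff = _chain_positions(model, p, p.stance)
        swing_s = (p.period - p.stance) / model.frame_rate
        row: dict[str, object] = {
            "cycle": k,
            "step_length": abs(at_contact["toe"][0] - at_contact["toe_left"][0]),
            "stride_length": abs(at_contact["toe"][0] - at_liftoff["toe"][0])
            + swing_s * model.analyzed_belt_speed * 100.0,
            "toe_hip_distance_contact": at_contact["toe"][0] - hip_x,
            "toe_hip_distance_liftoff": at_liftoff["toe"][0] - hip_x,
        }
        for event, pos in (("contact", at_contact), ("liftoff", at_liftoff)):
            for joint, (a, b, c) in kinematics.JOINT_DEFINITIONS.items():
                row[f"{joint}_angle_{event}"] = kinematics.joint_angle(
                    pos[a], pos[b], pos[c]
                )
        rows.append(row)
    df = pd.DataFrame(rows, columns=["cycle", *kinematics.VARIABLE_COLUMNS])
    df["method"] = "truth"
    return df


# ---------------------------------------------------------------------------
# tracker renderings
# ---------------------------------------------------------------------------

def render_trackers(truth: PoseTrack, model: GaitModel):
    """Render the truth trajectory as the two tracker outputs.

    Returns ``(dlc_track, ref_track)``:

    * ``dlc_track`` — pixel units, image orientation (y down), Gaussian
      jitter of ``noise_dlc_px``, simulated likelihood near 1 with
      occasional dropouts (low likelihood + a large position error), and
      two static calibration markers 10 cm apart appended;
    * ``ref_track`` — cm, kinematic orientation, per-frame jitter of
      ``noise_ref_cm`` plus a static per-marker placement offset
      (marker-placement variability of a reflective-marker system).
    """
    if truth.units != "cm":
        raise ValueError("truth track must be in cm")
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 1]))
    n, m = truth.n_frames, len(truth.markers)
    s = model.cm_per_px

    # --- markerless-pose rendering (px, image orientation) ---------------
    px = np.empty((n, m + 2, 2))
    px[:, :m, 0] = truth.xy[:, :, 0] / s
    px[:, :m, 1] = model.image_height_px - truth.xy[:, :, 1] / s
    cal_x, cal_y = model.calibration_xy_cm
    px[:, m, 0] = cal_x / s
    px[:, m, 1] = model.image_height_px - cal_y / s
    px[:, m + 1, 0] = (cal_x + model.calibration_separation_cm) / s
    px[:, m + 1, 1] = model.image_height_px - cal_y / s
    if model.noise_dlc_px > 0:
        px += rng.normal(0.0, model.noise_dlc_px, px.shape)
    if model.noise_dlc_px == 0 and model.dropout_prob == 0:
        # a noiseless tracker has nothing to be uncertain about
        likelihood = np.ones((n, m + 2))
    else:
        likelihood = rng.beta(40.0, 1.0, (n, m + 2))
        if model.dropout_prob > 0:
            drop = rng.random((n, m + 2)) < model.dropout_prob
            likelihood[drop] = rng.uniform(0.0, 0.5, int(drop.sum()))
            px[drop] += rng.normal(0.0, model.dropout_noise_px,
                                   (int(drop.sum()), 2))
    dlc = PoseTrack(
        truth.frame_rate, truth.markers + ("cal_a", "cal_b"), px,
        np.clip(likelihood, 0.0, 1.0), units="px", orientation="image",
    )

    # --- reflective-marker rendering (cm, kinematic) ----------------------
    ref_xy = truth.xy.copy()
    if model.ref_offset_cm > 0:
        ref_xy += rng.normal(0.0, model.ref_offset_cm, (1, m, 2))
    if model.noise_ref_cm > 0:
        ref_xy += rng.normal(0.0, model.noise_ref_cm, ref_xy.shape)
    ref = replace(truth, xy=ref_xy)
    return dlc, ref


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_dlc(track: PoseTrack, path: str | Path, scorer: str = "synthetic") -> None:
    """Write a pixel-space track in the three-header-row CSV dialect."""
    if track.likelihood is None:
        raise ValueError("DLC dialect requires likelihood values")
    header1 = ["scorer"] + [scorer] * (3 * len(track.markers))
    header2 = ["bodyparts"] + [m for m in track.markers for _ in range(3)]
    header3 = ["coords"] + ["x", "y", "likelihood"] * len(track.markers)
    lines = [",".join(header1), ",".join(header2), ",".join(header3)]
    for f in range(track.n_frames):
        cells = [str(f)]
        for j in range(len(track.markers)):
            cells += [
                format(track.xy[f, j, 0], ".17g"),
                format(track.xy[f, j, 1], ".17g"),
                format(track.likelihood[f, j], ".17g"),
            ]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_reference(
    track: PoseTrack, events: GaitEvents, directory: str | Path,
    angles: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the reference-tracker CSV set (coords, events, angles)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "coords": directory / "ref_coords.csv",
        "events": directory / "ref_events.csv",
        "angles": directory / "ref_angles.csv",
    }
    rows = []
    for f in range(track.n_frames):
        for j, m in enumerate(track.markers):
            rows.append((f, m, format(track.xy[f, j, 0], ".17g"),
                         format(track.xy[f, j, 1], ".17g")))
    pd.DataFrame(rows, columns=["frame", "marker", "x_cm", "y_cm"]) \
        .to_csv(paths["coords"], index=False)

    ev_rows = sorted(
        [(int(f), "contact") for f in events.contacts]
        + [(int(f), "liftoff") for f in events.liftoffs]
    )
    pd.DataFrame(ev_rows, columns=["frame", "event"]) \
        .to_csv(paths["events"], index=False)

    if angles is None:
        angles = pd.DataFrame(columns=["frame", "joint", "angle_deg"])
    angles.to_csv(paths["angles"], index=False, float_format="%.17g")
    return paths


def write_fixture(model: GaitModel, directory: str | Path) -> dict[str, Path]:
    """Simulate a trial and write a complete fixture directory.

    Emits the markerless-pose CSV, the reference CSV set, the trial
    config, and the generator's truth tables — everything the pipeline
    needs to run end to end, in exactly the dialects ``pose_io`` reads.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth_track, events, truth_vars = simulate_gait(model)
    dlc, ref = render_trackers(truth_track, model)
    config = model.trial_config()

    paths: dict[str, Path] = {}
    paths["dlc"] = directory / "dlc.csv"
    write_dlc(dlc, paths["dlc"])

    cfg = config
    angle_rows = []
    for joint in kinematics.JOINT_DEFINITIONS:
        trace = kinematics.angle_trace(ref, cfg, joint)
        for f, a in enumerate(trace):
            angle_rows.append((f, joint, a))
    angles = pd.DataFrame(angle_rows, columns=["frame", "joint", "angle_deg"])
    paths.update(write_reference(ref, events, directory, angles))

    paths["config"] = directory / "config.yaml"
    config.to_yaml(paths["config"])

    paths["truth_variables"] = directory / "truth_variables.csv"
    truth_vars.to_csv(paths["truth_variables"], index=False, float_format="%.17g")
    return paths
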