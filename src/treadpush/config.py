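"""Model configuration: segments, joints, contact, controller, exoskeleton.

Default inertial parameters follow standard anthropometric regression tables
(de Leva-style segment mass fractions, center-of-mass positions and radii of
gyration) scaled to a configurable body mass and height.  The head, arms and
trunk above the pelvis are lumped into a single HAT segment.

Coordinate conventions, used everywhere in the package:

* world x anterior, y up; the treadmill surface is the plane y = 0 and its
  belt moves with velocity ``-belt_speed`` along x;
* in the zero configuration the model stands upright with both feet flat;
* joint angles: hip flexion, ankle dorsiflexion, knee flexion and toe
  (metatarsophalangeal) extension are positive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

JOINT_NAMES = (
    "lumbo_sacral",
    "r_hip",
    "r_knee",
    "r_ankle",
    "r_mtp",
    "l_hip",
    "l_knee",
    "l_ankle",
    "l_mtp",
)

SEGMENT_NAMES = (
    "pelvis",
    "hat",
    "r_thigh",
    "r_shank",
    "r_foot",
    "r_toes",
    "l_thigh",
    "l_shank",
    "l_foot",
    "l_toes",
)


@dataclass
class SegmentSpec:
    """One rigid segment of the planar chain.

    ``com_offset`` is the distance of the center of mass from the proximal
    joint along the segment's longitudinal axis.
    """

    name: str
    mass: float  # kg
    length: float  # m
    com_offset: float  # m
    inertia_com: float  # kg m^2
    proximal_joint: str | None = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be > 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if not (0 <= self.com_offset <= self.length):
            raise ValueError(f"segment {self.name}: com_offset outside [0, length]")
        if self.inertia_com < 0:
            raise ValueError(f"segment {self.name}: inertia_com must be >= 0")


@dataclass
class JointSpec:
    name: str
    parent: str
    child: str
    passive_stiffness: float | None = None  # N m / rad, metatarsophalangeal only
    passive_damping: float = 0.0  # N m s / rad


@dataclass
class ContactParams:
    """Penalty contact law parameters (Hunt-Crossley + regularized Coulomb)."""

    normal_stiffness: float = 2.0e6  # N / m^exponent
    exponent: float = 1.5
    normal_damping: float = 2.0  # s/m, force scales as (1 + damping * ddot)
    friction_coefficient: float = 0.9
    tangential_velocity_smoothing: float = 0.01  # m/s

    def __post_init__(self):
        if self.normal_stiffness < 0 or self.normal_damping < 0:
            raise ValueError("contact stiffness/damping must be >= 0")
        if self.friction_coefficient <= 0:
            raise ValueError("friction coefficient must be > 0")
        if self.tangential_velocity_smoothing <= 0:
            raise ValueError("velocity smoothing must be > 0")


@dataclass
class ContactSphere:
    segment: str
    local_position: tuple[float, float]  # m, segment frame
    radius: float  # m

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("contact sphere radius must be > 0")


@dataclass
class ControllerGains:
    """Per-joint PID gains plus the HAT-upright feedback pair.

    Defaults give stiff, near-critically-damped tracking sized from
    distal-chain inertia estimates; they were tuned once on the baseline gait
    and frozen.
    """

    hip: tuple[float, float, float] = (3200.0, 400.0, 220.0)
    knee: tuple[float, float, float] = (2600.0, 300.0, 90.0)
    ankle: tuple[float, float, float] = (2100.0, 300.0, 55.0)
    hat_upright: tuple[float, float] = (1500.0, 260.0)
    # pelvis-pitch posture PD, applied through the hip actuators (the
    # floating-base orientation is otherwise unregulated)
    pelvis_upright: tuple[float, float] = (1500.0, 450.0)
    # weight-scheduled pelvis-pitch feedback via the stance ankle (center-of-
    # pressure regulation); scaled by the instantaneous foot load
    ankle_posture: tuple[float, float] = (900.0, 0.0)
    # station keeping: stance-hip torque bias (N m per m, N m per m/s)
    # towards the treadmill origin; regulates the neutral antero-posterior
    # drift of treadmill walking
    station_keeping: tuple[float, float] = (400.0, 200.0)
    integrator_limit: float = 60.0  # N m

    def __post_init__(self):
        for g in (*self.hip, *self.knee, *self.ankle, *self.hat_upright,
                  *self.pelvis_upright, *self.ankle_posture,
                  *self.station_keeping):
            if g < 0:
                raise ValueError("controller gains must be >= 0")
        if self.integrator_limit <= 0:
            raise ValueError("integrator_limit must be > 0")


@dataclass
class ExoGeometry:
    """Attachment geometry of the assistance mechanism.

    Both the spool axis (on the foot) and the rigid-tendon attachment (on the
    shank) sit posterior to the ankle joint center, so tension in the rigid
    tendon produces plantarflexion torque.  The anchor is the tendon exit of
    the braking/pretensioning module in front of the treadmill.
    """

    anchor_position: tuple[float, float] = (1.0, 0.0)  # world, m
    spool_axis_local: tuple[float, float] = (-0.115, -0.03)  # foot frame, m
    shank_attachment_local: tuple[float, float] = (-0.12, -0.33)  # shank frame, m
    spool_ratio: float = 5.0

    def __post_init__(self):
        if self.spool_ratio <= 0:
            raise ValueError("spool_ratio must be > 0")
        if self.spool_axis_local[0] >= 0 or self.shank_attachment_local[0] >= 0:
            raise ValueError("attachment points must lie posterior to the ankle (x < 0)")


@dataclass
class ExoParams:
    """Control parameters of the assistance: stiffness and brake timings."""

    stiffness: float = 4.85  # N/m per kg body mass
    engage_phase: float = 29.0  # % stride
    disengage_phase: float = 53.0  # % stride
    enabled: bool = True

    def __post_init__(self):
        if self.enabled:
            if self.stiffness <= 0:
                raise ValueError("stiffness must be > 0")
            if not (0 <= self.engage_phase < self.disengage_phase < 100):
                raise ValueError("need 0 <= engage < disengage < 100 (% stride)")


@dataclass
class ModelConfig:
    """Full model description: 10 segments, 9 joints, belt, mass placement."""

    segments: list[SegmentSpec]
    joints: list[JointSpec]
    belt_speed: float = 1.18  # m/s
    gravity: float = 9.81
    body_mass: float = 70.0  # kg
    body_height: float = 1.73  # m
    added_mass: tuple[float, float] = (0.3, 0.5)  # (shank, foot) kg, exo side
    contact: ContactParams = field(default_factory=ContactParams)
    spheres: list[ContactSphere] = field(default_factory=list)
    gains: ControllerGains = field(default_factory=ControllerGains)
    fall_height_fraction: float = 0.6  # of standing pelvis height

    def __post_init__(self):
        if len(self.segments) != 10:
            raise ValueError(f"expected exactly 10 segments, got {len(self.segments)}")
        if len(self.joints) != 9:
            raise ValueError(f"expected exactly 9 joints, got {len(self.joints)}")
        names = [s.name for s in self.segments]
        if len(set(names)) != 10:
            raise ValueError("duplicate segment names")
        jnames = [j.name for j in self.joints]
        if len(set(jnames)) != 9:
            raise ValueError("duplicate joint names")
        mtp = [j for j in self.joints if j.passive_stiffness is not None]
        if sorted(j.name for j in mtp) != ["l_mtp", "r_mtp"]:
            raise ValueError("exactly the two metatarsophalangeal joints carry passive stiffness")
        # connectivity: every non-root segment reachable from pelvis
        children = {j.child: j.parent for j in self.joints}
        for s in names:
            if s == "pelvis":
                continue
            seen = set()
            cur = s
            while cur in children and cur not in seen:
                seen.add(cur)
                cur = children[cur]
            if cur != "pelvis":
                raise ValueError(f"segment {s} is not connected to the pelvis")


# ---------------------------------------------------------------------------
# defaults

# de Leva-style segment mass fractions; HAT takes the remainder so the sum is
# exactly the body mass.
_FRAC = {"pelvis": 0.1117, "thigh": 0.1416, "shank": 0.0433, "foot": 0.0123, "toes": 0.0014}

# foot geometry in the foot frame (origin at the ankle joint, flat sole at
# y = -SOLE_Y in the standing pose)
SOLE_Y = 0.07
HEEL_X = -0.055
MTP_X = 0.13
MTP_Y = -0.03
TOE_TIP_LOCAL = (0.045, -0.015)  # toes frame
SPHERE_R = 0.025
PELVIS_LS_Y = 0.10  # lumbo-sacral joint height above the hip center


def default_segments(body_mass: float = 70.0, body_height: float = 1.73) -> list[SegmentSpec]:
    """Anthropometric default segments scaled to body mass and height."""
    h = body_height / 1.73
    l_thigh, l_shank = 0.42 * h, 0.43 * h
    l_foot, l_toes = 0.26 * h, 0.07 * h
    m = body_mass
    hat_frac = 1.0 - _FRAC["pelvis"] - 2 * (
        _FRAC["thigh"] + _FRAC["shank"] + _FRAC["foot"] + _FRAC["toes"]
    )
    segs = [
        SegmentSpec("pelvis", _FRAC["pelvis"] * m, 0.10 * h, 0.05 * h, 0.08 * h * h, None),
        SegmentSpec("hat", hat_frac * m, 0.60 * h, 0.32 * h,
                    hat_frac * m * (0.372 * 0.60 * h) ** 2, "lumbo_sacral"),
    ]
    for side in ("r", "l"):
        segs += [
            SegmentSpec(f"{side}_thigh", _FRAC["thigh"] * m, l_thigh, 0.41 * l_thigh,
                        _FRAC["thigh"] * m * (0.329 * l_thigh) ** 2, f"{side}_hip"),
            SegmentSpec(f"{side}_shank", _FRAC["shank"] * m, l_shank, 0.44 * l_shank,
                        _FRAC["shank"] * m * (0.251 * l_shank) ** 2, f"{side}_knee"),
            SegmentSpec(f"{side}_foot", _FRAC["foot"] * m, l_foot, 0.05 * h,
                        _FRAC["foot"] * m * (0.257 * l_foot) ** 2, f"{side}_ankle"),
            SegmentSpec(f"{side}_toes", _FRAC["toes"] * m, l_toes, 0.025 * h,
                        1.0e-4, f"{side}_mtp"),
        ]
    # reorder: pelvis, hat, r leg, l leg already satisfied
    return segs


def default_joints(mtp_stiffness: float = 12.0, mtp_damping: float = 1.5) -> list[JointSpec]:
    joints = [JointSpec("lumbo_sacral", "pelvis", "hat")]
    for side in ("r", "l"):
        joints += [
            JointSpec(f"{side}_hip", "pelvis", f"{side}_thigh"),
            JointSpec(f"{side}_knee", f"{side}_thigh", f"{side}_shank"),
            JointSpec(f"{side}_ankle", f"{side}_shank", f"{side}_foot"),
            JointSpec(f"{side}_mtp", f"{side}_foot", f"{side}_toes",
                      passive_stiffness=mtp_stiffness, passive_damping=mtp_damping),
        ]
    return joints


def default_spheres() -> list[ContactSphere]:
    spheres = []
    for side in ("r", "l"):
        spheres += [
            ContactSphere(f"{side}_foot", (HEEL_X, -(SOLE_Y - SPHERE_R)), SPHERE_R),
            ContactSphere(f"{side}_foot", (MTP_X, -(SOLE_Y - SPHERE_R)), SPHERE_R),
            ContactSphere(f"{side}_toes", TOE_TIP_LOCAL, SPHERE_R),
        ]
    return spheres


def default_config(body_mass: float = 70.0, body_height: float = 1.73) -> ModelConfig:
    return ModelConfig(
        segments=default_segments(body_mass, body_height),
        joints=default_joints(),
        body_mass=body_mass,
        body_height=body_height,
        spheres=default_spheres(),
    )


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: ModelConfig, path, exo_params: ExoParams | None = None,
                exo_geometry: ExoGeometry | None = None) -> None:
    doc = {"model": _to_dict(config)}
    if exo_params is not None:
        doc["exoskeleton"] = _to_dict(exo_params)
    if exo_geometry is not None:
        doc["exoskeleton_geometry"] = _to_dict(exo_geometry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _tup(x):
    return tuple(x) if isinstance(x, list) else x


def load_config(path) -> tuple[ModelConfig, ExoParams | None, ExoGeometry | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    m = doc["model"]
    segs = [SegmentSpec(**s) for s in m.pop("segments")]
    joints = [JointSpec(**j) for j in m.pop("joints")]
    contact = ContactParams(**m.pop("contact"))
    spheres = [
        ContactSphere(s["segment"], _tup(s["local_position"]), s["radius"])
        for s in m.pop("spheres")
    ]
    g = m.pop("gains")
    gains = ControllerGains(
        hip=_tup(g["hip"]), knee=_tup(g["knee"]), ankle=_tup(g["ankle"]),
        hat_upright=_tup(g["hat_upright"]), integrator_limit=g["integrator_limit"],
        pelvis_upright=_tup(g.get("pelvis_upright", (1500.0, 450.0))),
        ankle_posture=_tup(g.get("ankle_posture", (900.0, 0.0))),
        station_keeping=_tup(g.get("station_keeping", (400.0, 200.0))),
    )
    m["added_mass"] = _tup(m["added_mass"])
    config = ModelConfig(segments=segs, joints=joints, contact=contact,
                         spheres=spheres, gains=gains, **m)
    exo_p = None
    if "exoskeleton" in doc:
        exo_p = ExoParams(**doc["exoskeleton"])
    exo_g = None
    if "exoskeleton_geometry" in doc:
        e = doc["exoskeleton_geometry"]
        exo_g = ExoGeometry(
            anchor_position=_tup(e["anchor_position"]),
            spool_axis_local=_tup(e["spool_axis_local"]),
            shank_attachment_local=_tup(e["shank_attachment_local"]),
            spool_ratio=e["spool_ratio"],
        )
    return config, exo_p, exo_g
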