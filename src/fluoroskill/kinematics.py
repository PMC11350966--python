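"""Forearm phantom, articulation chain and C-arm geometry.

The scene is a schematic right upper extremity lying supine on an arm
table, modelled as attenuating solid primitives (capsules, cylinders,
ellipsoids, boxes) grouped into three rigid segments: upper arm, forearm
(which carries the radius, ulna, volar plate and screws) and hand. The
arm articulates about three axes -- elbow flexion/extension, forearm
pronation/supination and wrist flexion/extension -- while the C-arm stays
fixed with a vertical beam (source above, detector below) by default.

Conventions
-----------
* Angles in degrees, lengths in millimetres.
* World frame: +x points distally along the neutral forearm, +z up
  (toward the X-ray source), +y completes a right-handed frame.
* The elbow joint sits at the origin; elbow flexion lifts the hand
  toward the source.  Pronation is positive (palm turns toward the
  detector); neutral is mid-prone, thumb up, palm facing -y.  Wrist
  flexion is positive (hand bends toward the palm).
* Joint limits: elbow [0, 150], rotation [-90, 90], wrist [-75, 75].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RigidTransform",
    "BonePrimitive",
    "ForearmPhantom",
    "ArticulationState",
    "CArmGeometry",
    "AngleRecord",
    "PosedPrimitive",
    "articulate",
    "nominal_state",
    "recorded_angles",
    "default_phantom",
    "default_carm",
    "JOINT_LIMITS",
    "NOMINAL_STATES",
    "VIEW_IDS",
]

VIEW_IDS = ("PA", "AP", "LAT", "FACET", "TANG")

JOINT_LIMITS = {
    "elbow_flexion_deg": (0.0, 150.0),
    "forearm_rotation_deg": (-90.0, 90.0),
    "wrist_flexion_deg": (-75.0, 75.0),
}


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: x -> R @ x + t (rotation orthonormal, det=+1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation matrix must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, center=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``center`` along ``axis``."""
        a = np.asarray(axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        a = a / n
        th = math.radians(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
        c = np.asarray(center, dtype=float)
        return cls(R, c - R @ c)

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


# ---------------------------------------------------------------------------
# primitives and phantom

_SHAPE_NDIMS = {"capsule": 2, "cylinder": 2, "ellipsoid": 3, "box": 3}


@dataclass(frozen=True)
class BonePrimitive:
    """One attenuating solid.

    Local shape conventions: capsules and cylinders have their axis along
    local +z with ``dimensions = (radius, half_length)`` (capsule
    half_length measured between cap centres); ellipsoids take semi-axes
    ``(a, b, c)``; boxes take half-extents ``(hx, hy, hz)``.  ``mu`` is
    the linear attenuation coefficient in 1/mm.
    """

    shape: str
    pose: RigidTransform
    dimensions: tuple
    mu: float
    label: str

    def __post_init__(self):
        if self.shape not in _SHAPE_NDIMS:
            raise ValueError(f"unknown shape kind: {self.shape!r}")
        dims = tuple(float(d) for d in self.dimensions)
        object.__setattr__(self, "dimensions", dims)
        if len(dims) != _SHAPE_NDIMS[self.shape]:
            raise ValueError(
                f"{self.shape} needs {_SHAPE_NDIMS[self.shape]} dimensions, got {len(dims)}"
            )
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be > 0")
        if self.mu < 0:
            raise ValueError("attenuation coefficient must be >= 0")


SEGMENTS = ("upperarm", "forearm", "hand")


@dataclass(frozen=True)
class ForearmPhantom:
    """Segmented phantom: each primitive belongs to exactly one segment.

    ``forearm_length`` locates the wrist joint at (forearm_length, 0, 0)
    in the neutral pose; the elbow joint is at the origin.
    """

    segments: dict
    forearm_length: float = 250.0

    def __post_init__(self):
        segs = {k: tuple(v) for k, v in self.segments.items()}
        object.__setattr__(self, "segments", segs)
        for name in segs:
            if name not in SEGMENTS:
                raise ValueError(f"unknown segment {name!r}")
        metal = [p for p in segs.get("forearm", ()) if p.mu >= 0.5]
        if not metal:
            raise ValueError("forearm segment must carry at least one metal primitive")

    @property
    def wrist_center(self) -> np.ndarray:
        return np.array([self.forearm_length, 0.0, 0.0])


@dataclass(frozen=True)
class PosedPrimitive:
    """A primitive placed in the world frame, tagged with its segment."""

    primitive: BonePrimitive
    world: RigidTransform
    segment: str


@dataclass(frozen=True)
class ArticulationState:
    elbow_flexion_deg: float = 0.0
    forearm_rotation_deg: float = 0.0
    wrist_flexion_deg: float = 0.0

    def __post_init__(self):
        for name, (lo, hi) in JOINT_LIMITS.items():
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v:g} outside joint limit [{lo:g}, {hi:g}]"
                )
            object.__setattr__(self, name, v)

    def as_tuple(self):
        return (
            self.elbow_flexion_deg,
            self.forearm_rotation_deg,
            self.wrist_flexion_deg,
        )


@dataclass(frozen=True)
class AngleRecord:
    """Angles recorded for one transferred image.

    Elbow flexion and forearm rotation are reported relative to the beam
    axis; the wrist angle (tangential view only) is measured between hand
    and forearm and is beam-independent.
    """

    elbow_flexion_deg: float
    forearm_rotation_deg: float
    wrist_angle_deg: float | None = None

    def __post_init__(self):
        for v in (self.elbow_flexion_deg, self.forearm_rotation_deg):
            if not math.isfinite(float(v)):
                raise ValueError("recorded angles must be finite")
        if self.wrist_angle_deg is not None and not math.isfinite(
            float(self.wrist_angle_deg)
        ):
            raise ValueError("recorded wrist angle must be finite")

    def angles(self) -> dict:
        out = {
            "elbow": float(self.elbow_flexion_deg),
            "rotation": float(self.forearm_rotation_deg),
        }
        if self.wrist_angle_deg is not None:
            out["wrist"] = float(self.wrist_angle_deg)
        return out


# ---------------------------------------------------------------------------
# C-arm


@dataclass(frozen=True)
class CArmGeometry:
    """Fixed C-arm: source above, detector below, beam along -z by default.

    The detector plane passes through ``det_origin`` with in-plane basis
    ``det_u`` (image columns) and ``det_v`` (image rows); the beam axis is
    orthogonal to the plane.  ``projection`` selects parallel (default)
    or cone-beam ray geometry.
    """

    beam_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    source_pos: np.ndarray = field(default_factory=lambda: np.array([250.0, 0.0, 600.0]))
    det_origin: np.ndarray = field(default_factory=lambda: np.array([250.0, 0.0, -150.0]))
    det_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    det_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    det_size_mm: tuple = (128.0, 128.0)
    pixel_pitch_mm: float = 0.5
    projection: str = "parallel"
    auto_center: bool = True

    def __post_init__(self):
        for name in ("beam_dir", "source_pos", "det_origin", "det_u", "det_v"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        b = self.beam_dir / np.linalg.norm(self.beam_dir)
        object.__setattr__(self, "beam_dir", b)
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be > 0")
        if min(self.det_size_mm) <= 0:
            raise ValueError("detector size must be > 0")
        if self.projection not in ("parallel", "cone"):
            raise ValueError("projection must be 'parallel' or 'cone'")
        if abs(float(b @ self.det_u)) > 1e-9 or abs(float(b @ self.det_v)) > 1e-9:
            raise ValueError("beam axis must be orthogonal to the detector plane")

    @property
    def shape_px(self) -> tuple:
        w = int(round(self.det_size_mm[0] / self.pixel_pitch_mm))
        h = int(round(self.det_size_mm[1] / self.pixel_pitch_mm))
        return (h, w)

    def to_json(self) -> str:
        return json.dumps(
            {
                "beam_dir": self.beam_dir.tolist(),
                "source_pos": self.source_pos.tolist(),
                "det_origin": self.det_origin.tolist(),
                "det_u": self.det_u.tolist(),
                "det_v": self.det_v.tolist(),
                "det_size_mm": list(self.det_size_mm),
                "pixel_pitch_mm": self.pixel_pitch_mm,
                "projection": self.projection,
                "auto_center": self.auto_center,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CArmGeometry":
        d = json.loads(text)
        d["det_size_mm"] = tuple(d["det_size_mm"])
        return cls(**d)


def default_carm(**overrides) -> CArmGeometry:
    """Default vertical-beam C-arm centred over the wrist region."""
    return replace(CArmGeometry(), **overrides) if overrides else CArmGeometry()


# ---------------------------------------------------------------------------
# articulation chain

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _chain_transforms(phantom: ForearmPhantom, state: ArticulationState):
    """Segment transforms for a given pose.

    Forearm: elbow flexion about the fixed elbow axis (world y, through
    the origin); positive flexion lifts the distal forearm toward +z.
    Hand: forearm transform, then axial rotation about the forearm long
    axis (pronation positive), then wrist flexion about the carried wrist
    axis through the wrist centre.
    """
    t_upper = RigidTransform.identity()
    t_fore = RigidTransform.from_axis_angle(_Y, -state.elbow_flexion_deg)
    r_axial = RigidTransform.from_axis_angle(_X, state.forearm_rotation_deg)
    r_wrist = RigidTransform.from_axis_angle(
        _Z, -state.wrist_flexion_deg, center=phantom.wrist_center
    )
    t_hand = t_fore @ r_axial @ r_wrist
    return {"upperarm": t_upper, "forearm": t_fore, "hand": t_hand}


def articulate(phantom: ForearmPhantom, state: ArticulationState) -> list:
    """Pose the phantom: returns the world-frame primitive list.

    Raises ``ValueError`` (from ``ArticulationState``) when any joint
    angle is outside its limit.
    """
    chain = _chain_transforms(phantom, state)
    scene = []
    for segment, prims in phantom.segments.items():
        t_seg = chain[segment]
        for prim in prims:
            scene.append(PosedPrimitive(prim, t_seg @ prim.pose, segment))
    return scene


# Nominal articulation per standard view: (elbow, rotation, wrist).  These
# drive the demo renderer and the synthetic cohort's aiming targets only;
# scoring is expert-referenced and never consults this table.
NOMINAL_STATES = {
    "PA": ArticulationState(0.0, 90.0, 0.0),
    "AP": ArticulationState(0.0, -90.0, 0.0),
    "LAT": ArticulationState(0.0, 0.0, 0.0),
    "FACET": ArticulationState(20.0, 0.0, 0.0),
    "TANG": ArticulationState(0.0, 90.0, 70.0),
}


def nominal_state(view_id: str) -> ArticulationState:
    """Nominal arm configuration for one of the 5 standard views."""
    try:
        return NOMINAL_STATES[view_id]
    except KeyError:
        raise KeyError(
            f"unknown view {view_id!r}; expected one of {', '.join(VIEW_IDS)}"
        ) from None


def _signed_angle_about(axis, v_from, v_to) -> float:
    """Signed angle (deg) from v_from to v_to about axis, all in 3D."""
    a = axis / np.linalg.norm(axis)
    u = v_from - (v_from @ a) * a
    w = v_to - (v_to @ a) * a
    s = float(np.cross(u, w) @ a)
    c = float(u @ w)
    return math.degrees(math.atan2(s, c))


def recorded_angles(
    state: ArticulationState, carm: CArmGeometry, view_id: str
) -> AngleRecord:
    """Angles the simulator logs for a transferred image.

    Elbow flexion relative to the beam is the elevation of the forearm
    long axis out of the detector plane; forearm rotation is the axial
    angle of the palm measured against the beam direction projected into
    the plane orthogonal to the forearm.  Under the default vertical beam
    both equal the joint angles.  The wrist angle (tangential view only)
    is the hand-forearm angle and does not depend on the beam.
    """
    if view_id not in VIEW_IDS:
        raise KeyError(f"unknown view {view_id!r}")
    phantom = _REFERENCE_PHANTOM
    chain = _chain_transforms(phantom, state)
    f = chain["forearm"].apply_vector(_X)
    b = carm.beam_dir

    elbow_rel = math.degrees(math.asin(float(np.clip(f @ (-b), -1.0, 1.0))))

    # palm direction with wrist flexion factored out
    t_palm = chain["forearm"] @ RigidTransform.from_axis_angle(
        _X, state.forearm_rotation_deg
    )
    palm = t_palm.apply_vector(-_Y)
    rot_rel = _signed_angle_about(f, b - (b @ f) * f, palm) + 90.0
    rot_rel = (rot_rel + 180.0) % 360.0 - 180.0

    if view_id != "TANG":
        return AngleRecord(elbow_rel, rot_rel)

    h = chain["hand"].apply_vector(_X)
    wrist_axis = t_palm.apply_vector(_Z)
    wrist_rel = -_signed_angle_about(wrist_axis, f, h)
    return AngleRecord(elbow_rel, rot_rel, wrist_rel)


# ---------------------------------------------------------------------------
# default phantom

_MU_BONE = 0.05   # 1/mm, cortical-bone order of magnitude
_MU_METAL = 1.0   # 1/mm, implant steel/titanium order of magnitude


def default_phantom() -> ForearmPhantom:
    """Schematic plated forearm.

    Radius and ulna run as parallel capsules from the elbow to the wrist;
    a volar locking plate (box) with four screws (thin cylinders) sits on
    the palmar cortex of the distal radius; the hand is a carpal
    ellipsoid block plus three metacarpal capsules.  Geometry is
    deliberately simple -- the images only need to respond correctly to
    articulation, not to look anatomical.
    """
    L = 250.0

    def cap(x0, x1, y, z, r, mu, label):
        mid = np.array([(x0 + x1) / 2.0, y, z])
        half = abs(x1 - x0) / 2.0
        pose = RigidTransform.from_axis_angle(_Y, 90.0) @ RigidTransform.identity()
        # capsule local axis is +z; rotate it onto +x then translate
        pose = RigidTransform(pose.rotation, mid)
        return BonePrimitive("capsule", pose, (r, half), mu, label)

    forearm = [
        cap(5.0, L - 12.0, -7.0, 0.0, 7.0, _MU_BONE, "radius"),
        cap(5.0, L - 18.0, 7.0, 0.0, 6.0, _MU_BONE, "ulna"),
        # volar plate: thin box on the palmar cortex (palm faces -y in neutral)
        BonePrimitive(
            "box",
            RigidTransform.from_translation([L - 30.0, -15.5, 0.0]),
            (25.0, 1.5, 6.0),
            _MU_METAL,
            "volar_plate",
        ),
    ]
    screw_rot = RigidTransform.from_axis_angle(_X, -90.0).rotation  # local z -> +y
    for i, x in enumerate((L - 48.0, L - 36.0, L - 24.0, L - 14.0)):
        forearm.append(
            BonePrimitive(
                "cylinder",
                RigidTransform(screw_rot, np.array([x, -10.0, 0.0])),
                (1.4, 7.0),
                _MU_METAL,
                f"screw_{i + 1}",
            )
        )

    hand = [
        BonePrimitive(
            "ellipsoid",
            RigidTransform.from_translation([L + 18.0, 0.0, 0.0]),
            (18.0, 14.0, 10.0),
            _MU_BONE,
            "carpal_block",
        )
    ]
    for j, y in enumerate((-12.0, 0.0, 12.0)):
        mid = np.array([L + 58.0, y, 0.0])
        pose = RigidTransform(
            RigidTransform.from_axis_angle(_Y, 90.0).rotation, mid
        )
        hand.append(
            BonePrimitive("capsule", pose, (4.0, 22.0), _MU_BONE, f"metacarpal_{j + 1}")
        )

    upper = [
        BonePrimitive(
            "capsule",
            RigidTransform(
                RigidTransform.from_axis_angle(_Y, 90.0).rotation,
                np.array([-90.0, 0.0, 0.0]),
            ),
            (12.0, 75.0),
            _MU_BONE,
            "humerus",
        )
    ]

    return ForearmPhantom(
        {"upperarm": upper, "forearm": forearm, "hand": hand}, forearm_length=L
    )


# recorded_angles only needs the wrist-joint location, which is a phantom
# constant; a module-level reference phantom keeps the call signature flat.
_REFERENCE_PHANTOM = None


def _init_reference():
    global _REFERENCE_PHANTOM
    if _REFERENCE_PHANTOM is None:
        _REFERENCE_PHANTOM = default_phantom()


_init_reference()
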