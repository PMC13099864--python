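"""2D range/crossrange arena: two-glint targets and the bat's kinematic state.

Coordinates are a continuous plane with x = crossrange and y = range; the bat
conventionally starts at the origin heading +y.  Every target is a pair of
point reflectors ("glints") whose centre-to-centre separation, seen end-on,
produces a two-way echo-delay difference ``dt = 2 * spacing / c``.  Target
spacings are therefore most naturally quoted in seconds of glint delay; a
100 us delay corresponds to 17 mm of separation at c = 340 m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "SOUND_SPEED",
    "EAR_SEPARATION",
    "DESIRED_SPACING",
    "Target",
    "BatState",
    "Scene",
    "build_scene",
    "preset_scene",
    "random_scene",
    "projected_glint_delay",
    "spacing_to_meters",
    "heading_vector",
    "heading_degrees",
    "load_scene",
    "save_scene",
    "PRESET_NAMES",
]

#: Speed of sound used throughout, m/s.  340 makes 17 mm <-> 100 us exact.
SOUND_SPEED = 340.0
#: Distance between the two ears, metres.
EAR_SEPARATION = 0.014
#: End-on glint delay of the one target the searcher is looking for, seconds.
DESIRED_SPACING = 100e-6

#: Minimum centre-to-centre distance between targets in generated scenes, m.
MIN_TARGET_DISTANCE = 0.30


def heading_vector(deg: float) -> np.ndarray:
    """Unit vector for a heading given in degrees CCW from the +y axis."""
    a = math.radians(deg)
    return np.array([-math.sin(a), math.cos(a)])


def heading_degrees(v: np.ndarray) -> float:
    """Inverse of :func:`heading_vector` (degrees CCW from +y, in (-180, 180])."""
    return math.degrees(math.atan2(-v[0], v[1]))


def spacing_to_meters(delay_s: float, c: float = SOUND_SPEED) -> float:
    """Convert an end-on two-way glint delay (s) to physical separation (m)."""
    return c * delay_s / 2.0


@dataclass
class Target:
    """A two-glint point target.

    ``position`` is the centre of the glint pair; the glints sit at
    ``position +/- (glint_spacing / 2) * glint_axis``.
    """

    id: str
    position: np.ndarray          # (2,) metres, (x crossrange, y range)
    glint_spacing: float          # metres, centre-to-centre
    glint_axis: np.ndarray        # (2,) unit vector (axis_mode "fixed")
    reflectivity: float = 1.0
    #: "fixed": the glint axis is a world-frame constant; "facing": the
    #: glint pair lies along the line of sight, so the target presents its
    #: full (end-on) glint delay to any observer.  Generated scenes default
    #: to "facing", which makes the classification feature intrinsic to the
    #: target rather than dependent on the approach direction.
    axis_mode: str = "fixed"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        self.glint_axis = np.asarray(self.glint_axis, float)
        if self.glint_spacing <= 0:
            raise ValueError(f"glint_spacing must be > 0, got {self.glint_spacing}")
        if self.axis_mode not in ("fixed", "facing"):
            raise ValueError(f"unknown axis_mode {self.axis_mode!r}")
        n = np.linalg.norm(self.glint_axis)
        if n == 0:
            raise ValueError("glint_axis must be nonzero")
        self.glint_axis = self.glint_axis / n

    def axis_toward(self, observer: np.ndarray | None = None) -> np.ndarray:
        """Effective glint axis for a given observer position."""
        if self.axis_mode == "facing" and observer is not None:
            v = np.asarray(observer, float) - self.position
            n = np.linalg.norm(v)
            if n > 0:
                return v / n
        return self.glint_axis

    def glint_positions(self, observer: np.ndarray | None = None) -> np.ndarray:
        """(2, 2) array with the two glint positions as seen from ``observer``."""
        off = 0.5 * self.glint_spacing * self.axis_toward(observer)
        return np.stack([self.position - off, self.position + off])

    @property
    def glints(self) -> np.ndarray:
        """(2, 2) array with the two glint positions (fixed-axis view)."""
        return self.glint_positions(None)

    def end_on_delay(self, c: float = SOUND_SPEED) -> float:
        """Two-way glint delay when viewed along the glint axis, seconds."""
        return 2.0 * self.glint_spacing / c


@dataclass
class BatState:
    """Pose of the model bat: position plus flight and sonar-beam headings."""

    position: np.ndarray
    flight_heading: np.ndarray
    beam_heading: np.ndarray
    speed: float = 0.3            # metres advanced per broadcast epoch
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        for name in ("flight_heading", "beam_heading"):
            v = np.asarray(getattr(self, name), float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be nonzero")
            setattr(self, name, v / n)

    def copy(self) -> "BatState":
        return BatState(
            self.position.copy(),
            self.flight_heading.copy(),
            self.beam_heading.copy(),
            self.speed,
            self.epoch_index,
        )


@dataclass
class Scene:
    """A search arena: targets, the bat's start pose and the physics constants."""

    targets: list[Target]
    bat_init: BatState
    desired_spacing: float = DESIRED_SPACING
    sound_speed: float = SOUND_SPEED
    ear_separation: float = EAR_SEPARATION

    def desired_targets(self, rel_tol: float = 0.05) -> list[Target]:
        """Targets whose end-on delay matches ``desired_spacing``."""
        return [
            t for t in self.targets
            if abs(t.end_on_delay(self.sound_speed) - self.desired_spacing)
            <= rel_tol * self.desired_spacing
        ]

    def validate(self) -> None:
        pos = np.array([t.position for t in self.targets])
        if len(pos) == 0:
            raise ValueError("scene has no targets")
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() == 0:
            raise ValueError("scene has targets at duplicate positions")


def projected_glint_delay(target: Target, observer: np.ndarray,
                          c: float = SOUND_SPEED) -> float:
    """Two-way delay difference between the two glint reflections seen from
    ``observer``.

    Exact two-distance formula ``|d2 - d1| * 2 / c``; in the far field this
    tends to ``(2 * spacing / c) * |cos(theta)|`` where theta is the aspect
    angle between the glint axis and the line of sight.  A broadside view
    returns 0, which is a valid (degenerate) value.
    """
    observer = np.asarray(observer, float)
    if np.allclose(observer, target.position):
        raise ValueError("observer coincides with target position")
    g = target.glint_positions(observer)
    d = np.linalg.norm(g - observer, axis=1)
    return abs(d[1] - d[0]) * 2.0 / c


def _axis_toward(target_pos: np.ndarray, point: np.ndarray) -> np.ndarray:
    v = np.asarray(point, float) - np.asarray(target_pos, float)
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([0.0, 1.0])
    return v / n


def build_scene(target_specs, bat_init: BatState | None = None, *,
                desired_spacing: float = DESIRED_SPACING,
                sound_speed: float = SOUND_SPEED,
                ear_separation: float = EAR_SEPARATION) -> Scene:
    """Build a validated :class:`Scene` from compact target specs.

    Each spec is ``(position, glint_delay_seconds)`` or
    ``(position, glint_delay_seconds, axis)``; delays are end-on two-way
    values converted internally via ``spacing_m = c * dt / 2``.  When the
    axis is omitted the target is built in "facing" mode: its glint pair
    lies along the line of sight, presenting the full end-on delay to any
    observer.  An explicit axis fixes the orientation in the world frame.
    """
    if bat_init is None:
        bat_init = BatState(np.zeros(2), np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    targets = []
    for i, spec in enumerate(target_specs):
        if len(spec) == 2:
            pos, dt = spec
            axis = _axis_toward(pos, bat_init.position)
            mode = "facing"
        else:
            pos, dt, axis = spec
            mode = "fixed"
        if dt <= 0:
            raise ValueError(f"non-positive glint delay {dt} for target {i}")
        targets.append(Target(
            id=f"T{i + 1}",
            position=np.asarray(pos, float),
            glint_spacing=spacing_to_meters(dt, sound_speed),
            glint_axis=np.asarray(axis, float),
            axis_mode=mode,
        ))
    scene = Scene(targets, bat_init, desired_spacing, sound_speed, ear_separation)
    scene.validate()
    return scene


# Preset layouts.  The published figures give only qualitative target
# arrangements, so these coordinates are this package's documented constants;
# each preset contains exactly one target with the desired 100 us spacing.
_PRESETS: dict[str, list[tuple[tuple[float, float], float]]] = {
    "single": [((0.0, 1.5), 100e-6)],
    # five targets, distractors spanning 50-1000 us
    "five": [
        ((-1.0, 1.2), 300e-6),
        ((0.9, 1.5), 50e-6),
        ((-0.7, 2.3), 500e-6),
        ((1.2, 2.5), 1000e-6),
        ((0.2, 3.0), 100e-6),
    ],
    # eight targets: one 300 us, six 1000 us, one desired
    "eight": [
        ((0.8, 1.1), 1000e-6),
        ((-0.9, 1.4), 300e-6),
        ((1.4, 1.9), 1000e-6),
        ((-1.4, 2.1), 1000e-6),
        ((0.3, 2.2), 1000e-6),
        ((-0.5, 2.9), 1000e-6),
        ((1.1, 3.0), 1000e-6),
        ((-1.2, 3.1), 100e-6),
    ],
}


def _preset_twenty() -> list[tuple[tuple[float, float], float]]:
    # 20 targets along the right and upper sides of the plane; distractor
    # spacings cycle through 200-2000 us, the desired target sits mid-plane.
    pool = [200e-6, 300e-6, 500e-6, 800e-6, 1000e-6, 1500e-6, 2000e-6]
    specs: list[tuple[tuple[float, float], float]] = []
    # right side: 10 targets going up at x ~ 1.8
    for i in range(10):
        specs.append(((1.8 - 0.04 * i, 0.8 + 0.36 * i), pool[i % len(pool)]))
    # upper side: 9 targets going left at y ~ 4.3
    for i in range(9):
        specs.append(((1.0 - 0.4 * i, 4.3), pool[(i + 3) % len(pool)]))
    specs.append(((-0.6, 3.2), 100e-6))
    return specs


def _preset_grid90() -> list[tuple[tuple[float, float], float]]:
    # 9 x 10 rectangular grid; spacings cycle 50-2000 us, one cell desired.
    pool = [50e-6, 200e-6, 300e-6, 500e-6, 1000e-6, 1500e-6, 2000e-6]
    specs: list[tuple[tuple[float, float], float]] = []
    xs = np.linspace(-1.8, 1.8, 10)
    ys = np.linspace(0.9, 3.3, 9)
    k = 0
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            if (iy, ix) == (6, 8):      # the desired target, deep in the grid
                specs.append(((float(x), float(y)), 100e-6))
            else:
                specs.append(((float(x), float(y)), pool[k % len(pool)]))
            k += 1
    return specs


PRESET_NAMES = ("single", "five", "eight", "twenty", "grid90")


def preset_scene(name: str) -> Scene:
    """Return one of the documented preset scenes.

    ``single`` is one desired target at (0, 1.5) m with the bat at the
    origin; ``five``/``eight``/``twenty``/``grid90`` hold 5/8/20/90 targets
    with distractor spacing sets matching the published scenes and exactly
    one 100 us target each.
    """
    if name == "twenty":
        specs = _preset_twenty()
    elif name == "grid90":
        specs = _preset_grid90()
    elif name in _PRESETS:
        specs = _PRESETS[name]
    else:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    return build_scene(specs)


def random_scene(n_targets: int,
                 spacing_pool=(30e-6, 50e-6, 200e-6, 300e-6, 1000e-6, 2000e-6),
                 arena=((-1.8, 1.8), (0.8, 3.6)),
                 seed: int = 0, *,
                 min_distance: float = 0.45,
                 max_tries: int = 2000) -> Scene:
    """Generate a random solvable scene: ``n_targets`` targets inside
    ``arena`` with one desired 100 us target and distractor spacings drawn
    from ``spacing_pool``.  Deterministic given ``seed``.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = arena
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n_targets:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_targets} targets with min distance "
                f"{min_distance} m in arena {arena} after {max_tries} tries"
            )
        p = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        tries += 1
        if all(np.linalg.norm(p - q) >= min_distance for q in positions):
            positions.append(p)
    spacings = [float(rng.choice(spacing_pool)) for _ in range(n_targets)]
    spacings[int(rng.integers(n_targets))] = DESIRED_SPACING
    specs = [((float(p[0]), float(p[1])), s) for p, s in zip(positions, spacings)]
    return build_scene(specs)


# ---------------------------------------------------------------- scene files

def save_scene(scene: Scene, path) -> None:
    """Write a scene to YAML (spacings in us, axis as degrees CCW from +y)."""
    doc = {
        "targets": [
            {
                "id": t.id,
                "x_m": float(t.position[0]),
                "y_m": float(t.position[1]),
                "spacing_us": float(t.end_on_delay(scene.sound_speed) * 1e6),
                "axis_deg": ("facing" if t.axis_mode == "facing"
                             else float(heading_degrees(t.glint_axis))),
                "reflectivity": float(t.reflectivity),
            }
            for t in scene.targets
        ],
        "bat": {
            "x_m": float(scene.bat_init.position[0]),
            "y_m": float(scene.bat_init.position[1]),
            "heading_deg": float(heading_degrees(scene.bat_init.flight_heading)),
        },
        "physics": {
            "c_mps": float(scene.sound_speed),
            "ear_separation_m": float(scene.ear_separation),
            "desired_spacing_us": float(scene.desired_spacing * 1e6),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scene(path) -> Scene:
    """Read a scene written by :func:`save_scene` (exact round trip)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    phys = doc.get("physics", {})
    c = float(phys.get("c_mps", SOUND_SPEED))
    bat = doc["bat"]
    heading = heading_vector(float(bat["heading_deg"]))
    bat_init = BatState(np.array([bat["x_m"], bat["y_m"]], float),
                        heading.copy(), heading.copy())
    targets = []
    for t in doc["targets"]:
        facing = t.get("axis_deg") == "facing"
        targets.append(Target(
            id=str(t["id"]),
            position=np.array([t["x_m"], t["y_m"]], float),
            glint_spacing=spacing_to_meters(float(t["spacing_us"]) * 1e-6, c),
            glint_axis=(np.array([0.0, 1.0]) if facing
                        else heading_vector(float(t["axis_deg"]))),
            reflectivity=float(t.get("reflectivity", 1.0)),
            axis_mode="facing" if facing else "fixed",
        ))
    scene = Scene(
        targets,
        bat_init,
        desired_spacing=float(phys.get("desired_spacing_us", 100.0)) * 1e-6,
        sound_speed=c,
        ear_separation=float(phys.get("ear_separation_m", EAR_SEPARATION)),
    )
    scene.validate()
    return scene
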