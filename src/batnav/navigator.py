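"""Binaural localisation and pursuit control.

Azimuth comes from the difference between the echo's arrival times at the
two ears; the sonar beam (head aim) turns quickly toward the estimated
bearing while the flight heading follows the beam under a tighter per-epoch
turn-rate limit, so the beam fixates the target before the flight path
aligns — reproducing the beam-leads-flight behaviour of hunting bats.
Classification by glint spacing happens only once the target is nearly dead
ahead (small azimuth), where the aspect distortion of the measured glint
delay is minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .receiver import GlintEstimate
from .scene import DESIRED_SPACING, EAR_SEPARATION, BatState

__all__ = [
    "NavParams",
    "EpochDecision",
    "binaural_azimuth",
    "select_nearest",
    "update_beam_aim",
    "update_flight",
    "classify_target",
    "relative_azimuth",
]


@dataclass(frozen=True)
class NavParams:
    """Controller constants.

    Defaults: 0.3 m advanced per epoch (~3 m/s at a 10 Hz pulse rate),
    flight turn limited to 15 deg/epoch while the beam may slew 60
    deg/epoch, classification gated to within 5 deg of dead ahead, accept
    tolerance +-20 us around the desired 100 us spacing, capture within
    0.1 m.
    """

    ear_separation: float = EAR_SEPARATION
    max_flight_turn: float = 15.0       # deg per epoch
    max_beam_turn: float = 60.0         # deg per epoch
    speed: float = 0.3                  # m per epoch
    classify_azimuth_gate: float = 5.0  # deg
    accept_tolerance: float = 20e-6     # s
    capture_radius: float = 0.1         # m
    lost_retries: int = 10
    glint_patience: int = 4             # in-gate epochs without a glint
                                        # measurement before giving up
    track_gate: float = 0.4e-3          # s, half-width of delay window;
                                        # tight enough that clusters merged
                                        # with a neighbouring target's echo
                                        # (delay-biased) are not trusted
    classify_max_range: float = 2.0     # m, classify only when this close

    def __post_init__(self) -> None:
        if not self.max_beam_turn > self.max_flight_turn > 0:
            raise ValueError("require max_beam_turn > max_flight_turn > 0")
        if self.accept_tolerance <= 0:
            raise ValueError("accept_tolerance must be > 0")


@dataclass
class EpochDecision:
    """What the bat concluded in one broadcast epoch."""

    selected_target: str | None
    azimuth_est: float | None           # deg, positive = right
    delay_est: float | None             # s
    glint_dt_est: float | None          # s
    action: str                         # approach | accept | reject | lost


def binaural_azimuth(left_delay: float, right_delay: float,
                     p: NavParams, c: float) -> tuple[float, bool]:
    """Azimuth (deg) from the interaural arrival-time difference.

    ``azimuth = arcsin(c * (left - right) / ear_separation)``; positive
    means the target lies to the right (its echo reaches the right ear
    first).  Differences beyond the physically possible +-a/c are clamped
    and flagged; returns ``(azimuth_deg, clamped)``.
    """
    x = c * (left_delay - right_delay) / p.ear_separation
    clamped = abs(x) > 1.0
    return math.degrees(math.asin(np.clip(x, -1.0, 1.0))), clamped


def select_nearest(estimates):
    """Pick the candidate with the shortest echo delay.

    ``estimates`` is a list of ``(candidate, delay_s)``; ties break toward
    the smaller candidate (id).  Raises LookupError when the scene is
    exhausted (no candidates remain).
    """
    if not estimates:
        raise LookupError("scene exhausted: no unrejected candidates")
    return min(estimates, key=lambda e: (e[1], e[0]))[0]


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    ca, sa = math.cos(a), math.sin(a)
    return np.array([ca * v[0] - sa * v[1], sa * v[0] + ca * v[1]])


def relative_azimuth(heading: np.ndarray, direction: np.ndarray) -> float:
    """Signed angle (deg) from ``heading`` to ``direction``; positive = right."""
    cross = heading[0] * direction[1] - heading[1] * direction[0]
    dot = float(np.dot(heading, direction))
    return -math.degrees(math.atan2(cross, dot))


def update_beam_aim(state: BatState, azimuth_est: float, p: NavParams) -> BatState:
    """Slew the sonar beam toward the estimated bearing, rate-limited.

    The beam rotates by the estimated azimuth, clipped to
    ``max_beam_turn``; with the default limit at or above the field of
    view the aim fixates in a single epoch.
    """
    turn = float(np.clip(azimuth_est, -p.max_beam_turn, p.max_beam_turn))
    out = state.copy()
    # positive azimuth = right = clockwise = negative CCW rotation
    out.beam_heading = _rotate(state.beam_heading, -turn)
    return out


def update_flight(state: BatState, p: NavParams,
                  speed: float | None = None,
                  max_turn: float | None = None) -> BatState:
    """Turn the flight heading toward the beam (rate-limited) and advance.

    The flight vector rotates toward the beam by at most
    ``max_flight_turn`` degrees (or ``max_turn`` when given), then the bat
    advances ``speed`` metres (default ``p.speed``) along the new heading
    and the epoch index increments.
    """
    limit = p.max_flight_turn if max_turn is None else max_turn
    off = relative_azimuth(state.flight_heading, state.beam_heading)
    turn = float(np.clip(off, -limit, limit))
    out = state.copy()
    out.flight_heading = _rotate(state.flight_heading, -turn)
    out.position = state.position + (p.speed if speed is None else speed) \
        * out.flight_heading
    out.epoch_index = state.epoch_index + 1
    return out


def classify_target(est: GlintEstimate | None, azimuth_est: float | None,
                    p: NavParams, desired: float = DESIRED_SPACING) -> str:
    """Accept/reject decision for the currently tracked target.

    No estimate -> "lost" (the caller re-emits and eventually drops the
    candidate).  While the target is outside the azimuth gate the verdict
    is "approach" (keep homing; the glint measurement is aspect-distorted).
    Inside the gate, accept only a clean single-mode echo whose glint delay
    sits within the accept tolerance of the desired spacing; anything else
    — wrong spacing, resolved multi-echo modes, or no measurable nulls —
    is rejected.
    """
    if est is None or azimuth_est is None:
        return "lost"
    if abs(azimuth_est) > p.classify_azimuth_gate:
        return "approach"
    if est.secondary_delays:
        return "reject"
    if est.glint_dt is None:
        return "reject"
    if abs(est.glint_dt - desired) <= p.accept_tolerance:
        return "accept"
    return "reject"
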