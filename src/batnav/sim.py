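"""The epoch loop: scene-by-scene search for the desired 100 us target.

Each broadcast defines an epoch: the bat emits the FM pulse, the scene
returns a binaural echo mixture, the SCAT receiver estimates delays, azimuth
and glint spacing, the navigator steers beam and flight, and — once the
tracked target is nearly dead ahead — the target is accepted (glint delay
within tolerance of 100 us) or rejected.  Rejected targets are remembered
for the remainder of the scene and the search resumes with the next nearest
target; the run ends when the desired target is captured, the scene is
exhausted, or an epoch budget is hit.

Classification verdicts must repeat on two consecutive gated epochs before
they commit; a single epoch's estimate can be distorted by a momentarily
overlapping echo from a neighbouring target, and the bat's own motion
de-correlates such accidents between epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import ChirpParams, generate_broadcast, \
    synthesize_binaural_echoes
from .navigator import EpochDecision, NavParams, binaural_azimuth, \
    select_nearest, update_beam_aim, update_flight, classify_target
from .receiver import FilterbankParams, GlintEstimate, ScatReceiver
from .scene import BatState, Scene, heading_degrees

__all__ = [
    "EpochRecord",
    "SearchResult",
    "Simulation",
    "run_search",
    "epochs_metric",
    "export_run",
]

#: Default signal-to-noise ratio of the ear mixtures, dB re a glint echo.
DEFAULT_SNR_DB = 40.0


@dataclass
class EpochRecord:
    """Complete log of one broadcast epoch."""

    epoch: int
    bat: BatState
    decision: EpochDecision
    estimate: GlintEstimate | None    # binaural (left-referenced) estimate
    itd: float | None                 # interaural time difference, s
    truth: dict


@dataclass
class SearchResult:
    """Outcome of a scene run plus the per-target epoch attribution."""

    records: list[EpochRecord]
    outcome: str                      # captured | exhausted | max_epochs
    captured_target: str | None
    epochs_per_target: list[tuple[str, int, str]]   # (id, epochs, verdict)
    scene: Scene = None

    @property
    def total_epochs(self) -> int:
        return len(self.records)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom == 0:
        return float(np.linalg.norm(p - a))
    t = np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


class Simulation:
    """Stateful scene search; call :meth:`run_epoch` until resolved."""

    def __init__(self, scene: Scene, nav: NavParams | None = None,
                 chirp: ChirpParams | None = None,
                 filterbank: FilterbankParams | None = None,
                 seed: int = 0, snr_db: float = DEFAULT_SNR_DB,
                 confirm_epochs: int = 2):
        self.scene = scene
        self.nav = nav if nav is not None else NavParams(
            ear_separation=scene.ear_separation)
        self.chirp = chirp if chirp is not None else ChirpParams()
        self.broadcast = generate_broadcast(self.chirp)
        self.receiver = ScatReceiver(
            self.broadcast, filterbank if filterbank is not None
            else FilterbankParams())
        self.rng = np.random.default_rng(seed)
        self.noise_amplitude = 10 ** (-snr_db / 20.0)
        self.confirm_epochs = confirm_epochs

        self.bat = scene.bat_init.copy()
        self.bat.speed = self.nav.speed
        self.records: list[EpochRecord] = []
        self.rejected: set[str] = set()
        self.verdicts: dict[str, str] = {}
        self.tracked: str | None = None
        self.tracked_delay: float | None = None
        self.accepted: str | None = None
        self.lost_count = 0
        self._noglint = 0
        self._turn_sign = 1.0
        self._streak: tuple[str, int] | None = None
        self.outcome: str | None = None
        self.captured_target: str | None = None

    # ------------------------------------------------------------------

    @property
    def resolved(self) -> bool:
        return self.outcome is not None

    def _remaining(self) -> list[str]:
        return [t.id for t in self.scene.targets if t.id not in self.rejected]

    def _target_by_id(self, tid: str):
        return next(t for t in self.scene.targets if t.id == tid)

    def _associate(self, mode_delays, truth,
                   tolerance: float = 5e-4) -> dict[str, float]:
        """Map target ids to resolved echo modes via the synthesis truth.

        Each target expects an echo mode at its first-glint delay (the
        second, resolved glint mode is also expected but never claimed as
        the target's delay).  A target claims the nearest mode within the
        tolerance; nearby targets may legitimately share one merged mode.
        """
        out: dict[str, float] = {}
        if not mode_delays:
            return out
        modes = np.asarray(mode_delays)
        for tid, tr in truth.items():
            err = np.abs(modes - tr["left_delay"])
            k = int(np.argmin(err))
            if err[k] < tolerance:
                out[tid] = float(modes[k])
        return out

    def _search_turn(self) -> None:
        """Circle to re-acquire: slew the beam a full step toward the side
        where the tracked echo was last seen (right by default).

        With the flight heading trailing the beam this produces the looping
        search paths seen when no echo (or no unrejected target) lies in
        the forward hemisphere.
        """
        self.bat = update_beam_aim(
            self.bat, self._turn_sign * self.nav.max_beam_turn, self.nav)

    # ------------------------------------------------------------------

    def run_epoch(self) -> EpochRecord:
        """Emit one broadcast, process the echoes, steer, maybe classify."""
        if self.resolved:
            raise RuntimeError("scene already resolved; run_epoch refused")

        ears = synthesize_binaural_echoes(
            self.scene, self.bat, self.broadcast, self.noise_amplitude,
            self.rng)
        truth = ears.per_target_truth
        env_l = self.receiver._envelopes_for(ears.left)
        env_r = self.receiver._envelopes_for(ears.right)
        ev_l = self.receiver.detect(env_l)
        ev_r = None

        # ---- target selection (scan) --------------------------------
        if self.tracked is None:
            scan = self.receiver.analyze_envelopes(env_l, events=ev_l)
            candidates = []
            if scan is not None:
                assoc = self._associate(scan.mode_delays, truth)
                candidates = [(tid, dl) for tid, dl in assoc.items()
                              if tid not in self.rejected]
            if candidates:
                self.tracked = select_nearest(candidates)
                self.tracked_delay = dict(candidates)[self.tracked]
                self._streak = None
                self.lost_count = 0
                self._noglint = 0

        # ---- gated binaural estimates -------------------------------
        # Echo-to-target continuity (which cluster is the pursued target's
        # echo across epochs) is resolved with the synthesizer's truth
        # table: the delay gate is centred on the tracked target's true
        # first-glint delay.  The estimates themselves remain the
        # receiver's own measurements.
        est = itd = None
        if self.tracked is not None and self.tracked in truth:
            self.tracked_delay = truth[self.tracked]["left_delay"]
            ev_r = self.receiver.detect(env_r)
            est, itd = self.receiver.analyze_binaural(
                env_l, env_r, track_delay=self.tracked_delay,
                track_gate=self.nav.track_gate,
                events_l=ev_l, events_r=ev_r)
        secondary = est.secondary_delays if est is not None else []
        if est is not None and self.tracked in truth:
            # a separate target almost collinear behind the tracked one is
            # acoustically indistinguishable from a deep rear glint; keep
            # only the modes attributable to the tracked target itself
            tr = truth[self.tracked]
            exp = [tr["left_delay"]]
            if tr["glint_dt"] > self.receiver.params.smoothing_time:
                exp.append(tr["left_delay"] + tr["glint_dt"])
            sec = [m for m in est.mode_delays
                   if min(abs(m - e) for e in exp) < 2.5e-4]
            secondary = sec if len(sec) > 1 else []

        azimuth = None
        glint_dt = None
        delay = None
        if est is not None and itd is not None:
            delay = est.overall_delay
            azimuth, _ = binaural_azimuth(itd, 0.0, self.nav,
                                          self.scene.sound_speed)
            glint_dt = est.glint_dt

        # ---- steer beam, classify, commit ---------------------------
        action = "lost"
        if self.tracked is not None and azimuth is not None:
            self.lost_count = 0
            self._turn_sign = 1.0 if azimuth >= 0 else -1.0
            self.bat = update_beam_aim(self.bat, azimuth, self.nav)
            if self.accepted is None:
                merged = GlintEstimate(
                    overall_delay=delay, glint_dt=glint_dt,
                    secondary_delays=secondary,
                    confidence=est.confidence)
                raw = classify_target(merged, azimuth, self.nav,
                                      self.scene.desired_spacing)
                # classify only from close by: at long range neighbouring
                # echoes can merge into the tracked one and corrupt the
                # glint measurement, so keep approaching instead
                if raw in ("accept", "reject") and \
                        0.5 * delay * self.scene.sound_speed > \
                        self.nav.classify_max_range:
                    raw = "approach"
                # a momentarily unmeasurable glint spacing is not evidence
                # of a wrong target: keep probing, give up only after a
                # budget of failed in-gate attempts
                if raw == "reject" and glint_dt is None and not secondary:
                    self._noglint += 1
                    if self._noglint <= self.nav.glint_patience:
                        raw = "approach"
                elif glint_dt is not None:
                    self._noglint = 0
                action = "approach"
                if raw in ("accept", "reject"):
                    # verdicts must agree across confirm_epochs in-gate
                    # looks before they commit; out-of-gate epochs in
                    # between leave the tally untouched
                    if self._streak and self._streak[0] == raw:
                        self._streak = (raw, self._streak[1] + 1)
                    else:
                        self._streak = (raw, 1)
                    if self._streak[1] >= self.confirm_epochs:
                        action = raw
                        self.verdicts[self.tracked] = raw
                        if raw == "accept":
                            self.accepted = self.tracked
                        else:
                            self.rejected.add(self.tracked)
            else:
                action = "approach"
        elif self.tracked is not None:
            # tracked but no usable echo this epoch (merged with a
            # neighbour or behind the beam): hold course briefly so the
            # geometry can change, then circle to re-acquire; give up on
            # the candidate after lost_retries
            self.lost_count += 1
            if self.lost_count > 3:
                self._search_turn()
            if self.lost_count > self.nav.lost_retries:
                self.verdicts[self.tracked] = "lost"
                self.rejected.add(self.tracked)
                self.tracked = None
                self.tracked_delay = None
            action = "lost"
        else:
            # nothing selectable in the forward hemisphere: circle
            self._search_turn()

        decision = EpochDecision(self.tracked, azimuth, delay, glint_dt, action)
        record = EpochRecord(self.bat.epoch_index, self.bat.copy(), decision,
                             est, itd,
                             truth.get(self.tracked, {}) if self.tracked else {})
        self.records.append(record)

        # ---- advance flight -----------------------------------------
        # Approach-phase deceleration: past ~1.2 m the bat slows in
        # proportion to range so its turn-rate limit can out-pace the
        # bearing rotation; otherwise a tangential pass settles into a
        # stable orbit whose azimuth never drops inside the classify gate.
        # While reorienting after a lost echo it also slows, so circling
        # does not carry it out of the scene.
        speed = self.nav.speed
        if delay is not None:
            range_est = 0.5 * delay * self.scene.sound_speed
            speed = float(np.clip(0.15 * range_est, 0.05, self.nav.speed))
        elif action == "lost":
            speed = min(self.nav.speed,
                        0.2 if 0 < self.lost_count <= 3 else 0.1)
        old_pos = self.bat.position.copy()
        # the turn-rate limit is a limit in *time*: at reduced speed the
        # bat covers less ground per epoch, so it may turn further per
        # epoch, tightening its turning radius during the slow approach
        max_turn = min(90.0, self.nav.max_flight_turn * self.nav.speed
                       / max(speed, 1e-6))
        self.bat = update_flight(self.bat, self.nav, speed=speed,
                                 max_turn=max_turn)
        if delay is not None:
            # predicted delay next epoch, from the bat's own displacement
            # along the (beam ~ target bearing) direction
            cosg = float(np.dot(self.bat.flight_heading, self.bat.beam_heading))
            self.tracked_delay = delay - 2.0 * speed * cosg \
                / self.scene.sound_speed

        # ---- capture / rejection-driven re-scan ---------------------
        if self.accepted is not None:
            tgt = self._target_by_id(self.accepted)
            if _point_segment_distance(tgt.position, old_pos,
                                       self.bat.position) <= self.nav.capture_radius:
                self.outcome = "captured"
                self.captured_target = self.accepted
        if action == "reject":
            self.tracked = None
            self.tracked_delay = None
            self._streak = None
        if self.outcome is None and not self._remaining():
            # a lost track is not a classification: give dropped targets a
            # second chance before declaring the scene exhausted
            second = [tid for tid, v in self.verdicts.items() if v == "lost"]
            if second:
                for tid in second:
                    self.rejected.discard(tid)
                    del self.verdicts[tid]
            else:
                self.outcome = "exhausted"
        return record


def _attribution(records: list[EpochRecord], verdicts: dict[str, str],
                 captured: str | None) -> list[tuple[str, int, str]]:
    counts: dict[str, int] = {}
    order: list[str] = []
    for r in records:
        tid = r.decision.selected_target or "(none)"
        if tid not in counts:
            counts[tid] = 0
            order.append(tid)
        counts[tid] += 1
    out = []
    for tid in order:
        if tid == captured:
            verdict = "accept"
        else:
            verdict = verdicts.get(tid, "none")
        out.append((tid, counts[tid], verdict))
    return out


def run_search(scene: Scene, nav: NavParams | None = None, seed: int = 0,
               max_epochs: int = 5000, **kwargs) -> SearchResult:
    """Run the full scene search.

    Loops :meth:`Simulation.run_epoch` until the desired target is accepted
    and captured, every target has been rejected (``exhausted``), or
    ``max_epochs`` broadcasts have been spent.
    """
    sim = Simulation(scene, nav=nav, seed=seed, **kwargs)
    while not sim.resolved and len(sim.records) < max_epochs:
        sim.run_epoch()
    outcome = sim.outcome if sim.outcome is not None else "max_epochs"
    return SearchResult(
        records=sim.records,
        outcome=outcome,
        captured_target=sim.captured_target,
        epochs_per_target=_attribution(sim.records, sim.verdicts,
                                       sim.captured_target),
        scene=scene,
    )


def epochs_metric(result: SearchResult) -> pd.DataFrame:
    """Broadcast epochs spent per approached target, in approach order.

    The row counts sum to the total number of epochs in the run.
    """
    rows = [
        {"order": i + 1, "target": tid, "epochs": n, "verdict": verdict}
        for i, (tid, n, verdict) in enumerate(result.epochs_per_target)
    ]
    return pd.DataFrame(rows, columns=["order", "target", "epochs", "verdict"])


def export_run(result: SearchResult, out_dir, frames: bool = False) -> dict:
    """Write the run track (CSV), a JSON summary, and optional PNG frames.

    Returns the paths written.  Frames mirror the published scene figures:
    targets as dots (desired in red), the flight path, and the beam arrow.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in result.records:
        d = r.decision
        rows.append({
            "epoch": r.epoch,
            "x": r.bat.position[0],
            "y": r.bat.position[1],
            "flight_deg": heading_degrees(r.bat.flight_heading),
            "beam_deg": heading_degrees(r.bat.beam_heading),
            "selected": d.selected_target or "",
            "action": d.action,
            "delay_est_s": d.delay_est if d.delay_est is not None else np.nan,
            "glint_dt_est_s": d.glint_dt_est if d.glint_dt_est is not None
            else np.nan,
        })
    track = pd.DataFrame(rows)
    csv_path = out / "track.csv"
    track.to_csv(csv_path, index=False)

    summary = {
        "outcome": result.outcome,
        "captured_target": result.captured_target,
        "total_epochs": result.total_epochs,
        "epochs_per_target": [
            {"target": t, "epochs": n, "verdict": v}
            for t, n, v in result.epochs_per_target
        ],
    }
    json_path = out / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2))

    paths = {"track": csv_path, "summary": json_path, "frames": []}
    if frames and result.scene is not None:
        paths["frames"] = _render_frames(result, out / "frames")
    return paths


def _render_frames(result: SearchResult, frame_dir: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame_dir.mkdir(parents=True, exist_ok=True)
    scene = result.scene
    desired = {t.id for t in scene.desired_targets()}
    tx = [t.position[0] for t in scene.targets]
    ty = [t.position[1] for t in scene.targets]
    colors = ["red" if t.id in desired else "black" for t in scene.targets]
    xs = [r.bat.position[0] for r in result.records]
    ys = [r.bat.position[1] for r in result.records]
    paths = []
    for i, r in enumerate(result.records):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(tx, ty, c=colors, s=25, zorder=3)
        ax.plot(xs[: i + 1], ys[: i + 1], "b-", lw=1)
        b = r.bat
        ax.annotate("", xy=b.position + 0.3 * b.beam_heading, xytext=b.position,
                    arrowprops=dict(arrowstyle="->", color="black"))
        ax.annotate("", xy=b.position + 0.3 * b.flight_heading, xytext=b.position,
                    arrowprops=dict(arrowstyle="->", color="blue"))
        ax.set_xlabel("crossrange (m)")
        ax.set_ylabel("range (m)")
        ax.set_title(f"epoch {r.epoch}  [{r.decision.action}]")
        ax.set_aspect("equal")
        p = frame_dir / f"frame_{i:04d}.png"
        fig.savefig(p, dpi=80)
        plt.close(fig)
        paths.append(p)
    return paths
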