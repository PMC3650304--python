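"""Discrete-event simulation of the closed-loop virtual-reality paradigm.

A small moving target sweeps a peripheral zone of the visual field until the
(simulated) larva swims.  Threshold-crossing of the tail sensor triggers —
after an intrinsic detection latency — a fast translation of target and
background toward the visual-field center, emulating the retinal slip of an
orienting turn.  Paradigms:

``open_loop``
    no update; the trial ends with the first swim or times out (56 s).
``sequence`` / ``hold_until_swim_end``
    the target holds at the update location until the end of the swim, then
    resumes motion into the contralateral hemifield; an escalation schedule
    can grow size and velocity after each bout, emulating approach.
``delayed_reappearance``
    the stimulus hides on detection and reappears at the center exactly at
    ``swim_onset + update_delay``, then moves toward the periphery; the
    second swim ends the trial.

Timing measures follow the two-step paradigm conventions: the update delay
Delta-t and the inter-bout interval IBI are measured from the end of the
first swim, the reaction time RT from the onset of the second stimulus, so
``Delta-t = IBI - RT`` whenever all three are defined.

Stimulus azimuths are signed degrees, positive to the fish's right.  The
``update_location`` config value uses the undershoot/overshoot convention:
negative keeps the target short of the midline on the original side,
positive puts it beyond the midline.  Simulated time is continuous float
milliseconds (event-driven); optional 60 Hz display quantization is off by
default so logic stays separate from hardware artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "StimulusConfig",
    "TrialLog",
    "Event",
    "ResponderParams",
    "Responder",
    "responder_agent",
    "detect_swim_online",
    "run_trial",
    "run_grid",
    "measure_timing",
]


@dataclass
class StimulusConfig:
    zone: tuple[float, float] = (35.0, 55.0)       # deg, sweep interval
    target_size: float = 2.0                       # deg (width; height = width/2)
    target_velocity: float = 20.0                  # deg/s
    update_location: float = 0.0                   # deg, in [-10, +10]
    update_velocity: float = 400.0                 # deg/s
    update_delay_ms: float = 0.0                   # 0 or 100-500 (two-step)
    escalation: list[tuple[float, float]] | None = None   # (size, vel) per bout
    timeout_s: float = 56.0                        # no-response abort
    response_window_s: float = 60.0                # grid-probability interval
    detection_latency_ms: float = 40.0             # intrinsic loop delay
    sensor_fs: float = 1000.0
    paradigm: str = "sequence"
    max_bouts: int = 6
    refresh_hz: float | None = None                # optional display quantization

    def __post_init__(self) -> None:
        if abs(self.update_location) > 10.0:
            raise ValueError("update location must be within +/-10 deg")
        if not (0.0 <= self.zone[0] < self.zone[1] <= 90.0):
            raise ValueError("zone must lie within [0, 90] deg")
        if self.timeout_s <= 0:
            raise ValueError("timeout must be positive")
        if self.paradigm not in ("open_loop", "sequence",
                                 "hold_until_swim_end", "delayed_reappearance"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")


@dataclass
class Event:
    t_ms: float
    name: str
    payload: dict = field(default_factory=dict)


@dataclass
class TrialLog:
    events: list[Event] = field(default_factory=list)
    side: int = 1                                   # +1 right, -1 left
    per_bout_stimulus: list[tuple[float, float]] = field(default_factory=list)

    def log(self, t_ms: float, name: str, **payload) -> None:
        if self.events and t_ms < self.events[-1].t_ms - 1e-9:
            # keep the log time-ordered even when events are scheduled
            # out of order (e.g. reappearance before translation end)
            ev = Event(t_ms, name, payload)
            i = next(j for j, e in enumerate(self.events) if e.t_ms > t_ms + 1e-9)
            self.events.insert(i, ev)
            return
        self.events.append(Event(t_ms, name, payload))

    def times(self, name: str) -> list[float]:
        return [e.t_ms for e in self.events if e.name == name]

    def first(self, name: str) -> Event | None:
        return next((e for e in self.events if e.name == name), None)


# ---------------------------------------------------------------------------
# online swim detection
# ---------------------------------------------------------------------------

def detect_swim_online(
    voltage: np.ndarray,
    threshold: float,
    quiet_window_ms: float = 50.0,
    fs: float = 1000.0,
) -> list[tuple[float, float]]:
    """Causal swim detection on a sensor stream.

    Onset at the first sample with ``|V| >= threshold``; the swim ends when
    ``|V|`` stays below threshold continuously for ``quiet_window_ms`` (the
    end timestamp is the start of that quiet window).  Uses no future
    samples beyond the quiet window.
    """
    dt = 1000.0 / fs
    quiet_n = max(1, int(round(quiet_window_ms / dt)))
    events: list[tuple[float, float]] = []
    onset_i: int | None = None
    quiet = 0
    for i, v in enumerate(np.abs(np.asarray(voltage, dtype=float))):
        if v >= threshold:
            if onset_i is None:
                onset_i = i
            quiet = 0
        elif onset_i is not None:
            quiet += 1
            if quiet >= quiet_n:
                events.append((onset_i * dt, (i - quiet + 1) * dt))
                onset_i = None
                quiet = 0
    if onset_i is not None:
        events.append((onset_i * dt, len(voltage) * dt))
    return events


# ---------------------------------------------------------------------------
# responder agent
# ---------------------------------------------------------------------------

@dataclass
class ResponderParams:
    """Plug-in behavioral agent closing the loop.

    The reaction time to a stimulus onset is
    ``base_rt + location_penalty * |update location| + delay_penalty(|dt|)
    - size_velocity_gain * escalation - noise``-free or noisy; swims are
    directed toward the target.  ``response_prob`` may be a constant or a
    callable ``p(size_deg, velocity_deg_s)`` used in open-loop trials.
    """

    base_rt_ms: float = 420.0
    location_penalty_ms_per_deg: float = 15.0
    delay_penalty_ms_per_ms: float = 0.4       # on |Delta-t|
    size_velocity_gain_ms: float = 3.0         # per escalated deg + deg/s
    noise_sd_ms: float = 0.0
    refractory_ms: float = 100.0
    swim_duration_ms: float = 140.0
    response_prob: float | Callable[[float, float], float] = 1.0
    max_swims: int | None = None
    min_rt_ms: float = 50.0


class Responder:
    """Deterministic-friendly responder built from :class:`ResponderParams`."""

    def __init__(self, params: ResponderParams | None = None, **kw):
        self.params = params if params is not None else ResponderParams(**kw)

    def responds(self, size: float, velocity: float,
                 rng: np.random.Generator) -> bool:
        p = self.params.response_prob
        if callable(p):
            p = p(size, velocity)
        return bool(rng.random() < p)

    def reaction_time(
        self,
        rng: np.random.Generator,
        update_location: float = 0.0,
        dt_ms: float | None = None,
        size: float = 2.0,
        velocity: float = 20.0,
        base_size: float = 2.0,
        base_velocity: float = 20.0,
    ) -> float:
        p = self.params
        rt = p.base_rt_ms
        rt += p.location_penalty_ms_per_deg * abs(update_location)
        if dt_ms is not None:
            rt += p.delay_penalty_ms_per_ms * abs(dt_ms)
        rt -= p.size_velocity_gain_ms * ((size - base_size)
                                         + (velocity - base_velocity))
        if p.noise_sd_ms > 0:
            rt += rng.normal(0.0, p.noise_sd_ms)
        return max(p.min_rt_ms, rt)


def responder_agent(params: ResponderParams | None = None, **kw) -> Responder:
    """Factory for the plug-in agent (see :class:`ResponderParams`)."""
    return Responder(params, **kw)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def _quantize(t: float, cfg: StimulusConfig) -> float:
    if cfg.refresh_hz:
        period = 1000.0 / cfg.refresh_hz
        return round(t / period) * period
    return t


def run_trial(cfg: StimulusConfig, responder: Responder, seed: int = 0) -> TrialLog:
    """Run one closed-loop trial; every state transition is logged."""
    rng = np.random.default_rng(seed)
    log = TrialLog(side=1 if rng.integers(2) else -1)
    s = log.side
    timeout_ms = cfg.timeout_s * 1000.0
    size, vel = cfg.target_size, cfg.target_velocity
    base_size, base_vel = size, vel

    # initial sweep: target moves peripherally through the zone on side s
    pos0 = s * cfg.zone[0]
    sweep_dir = s  # toward the periphery
    log.log(0.0, "stimulus_on", position_deg=pos0, size_deg=size,
            velocity_deg_s=vel)
    t_appear = 0.0

    def pos_at(t: float, t_start: float, p_start: float, direction: int) -> float:
        span = cfg.zone[1] - cfg.zone[0]
        if span <= 0:
            return p_start
        # bounce inside the zone on side s during the initial sweep
        x = abs(p_start) - cfg.zone[0] + (t - t_start) / 1000.0 * vel
        x = x % (2 * span)
        x = span - abs(x - span)
        return np.sign(p_start) * (cfg.zone[0] + x) if p_start else x

    n_swims = 0
    update_loc_for_rt = 0.0
    dt_for_rt: float | None = None
    cur_pos = pos0
    cur_dir = sweep_dir
    first_sweep = True
    t_now = 0.0

    while True:
        if (responder.params.max_swims is not None
                and n_swims >= responder.params.max_swims):
            log.log(t_now, "trial_end", reason="responder_stopped")
            break
        if n_swims >= cfg.max_bouts:
            log.log(t_now, "trial_end", reason="max_bouts")
            break
        if not responder.responds(size, vel, rng):
            log.log(timeout_ms, "trial_end", reason="timeout")
            break
        rt = responder.reaction_time(
            rng, update_location=update_loc_for_rt, dt_ms=dt_for_rt,
            size=size, velocity=vel, base_size=base_size, base_velocity=base_vel,
        )
        onset = t_appear + rt
        if n_swims > 0:
            prev_end = log.times("swim_end")[-1]
            onset = max(onset, prev_end + responder.params.refractory_ms)
        if onset > timeout_ms:
            log.log(timeout_ms, "trial_end", reason="timeout")
            break

        swim_end = onset + responder.params.swim_duration_ms
        log.log(onset, "swim_onset", ordinal=n_swims)
        log.log(swim_end, "swim_end", ordinal=n_swims)
        log.per_bout_stimulus.append((size, vel))
        n_swims += 1
        t_now = swim_end

        if cfg.paradigm == "open_loop":
            log.log(swim_end, "trial_end", reason="response")
            break
        if cfg.paradigm == "delayed_reappearance" and n_swims >= 2:
            log.log(swim_end, "trial_end", reason="complete")
            break

        # closed loop: detection latency, then target+background translation
        det = onset + cfg.detection_latency_ms
        if first_sweep:
            p_det = pos_at(det, t_appear, cur_pos, cur_dir)
            first_sweep = False
        else:
            p_det = cur_pos + cur_dir * vel * (det - t_appear) / 1000.0
        target_pos = 0.0 if cfg.paradigm == "delayed_reappearance" \
            else -s * cfg.update_location
        trans_dur = abs(target_pos - p_det) / cfg.update_velocity * 1000.0
        log.log(det, "translation_start", from_deg=p_det, to_deg=target_pos)
        log.log(det + trans_dur, "translation_end", from_deg=p_det,
                to_deg=target_pos, duration_ms=trans_dur)

        if cfg.paradigm == "delayed_reappearance":
            # stimulus hides on detection; target and background translate
            # hidden, and the target reappears at the center exactly at
            # swim onset + configured delay
            log.log(det, "stimulus_hidden")
            reappear = _quantize(onset + cfg.update_delay_ms, cfg)
            log.log(reappear, "stimulus_reappear", position_deg=0.0,
                    size_deg=size, velocity_deg_s=vel)
            dt_for_rt = reappear - swim_end
            update_loc_for_rt = 0.0
            t_appear = reappear
            cur_pos, cur_dir = 0.0, -s
            t_now = max(t_now, reappear)
        else:
            # hold at the update location until the end of the swim,
            # then resume motion toward the contralateral hemifield
            resume = max(swim_end, det + trans_dur)
            if cfg.escalation and n_swims - 1 < len(cfg.escalation):
                size, vel = cfg.escalation[n_swims - 1]
            log.log(resume, "stimulus_resume", position_deg=target_pos,
                    size_deg=size, velocity_deg_s=vel)
            update_loc_for_rt = cfg.update_location
            dt_for_rt = resume - swim_end
            t_appear = resume
            cur_pos, cur_dir = target_pos, -s
            t_now = resume

    if not log.times("trial_end"):
        log.log(t_now, "trial_end", reason="complete")
    return log


def run_grid(
    sizes: list[float],
    velocities: list[float],
    trials_per_condition: int,
    responder: Responder,
    seed: int = 0,
    cfg: StimulusConfig | None = None,
):
    """Open-loop response-probability table over a size x velocity grid."""
    import pandas as pd

    if trials_per_condition <= 0:
        raise ValueError("need at least one trial per condition")
    base = cfg or StimulusConfig(paradigm="open_loop",
                                 zone=(30.0, 50.0))
    rows = []
    rng = np.random.default_rng(seed)
    for sz in sizes:
        for v in velocities:
            c = replace(base, target_size=sz, target_velocity=v,
                        paradigm="open_loop")
            n_resp = 0
            for _ in range(trials_per_condition):
                log = run_trial(c, responder, seed=int(rng.integers(0, 2**31 - 1)))
                if log.times("swim_onset"):
                    n_resp += 1
            rows.append({"size_deg": sz, "velocity_deg_s": v,
                         "n_trials": trials_per_condition,
                         "p_response": n_resp / trials_per_condition})
    return pd.DataFrame(rows)


def measure_timing(log: TrialLog) -> dict:
    """IBI, RT, and Delta-t from a trial log (None where undefined).

    IBI = onset of 2nd swim - end of 1st swim; RT = onset of 2nd swim -
    onset of 2nd stimulus (reappearance or resume); Delta-t = 2nd-stimulus
    onset - end of 1st swim (negative when the stimulus returns before the
    swim ends).
    """
    onsets = log.times("swim_onset")
    ends = log.times("swim_end")
    second_stim = (log.times("stimulus_reappear")
                   or log.times("stimulus_resume"))
    out = {"ibi_ms": None, "rt_ms": None, "dt_ms": None}
    if ends and second_stim:
        out["dt_ms"] = second_stim[0] - ends[0]
    if len(onsets) >= 2 and ends:
        out["ibi_ms"] = onsets[1] - ends[0]
        if second_stim:
            out["rt_ms"] = onsets[1] - second_stim[0]
    return out


def log_to_jsonl(log: TrialLog) -> str:
    """Serialize a TrialLog as JSON-lines (one event per line)."""
    import json

    lines = [json.dumps({"t_ms": e.t_ms, "event": e.name, **e.payload})
             for e in log.events]
    return "\n".join(lines) + "\n"
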