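"""Single-trial simulation and change-of-mind classification.

Outcome taxonomy (first chosen target vs final target):

* ``no_com`` — same target throughout.
* ``com_p`` — perceptual change of mind: opposite side, same colour
  (the diagonal switch; the colour intention is pursued).
* ``com_p_i`` — perceptual + intentional change of mind: opposite side
  *and* the alternative colour (the horizontal switch).
* ``vertical`` — same side, different colour; interpreted as the
  correction of an initial colour (target-selection) error.
* ``double_com`` — three or more distinct chosen actions; excluded
  from summary rates, mirroring the behavioural exclusion.

Classification is available both from threshold-crossing events
(simulated trials) and from the movement trajectory alone via the 10 %
x/y commitment criterion, which applies equally to empirical cursor
logs sampled at 125 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkParams
from .params import ParameterVector
from .task import TargetLayout, TaskParams, degrees_to_pixels, standard_layout
from .engine import simulate_trials

OUTCOMES = ("no_com", "com_p", "com_p_i", "vertical", "double_com")


@dataclass(frozen=True)
class TrialSpec:
    """Everything needed to reproduce one trial."""

    condition: str = "test"          # test | easy | conflict
    coh: float | None = None         # None: resolved from condition/parameters
    col: float | None = None
    direction: int = 0               # 0 left, 1 right
    chosen_colour: int = 0
    onset: float = 850.0             # stimulus onset, ms after trial start
    layout: TargetLayout = field(default_factory=standard_layout)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("test", "easy", "conflict"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.direction not in (0, 1) or self.chosen_colour not in (0, 1):
            raise ValueError("direction and chosen_colour must be 0 or 1")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")


@dataclass
class TrialResult:
    """Scalar outcome of one simulated trial plus its full trajectory."""

    first_choice: int
    final_choice: int
    events: list               # (time ms, target index) threshold crossings
    rt: float                  # stimulus onset -> movement initiation, ms
    mt: float                  # movement initiation -> target contact, ms
    outcome: str
    early: bool
    miss: bool
    perceptual_correct: bool
    colour_correct_initial: bool
    colour_correct_final: bool
    trajectory: np.ndarray     # (t ms, x px, y px) rows
    rates: np.ndarray          # per-ms firing-rate history, (steps, 12)


def detect_choice(
    action_rates,
    theta: float = 40.0,
    margin: float = 10.0,
    current_choice: int | None = None,
) -> int | None:
    """Winner-take-all readout of the four action rates.

    Returns the index of the action node at or above ``theta`` that
    exceeds every other action node by at least ``margin``; ``None`` when
    no node qualifies.  A returned node differing from ``current_choice``
    is a redirection event.  The mutual-margin requirement makes ties
    impossible: two nodes cannot each exceed the other by 10 Hz.
    """
    a = np.asarray(action_rates, dtype=float)
    if a.shape != (4,):
        raise ValueError("expected four action rates")
    top = int(np.argmax(a))
    rivals = np.delete(a, top)
    if a[top] >= theta and a[top] - rivals.max() >= margin:
        return top
    return None


def classify_trial(
    first_choice: int,
    final_choice: int,
    layout: TargetLayout,
    n_events: int = 1,
) -> str:
    """Outcome class from the (first, final) chosen-target pair."""
    for c in (first_choice, final_choice):
        if not 0 <= c <= 3:
            raise ValueError(f"choice {c} is not bound to a layout target")
    if n_events >= 3:
        return "double_com"
    if first_choice == final_choice:
        return "no_com"
    colours, sides = layout.colours, layout.sides
    same_side = sides[first_choice] == sides[final_choice]
    same_col = colours[first_choice] == colours[final_choice]
    if not same_side and same_col:
        return "com_p"
    if not same_side and not same_col:
        return "com_p_i"
    return "vertical"


def classify_trajectory(
    traj,
    layout: TargetLayout,
    px_per_deg: float = None,
    target_radius_deg: float = 0.9,
    commit_fraction: float = 0.1,
) -> str:
    """Classify a cursor trajectory by the 10 % commitment criterion.

    Commitment to a target is registered once the cursor has covered at
    least ``commit_fraction`` of both that target's x- and y-distance in
    its direction.  The first committed target and the target disc the
    trajectory ends in are then mapped exactly as :func:`classify_trial`.
    A trajectory ending outside every target disc is ``"unclassifiable"``.

    Works on simulated trajectories and on empirical cursor logs alike
    (rows of time, x, y in pixels; sampling rate is irrelevant).
    """
    from .task import PX_PER_DEG
    px_per_deg = PX_PER_DEG if px_per_deg is None else px_per_deg
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] < 3 or traj.shape[0] < 1:
        raise ValueError("trajectory must be rows of (t, x, y)")
    xy = traj[:, 1:3]
    tpos = layout.positions_px(px_per_deg)
    radius = float(degrees_to_pixels(target_radius_deg, px_per_deg))

    end = xy[-1]
    in_disc = np.linalg.norm(tpos - end, axis=1) <= radius
    if not in_disc.any():
        return "unclassifiable"
    final = int(np.argmax(in_disc))

    committed: list[int] = []
    thresh = commit_fraction * np.abs(tpos)  # (4, 2)
    for k in range(4):
        tx, ty = tpos[k]
        ok_x = xy[:, 0] * np.sign(tx) >= thresh[k, 0]
        ok_y = xy[:, 1] * np.sign(ty) >= thresh[k, 1]
        hits = np.nonzero(ok_x & ok_y)[0]
        if hits.size:
            committed.append((hits[0], k))
    if not committed:
        return "unclassifiable"
    committed.sort()
    first = committed[0][1]
    distinct = [first]
    for _, k in committed[1:]:
        if k != distinct[-1]:
            distinct.append(k)
    n_events = max(len(distinct), 1 + (final != first))
    return classify_trial(first, final, layout, n_events=n_events)


def simulate_movement(
    choice_events,
    layout: TargetLayout,
    speed: float = 0.7,
    motor_delay: float = 180.0,
    px_per_deg: float = None,
    dt: float = 1.0,
) -> np.ndarray:
    """Piecewise-linear cursor path from a stream of choice events.

    The cursor leaves the centre ``motor_delay`` ms after the first
    event, heads straight for the currently chosen target at constant
    ``speed`` and is re-aimed from its current position whenever a later
    event names a different target.  Deterministic: replaying the same
    event stream yields the identical trajectory.
    """
    from .task import PX_PER_DEG
    px_per_deg = PX_PER_DEG if px_per_deg is None else px_per_deg
    events = sorted((float(t), int(k)) for t, k in choice_events)
    if not events:
        raise ValueError("at least one choice event is required")
    tpos = layout.positions_px(px_per_deg)
    t0 = events[0][0] + motor_delay
    pos = np.zeros(2)
    samples = [(t0, pos[0], pos[1])]
    t = t0
    ev_idx = 0
    cur = events[0][1]
    while True:
        while ev_idx + 1 < len(events) and events[ev_idx + 1][0] <= t:
            ev_idx += 1
            cur = events[ev_idx][1]
        vec = tpos[cur] - pos
        dist = float(np.linalg.norm(vec))
        if dist <= 1e-9:
            break
        step_len = min(speed * dt, dist)
        pos = pos + vec / dist * step_len
        t += dt
        samples.append((t, pos[0], pos[1]))
        if step_len == dist and ev_idx + 1 >= len(events):
            break
    return np.asarray(samples)


def run_trial(
    spec: TrialSpec,
    pv: ParameterVector,
    net: NetworkParams | None = None,
    task: TaskParams | None = None,
) -> TrialResult:
    """Simulate one trial end to end and return its full result.

    The trial runs through the same vectorised engine as condition
    campaigns (batch of one), so single-trial and campaign results are
    bitwise consistent for a given seed.
    """
    pv_eff = pv
    if spec.coh is not None and spec.condition == "test":
        pv_eff = pv.replace(coh=spec.coh)
    if spec.col is not None:
        pv_eff = pv_eff.replace(col=spec.col)
    df = simulate_trials(
        pv_eff, 1, spec.condition, spec.layout,
        net=net, task=task, seed=spec.seed,
        directions=np.array([spec.direction]),
        chosen=np.array([spec.chosen_colour]),
        onsets=np.array([spec.onset]),
        record=True,
    )
    row = df.iloc[0]
    return TrialResult(
        first_choice=int(row.first_choice),
        final_choice=int(row.final_choice),
        events=list(row.events),
        rt=float(row.rt),
        mt=float(row.mt),
        outcome=str(row.outcome),
        early=bool(row.early),
        miss=bool(row.miss),
        perceptual_correct=bool(row.perceptual_correct),
        colour_correct_initial=bool(row.colour_correct_initial),
        colour_correct_final=bool(row.colour_correct_final),
        trajectory=row.trajectory,
        rates=row.rates,
    )
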