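"""Trial geometry, network wiring, and the three external input encoders.

A trial presents four reach targets, two of each of two colours, one on
each side of the screen per colour in the standard (diagonal) layouts, or
both same-colour targets on one side in the conflict layout.  Three
input streams drive the network:

* sensory drive: motion-coherence-weighted input to S1/S2, gated on
  200 ms after stimulus onset;
* intention drive: intention-strength-weighted input to I1/I2, active
  from trial start;
* cost drive: distance-proportional input to C1-C4, normalised so the
  four inputs always sum to four input units.

Each encoder is normalised so total external input is constant across
evidence levels — only relative evidence moves the competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    IDX_A,
    IDX_C,
    IDX_I1,
    IDX_I2,
    IDX_S1,
    IDX_S2,
    N_NODES,
    WeightMatrix,
)

#: Calibrated screen scale: chosen so a straight reach to the standard
#: 9.6-degree target lasts ~450 ms at the fixed 0.7 px/ms cursor speed.
PX_PER_DEG = 32.8

COLOUR_NAMES = ("blue", "green")
SIDE_NAMES = ("left", "right")


@dataclass(frozen=True)
class Target:
    """One reach target: screen position in degrees, colour and side."""

    x_deg: float
    y_deg: float
    colour: int  # 0 or 1
    side: int    # 0 = left, 1 = right

    def __post_init__(self) -> None:
        if self.colour not in (0, 1) or self.side not in (0, 1):
            raise ValueError("colour and side must be 0 or 1")
        if self.x_deg != 0 and (self.x_deg < 0) != (self.side == 0):
            raise ValueError("side flag must match the sign of x")


@dataclass(frozen=True)
class TargetLayout:
    """Four targets plus the layout family they belong to."""

    targets: tuple[Target, Target, Target, Target]
    family: str = "exp1-standard"

    def __post_init__(self) -> None:
        if len(self.targets) != 4:
            raise ValueError("a layout has exactly four targets")
        colours = [t.colour for t in self.targets]
        sides = [t.side for t in self.targets]
        if colours.count(0) != 2 or sides.count(0) != 2:
            raise ValueError("layout needs two targets per colour and per side")
        ecc = [np.hypot(t.x_deg, t.y_deg) for t in self.targets]
        if not np.allclose(ecc, ecc[0]):
            raise ValueError("all four targets must be equidistant from centre")

    def positions_px(self, px_per_deg: float = PX_PER_DEG) -> np.ndarray:
        """4x2 array of target positions in pixels."""
        return np.array(
            [[degrees_to_pixels(t.x_deg, px_per_deg),
              degrees_to_pixels(t.y_deg, px_per_deg)] for t in self.targets]
        )

    @property
    def colours(self) -> np.ndarray:
        return np.array([t.colour for t in self.targets], dtype=int)

    @property
    def sides(self) -> np.ndarray:
        return np.array([t.side for t in self.targets], dtype=int)


def _diagonal_layout(x: float, y: float, family: str) -> TargetLayout:
    # Same-colour targets diagonally opposite; node convention follows the
    # standard wiring diagram: A1 left-blue, A2 right-blue, A3 left-green,
    # A4 right-green.
    return TargetLayout(
        targets=(
            Target(-x, +y, colour=0, side=0),   # left-blue
            Target(+x, -y, colour=0, side=1),   # right-blue
            Target(-x, -y, colour=1, side=0),   # left-green
            Target(+x, +y, colour=1, side=1),   # right-green
        ),
        family=family,
    )


def standard_layout() -> TargetLayout:
    """Exp-1 geometry: targets at (+-6.0, +-7.5) degrees, 9.6 deg out."""
    return _diagonal_layout(6.0, 7.5, "exp1-standard")


def far_layout() -> TargetLayout:
    """Exp-2 horizontally far targets: (+-18, +-6) degrees."""
    return _diagonal_layout(18.0, 6.0, "exp2-far")


def close_layout() -> TargetLayout:
    """Exp-2 horizontally close targets: (+-6, +-18) degrees."""
    return _diagonal_layout(6.0, 18.0, "exp2-close")


def conflict_layout() -> TargetLayout:
    """Both targets of each colour on one side (blue right, green left)."""
    return TargetLayout(
        targets=(
            Target(+6.0, +7.5, colour=0, side=1),
            Target(+6.0, -7.5, colour=0, side=1),
            Target(-6.0, +7.5, colour=1, side=0),
            Target(-6.0, -7.5, colour=1, side=0),
        ),
        family="conflict",
    )


LAYOUT_FAMILIES = {
    "exp1-standard": standard_layout,
    "exp2-far": far_layout,
    "exp2-close": close_layout,
    "conflict": conflict_layout,
}


@dataclass(frozen=True)
class TaskParams:
    """Trial-level constants outside the network equations."""

    px_per_deg: float = PX_PER_DEG
    speed: float = 0.7                    # cursor speed, px/ms
    kappa: float = 0.1                    # cross-colour / same-colour action inhibition ratio
    cost_lateral: float = 0.0             # lateral inhibition among cost nodes (off by default)
    onset_min: float = 700.0              # stimulus onset window after trial start, ms
    onset_max: float = 1000.0
    deadline: float = 1000.0              # RT limit; slower trials are misses
    trial_cap: float = 3000.0             # hard cap on post-stimulus simulation, ms

    def __post_init__(self) -> None:
        if self.px_per_deg <= 0 or self.speed <= 0:
            raise ValueError("px_per_deg and speed must be positive")
        if not 0 <= self.kappa:
            raise ValueError("kappa must be non-negative")
        if self.onset_min > self.onset_max:
            raise ValueError("onset window inverted")


def degrees_to_pixels(pos_deg, px_per_deg: float = PX_PER_DEG):
    """Linear visual-degree to screen-pixel conversion."""
    if px_per_deg <= 0:
        raise ValueError("conversion constant must be positive")
    return np.asarray(pos_deg, dtype=float) * px_per_deg


def sensory_drive(
    coh: float,
    direction: int,
    t_since_stim_onset: float,
    f_in: float = 60.0,
    sensory_delay: float = 200.0,
) -> np.ndarray:
    """Inputs to (S1, S2) in Hz.

    Zero until the sensory delay has elapsed; thereafter
    ``f_in * (1 + coh/100)`` to the node preferring the true motion
    direction and ``f_in * (1 - coh/100)`` to the other, so the pair
    always sums to ``2 * f_in``.
    """
    if not 0 <= coh <= 100:
        raise ValueError("coherence must lie in [0, 100] %")
    if direction not in (0, 1):
        raise ValueError("direction must be 0 (left) or 1 (right)")
    if t_since_stim_onset < sensory_delay:
        return np.zeros(2)
    hi = f_in * (1 + coh / 100.0)
    lo = f_in * (1 - coh / 100.0)
    return np.array([hi, lo]) if direction == 0 else np.array([lo, hi])


def intention_drive(col: float, chosen_colour: int, f_in: float = 60.0) -> np.ndarray:
    """Inputs to (I1, I2) in Hz, active from trial start.

    ``f_in * (1 + col/100)`` to the chosen colour's node and
    ``f_in * (1 - col/100)`` to the other.
    """
    if not 0 <= col <= 100:
        raise ValueError("intention strength must lie in [0, 100] %")
    if chosen_colour not in (0, 1):
        raise ValueError("chosen_colour must be 0 or 1")
    hi = f_in * (1 + col / 100.0)
    lo = f_in * (1 - col / 100.0)
    return np.array([hi, lo]) if chosen_colour == 0 else np.array([lo, hi])


def cost_drive(distances, f_in: float = 60.0) -> np.ndarray:
    """Inputs to (C1..C4) in Hz: normalised distance shares.

    ``in_Ck = 4 * f_in * d_k / sum_j d_j`` — equal to ``f_in`` each while
    the cursor sits at the centre of an equidistant layout, and summing to
    ``4 * f_in`` for any cursor position, keeping total external input
    balanced as the cursor moves.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[-1] != 4:
        raise ValueError("expected four target distances")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    total = d.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cursor cannot coincide with all four targets")
    return 4.0 * f_in * d / total


def wire_network(layout: TargetLayout, pv, task: TaskParams | None = None) -> WeightMatrix:
    """Build the signed 12x12 weight matrix for one layout.

    Wiring rules: each intention node excites the two actions whose
    targets share its colour; each sensory node excites the two actions
    on its side; each cost node inhibits its own action, and the cost
    nodes of a colour inhibit that colour's intention node at half the
    cost->action magnitude; lateral inhibition within the I pair, the S
    pair and among actions (same-colour pairs at full magnitude,
    cross-colour pairs scaled by ``kappa``); sensory self-excitation on
    the diagonal.  ``pv`` provides the five connection magnitudes,
    ``task`` the ``kappa`` and ``cost_lateral`` switches.
    """
    task = task or TaskParams()
    return _wire(layout, pv.w_ia, pv.w_sa, pv.w_ca, pv.w_ss, pv.w_lat,
                 kappa=task.kappa, cost_lateral=task.cost_lateral)


def _wire(
    layout: TargetLayout,
    w_ia: float,
    w_sa: float,
    w_ca: float,
    w_ss: float,
    w_lat: float,
    kappa: float = 0.5,
    cost_lateral: float = 0.0,
) -> WeightMatrix:
    colours = layout.colours
    sides = layout.sides
    W = np.zeros((N_NODES, N_NODES))
    for k in range(4):
        a, c = IDX_A[k], IDX_C[k]
        i_node = IDX_I1 if colours[k] == 0 else IDX_I2
        s_node = IDX_S1 if sides[k] == 0 else IDX_S2
        W[a, i_node] = +w_ia
        W[a, s_node] = +w_sa
        W[a, c] = -w_ca
        W[i_node, c] = -0.5 * w_ca
    # Lateral inhibition within each competing pair.
    W[IDX_I1, IDX_I2] = W[IDX_I2, IDX_I1] = -w_lat
    W[IDX_S1, IDX_S2] = W[IDX_S2, IDX_S1] = -w_lat
    for k in range(4):
        for m in range(4):
            if k == m:
                continue
            scale = 1.0 if colours[k] == colours[m] else kappa
            W[IDX_A[k], IDX_A[m]] = -w_lat * scale
    if cost_lateral:
        for k in range(4):
            for m in range(4):
                if k != m:
                    W[IDX_C[k], IDX_C[m]] = -cost_lateral
    # Sensory self-excitation: temporal integration of motion evidence.
    W[IDX_S1, IDX_S1] = W[IDX_S2, IDX_S2] = +w_ss
    gov = np.where(colours == 0, 0, 1)
    return WeightMatrix(W=W, gov=gov)
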