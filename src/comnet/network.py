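"""Mean-field firing-rate dynamics of the 12-node attractor network.

The network couples two intention nodes (I1, I2: endogenous colour choice),
two sensory nodes (S1, S2: leftward/rightward motion evidence), four cost
nodes (C1-C4: distance-dependent motor cost of each reach target) and four
action nodes (A1-A4), one per reach target.  Firing rates are updated in
1 ms Euler-Maruyama steps: each node relaxes toward its total stimulation
(external drive plus weighted recurrent input) with time constant ``tau``,
then receives additive Gaussian noise and is clamped to [0, 100] Hz.

The hierarchy enters through the noise term: the variance of each action
node shrinks in proportion to the firing rate of the intention node that
governs it, so strong intentions stabilise the actions that serve them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical node ordering used throughout the package.
NODE_NAMES = (
    "I1", "I2", "S1", "S2",
    "C1", "C2", "C3", "C4",
    "A1", "A2", "A3", "A4",
)
N_NODES = 12
I_NODES = slice(0, 2)
S_NODES = slice(2, 4)
C_NODES = slice(4, 8)
A_NODES = slice(8, 12)
IDX_I1, IDX_I2, IDX_S1, IDX_S2 = 0, 1, 2, 3
IDX_C = (4, 5, 6, 7)
IDX_A = (8, 9, 10, 11)

#: Node roles that receive direct external drive (action nodes never do).
INPUT_ROLES = ("intention", "sensory", "cost")


def node_role(i: int) -> str:
    if i < 2:
        return "intention"
    if i < 4:
        return "sensory"
    if i < 8:
        return "cost"
    return "action"


@dataclass(frozen=True)
class NetworkParams:
    """Fixed constants of the firing-rate model.

    All rates in Hz, variances in Hz^2, times in ms.  Defaults are the
    model's published operating constants; ``nondecision`` must equal
    ``sensory_delay + motor_delay``.
    """

    tau: float = 100.0          # integration time constant
    sigma0_sq: float = 2.0      # baseline noise variance of every node
    h: float = 0.0              # hierarchical noise-control factor
    theta: float = 40.0         # action threshold
    margin: float = 10.0        # winner margin over all other action nodes
    f_in: float = 60.0          # external input rate unit
    sensory_delay: float = 200.0
    motor_delay: float = 180.0
    nondecision: float = 380.0
    r_init: float = 10.0
    r_min: float = 0.0
    r_max: float = 100.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma0_sq < 0:
            raise ValueError("sigma0_sq must be non-negative")
        if self.h < 0:
            raise ValueError("hierarchical noise factor h must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if min(self.sensory_delay, self.motor_delay) < 0:
            raise ValueError("delays must be non-negative")
        if self.nondecision != self.sensory_delay + self.motor_delay:
            raise ValueError("nondecision must equal sensory_delay + motor_delay")
        if self.r_min >= self.r_max:
            raise ValueError("r_min must be below r_max")


@dataclass
class WeightMatrix:
    """Signed 12x12 connection matrix ``W[target, source]`` plus the
    action->intention governance map used by the noise schedule.

    ``gov[k]`` is the index (0 or 1) of the intention node whose firing
    rate suppresses noise in action node ``A{k+1}``.
    """

    W: np.ndarray
    gov: np.ndarray = field(
        default_factory=lambda: np.array([0, 0, 1, 1], dtype=int)
    )

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.gov = np.asarray(self.gov, dtype=int)
        if self.W.shape != (N_NODES, N_NODES):
            raise ValueError(f"weight matrix must be {N_NODES}x{N_NODES}")
        if self.gov.shape != (4,) or not np.isin(self.gov, [0, 1]).all():
            raise ValueError("gov must map the 4 action nodes onto I1/I2")


@dataclass
class NetworkState:
    """Firing rates, per-node noise variances and clock at one time step."""

    t: float
    r: np.ndarray
    sigma_sq: np.ndarray

    @classmethod
    def initial(cls, params: NetworkParams) -> "NetworkState":
        return cls(
            t=0.0,
            r=np.full(N_NODES, params.r_init, dtype=float),
            sigma_sq=np.full(N_NODES, params.sigma0_sq, dtype=float),
        )

    def validate(self, params: NetworkParams) -> None:
        r = np.asarray(self.r, dtype=float)
        s2 = np.asarray(self.sigma_sq, dtype=float)
        if r.shape != (N_NODES,) or s2.shape != (N_NODES,):
            raise ValueError("state vectors must have 12 entries")
        if (r < params.r_min - 1e-12).any() or (r > params.r_max + 1e-12).any():
            raise ValueError("firing rates outside permitted bounds")
        if (s2 < 0).any():
            raise ValueError("noise variances must be non-negative")


def total_stimulation(
    r_prev: np.ndarray, weights: WeightMatrix, external: np.ndarray
) -> np.ndarray:
    """Total drive into every node: external input plus recurrent input.

    ``stim_i = in_i + sum_j r_j * W[i, j]`` with rates taken from the
    previous time step.
    """
    r_prev = np.asarray(r_prev, dtype=float)
    external = np.asarray(external, dtype=float)
    if r_prev.shape[-1] != N_NODES or external.shape[-1] != N_NODES:
        raise ValueError("rate and input vectors must have 12 entries")
    return external + r_prev @ weights.W.T


def rate_update(r_prev, stim, tau: float):
    """Deterministic Euler relaxation toward the stimulation level.

    One 1 ms step of ``dr = (stim - r) / tau``, before noise and clamping.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return r_prev + (np.asarray(stim, dtype=float) - r_prev) / tau


def noise_schedule(sigma0_sq: float, h: float, r_intention) -> np.ndarray:
    """Noise variance of action nodes under top-down intention control.

    ``sigma^2 = sigma0^2 - h * (r_I / 100) * sigma0^2``, floored at zero:
    an intention firing at its 100 Hz maximum with ``h = 1`` silences the
    noise of the two action nodes it governs.
    """
    if h < 0:
        raise ValueError("hierarchical noise factor h must be non-negative")
    r_intention = np.asarray(r_intention, dtype=float)
    out = sigma0_sq - h * (r_intention / 100.0) * sigma0_sq
    return np.maximum(out, 0.0)


def apply_noise(
    r,
    sigma_sq,
    rng: np.random.Generator,
    r_min: float = 0.0,
    r_max: float = 100.0,
):
    """Add zero-mean Gaussian noise of the given variance, then clamp."""
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    if (sigma_sq < 0).any():
        raise ValueError("noise variance must be non-negative")
    noisy = r + rng.standard_normal(np.shape(r)) * np.sqrt(sigma_sq)
    return np.clip(noisy, r_min, r_max)


def step(
    state: NetworkState,
    weights: WeightMatrix,
    external: np.ndarray,
    params: NetworkParams,
    rng: np.random.Generator,
) -> NetworkState:
    """Advance the network by one ``dt`` step.

    Composition per step: total stimulation from previous-step rates,
    Euler relaxation, the action-node noise schedule driven by the
    previous-step intention rates, additive Gaussian noise on every node
    and clamping to the permitted rate range.
    """
    state.validate(params)
    stim = total_stimulation(state.r, weights, external)
    r_new = rate_update(state.r, stim, params.tau)
    sigma_sq = np.full(N_NODES, params.sigma0_sq, dtype=float)
    sigma_sq[A_NODES] = noise_schedule(
        params.sigma0_sq, params.h, state.r[weights.gov]
    )
    r_new = apply_noise(r_new, sigma_sq, rng, params.r_min, params.r_max)
    return NetworkState(t=state.t + params.dt, r=r_new, sigma_sq=sigma_sq)
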