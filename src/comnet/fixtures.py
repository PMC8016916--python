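"""Canned test assets, generated programmatically.

Everything here is synthetic and hand-constructed: toy trajectories
exercising each change-of-mind class, a frozen weight matrix with
expected stimulation vectors computed by an explicit dot-product loop,
and a zero-noise trial specification with a known deterministic
outcome.
"""

from __future__ import annotations

import numpy as np

from .network import N_NODES, NetworkParams
from .params import ParameterVector
from .task import PX_PER_DEG, standard_layout
from .trial import TrialSpec, simulate_movement

#: Hand-picked, plausibly scaled parameters for deterministic fixtures
#: (not the reference fit; chosen for clear-cut zero-noise behaviour).
FIXTURE_PARAMS = ParameterVector(
    w_ia=0.35, w_sa=0.45, w_ca=0.20, w_ss=0.60, w_lat=0.40,
    coh=12.0, col=40.0, h=0.7,
)


def make_fixtures(seed: int = 0) -> dict:
    """Build the canned assets used across the test suite."""
    rng = np.random.default_rng(seed)
    layout = standard_layout()

    # (a) trajectories: event streams through the deterministic kinematics,
    # plus one path that ends outside every target disc.
    t0 = 1000.0
    trajectories = {
        "straight": simulate_movement([(t0, 0)], layout),
        "diagonal_switch": simulate_movement([(t0, 1), (t0 + 300, 0)], layout),
        "horizontal_switch": simulate_movement([(t0, 1), (t0 + 300, 2)], layout),
        "vertical_switch": simulate_movement([(t0, 0), (t0 + 300, 2)], layout),
        "double_switch": simulate_movement(
            [(t0, 1), (t0 + 260, 0), (t0 + 600, 2)], layout),
    }
    stray = np.array([[t0 + k, 0.3 * k, 0.1 * k] for k in range(120)])
    trajectories["unclassifiable"] = stray

    expected_classes = {
        "straight": "no_com",
        "diagonal_switch": "com_p",
        "horizontal_switch": "com_p_i",
        "vertical_switch": "vertical",
        "double_switch": "double_com",
        "unclassifiable": "unclassifiable",
    }

    # (b) a frozen weight matrix with expected stimulation from an
    # explicit elementwise oracle.
    from .task import wire_network
    weights = wire_network(layout, FIXTURE_PARAMS)
    rates = rng.uniform(0.0, 30.0, N_NODES)
    external = np.zeros(N_NODES)
    external[2] = 108.0
    external[4:8] = 60.0
    expected_stim = np.zeros(N_NODES)
    for i in range(N_NODES):
        acc = external[i]
        for j in range(N_NODES):
            acc += rates[j] * weights.W[i, j]
        expected_stim[i] = acc

    # (c) a zero-noise trial with a known deterministic outcome: an easy
    # leftward trial with a blue intention must end at left-blue with no
    # change of mind, identically on every run.
    zero_noise_net = NetworkParams(sigma0_sq=0.0, h=FIXTURE_PARAMS.h)
    zero_noise_spec = TrialSpec(
        condition="easy", direction=0, chosen_colour=0, onset=800.0, seed=0,
    )

    return {
        "layout": layout,
        "px_per_deg": PX_PER_DEG,
        "trajectories": trajectories,
        "expected_classes": expected_classes,
        "weights": weights,
        "rates": rates,
        "external": external,
        "expected_stim": expected_stim,
        "params": FIXTURE_PARAMS,
        "zero_noise_net": zero_noise_net,
        "zero_noise_spec": zero_noise_spec,
    }
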