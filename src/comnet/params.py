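"""The free parameters of the model and the shipped reference fit.

Eight quantities are calibrated against behaviour: five connection
strengths, the two evidence strengths (motion coherence and intention
strength) and the hierarchical noise-control factor.  Everything else in
the model is a fixed constant (see :class:`comnet.network.NetworkParams`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import yaml

PARAM_NAMES = ("w_ia", "w_sa", "w_ca", "w_ss", "w_lat", "coh", "col", "h")

#: Broad search bounds used by the fitting module: weights in [0, 2],
#: coherence in [2, 40] %, intention strength in [0, 100] %, h in [0, 1].
PARAM_BOUNDS = {
    "w_ia": (0.0, 2.0),
    "w_sa": (0.0, 2.0),
    "w_ca": (0.0, 2.0),
    "w_ss": (0.0, 2.0),
    "w_lat": (0.0, 2.0),
    "coh": (2.0, 40.0),
    "col": (0.0, 100.0),
    "h": (0.0, 1.0),
}


@dataclass(frozen=True)
class ParameterVector:
    """The eight fitted quantities of the model.

    Parameters
    ----------
    w_ia : intention -> action excitation (Hz per Hz).
    w_sa : sensory -> action excitation.
    w_ca : cost -> action inhibition magnitude; the cost -> intention
        inhibition is fixed at half this value.
    w_ss : sensory self-excitation (temporal integration of evidence).
    w_lat : lateral-inhibition magnitude within each competing pair.
    coh : test-trial motion coherence in %.
    col : endogenous intention strength in %.
    h : hierarchical noise-control factor; 1 means a maximally firing
        intention silences the noise of its action nodes.
    """

    w_ia: float
    w_sa: float
    w_ca: float
    w_ss: float
    w_lat: float
    coh: float
    col: float
    h: float

    def __post_init__(self) -> None:
        for name in ("w_ia", "w_sa", "w_ca", "w_ss", "w_lat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative (signs are "
                                 "applied by the wiring, not the magnitude)")
        if not 0 <= self.coh <= 100:
            raise ValueError("coh must lie in [0, 100] %")
        if not 0 <= self.col <= 100:
            raise ValueError("col must lie in [0, 100] %")
        if self.h < 0:
            raise ValueError("h must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, x.tolist())))

    def replace(self, **kw) -> "ParameterVector":
        vals = {f.name: getattr(self, f.name) for f in fields(self)}
        vals.update(kw)
        return ParameterVector(**vals)

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


def reference_parameters() -> ParameterVector:
    """The package's reference fit, produced by its own fitting run
    against the behavioural summary targets (see ``comnet.fitting``)."""
    text = resources.files("comnet").joinpath("data/reference_fit.yaml").read_text()
    raw = yaml.safe_load(text)
    return ParameterVector(**{n: float(raw[n]) for n in PARAM_NAMES})
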