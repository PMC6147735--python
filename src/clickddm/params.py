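"""Model parameters for the bounded evidence accumulator.

The accumulator value ``a(t)`` integrates right-minus-left click evidence.
Eleven parameters govern its dynamics and the mapping from its final value
to a choice:

==================  =============  ====================================================
field               units          meaning
==================  =============  ====================================================
lam                 1/s            memory drift: leak (lam < 0) or instability (lam > 0)
sigma2_a            clicks^2/s     diffusion variance of the accumulator per unit time
sigma2_s_ipsi       unitless       per-click noise variance, ipsilateral clicks
sigma2_s_contra     unitless       per-click noise variance, contralateral clicks
bound_B             clicks         sticky (absorbing) decision bound at |a| = B
phi                 unitless       per-click adaptation multiplier (depression < 1)
tau_phi             s              recovery time constant of adaptation
bias_thresh         clicks         decision borderline: choose right when a > thresh
lapse_total         fraction       kappa_C + kappa_I (total lapse)
lapse_biased        fraction       kappa_C - kappa_I (lateralized lapse)
input_gain          unitless       ipsilateral click weight g_w in [0, 1]; 0.5 balanced
==================  =============  ====================================================

"Ipsilateral"/"contralateral" are defined relative to a perturbed hemisphere
(see :class:`clickddm.stimuli.Session`); in the symmetric model the two
sensory-noise variances are equal, ``lapse_biased = 0`` and
``input_gain = 0.5``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "DEFAULT_BOUNDS", "INTERNAL_ORDER", "CANONICAL_ORDER"]

#: Order of the internal (fitting) coordinate vector.  The two lapse
#: components are carried as kappa_C, kappa_I (each naturally in [0, 1])
#: rather than total/biased, so that box bounds are exact.
INTERNAL_ORDER = (
    "lam",
    "sigma2_a",
    "sigma2_s_ipsi",
    "sigma2_s_contra",
    "bound_B",
    "phi",
    "tau_phi",
    "bias_thresh",
    "kappa_C",
    "kappa_I",
    "input_gain",
)

#: Order of the canonical parameter fields (as stored on ModelParams).
CANONICAL_ORDER = (
    "lam",
    "sigma2_a",
    "sigma2_s_ipsi",
    "sigma2_s_contra",
    "bound_B",
    "phi",
    "tau_phi",
    "bias_thresh",
    "lapse_total",
    "lapse_biased",
    "input_gain",
)

#: Default box bounds for the internal coordinates (used by the tanh
#: reparameterization during fitting).  Generous ranges chosen to cover
#: plausible fits for 40 Hz click stimuli.
DEFAULT_BOUNDS = {
    "lam": (-10.0, 10.0),
    "sigma2_a": (0.0, 200.0),
    "sigma2_s_ipsi": (0.0, 20.0),
    "sigma2_s_contra": (0.0, 20.0),
    "bound_B": (1.0, 30.0),
    "phi": (0.01, 1.5),
    "tau_phi": (0.005, 1.5),
    "bias_thresh": (-5.0, 5.0),
    "kappa_C": (0.0, 1.0),
    "kappa_I": (0.0, 1.0),
    "input_gain": (0.0, 1.0),
}


@dataclass
class ModelParams:
    lam: float = 0.0
    sigma2_a: float = 0.0
    sigma2_s_ipsi: float = 0.0
    sigma2_s_contra: float = 0.0
    bound_B: float = math.inf
    phi: float = 1.0
    tau_phi: float = 0.05
    bias_thresh: float = 0.0
    lapse_total: float = 0.0
    lapse_biased: float = 0.0
    input_gain: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    # -- derived lapse components -------------------------------------
    @property
    def kappa_C(self) -> float:
        """Fraction of model-contralateral categorizations converted to ipsi."""
        return 0.5 * (self.lapse_total + self.lapse_biased)

    @property
    def kappa_I(self) -> float:
        """Fraction of model-ipsilateral categorizations converted to contra."""
        return 0.5 * (self.lapse_total - self.lapse_biased)

    def validate(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_s_ipsi < 0 or self.sigma2_s_contra < 0:
            raise ValueError("noise variances must be nonnegative")
        if self.bound_B <= 0:
            raise ValueError("bound_B must be positive")
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")
        if self.phi < 0:
            raise ValueError("phi must be nonnegative")
        if not (0.0 <= self.kappa_C <= 1.0 and 0.0 <= self.kappa_I <= 1.0):
            raise ValueError(
                "derived lapse components kappa_C=(total+biased)/2 and "
                "kappa_I=(total-biased)/2 must each lie in [0, 1]"
            )
        if not (0.0 <= self.input_gain <= 1.0):
            raise ValueError("input_gain must lie in [0, 1]")

    # -- constructors --------------------------------------------------
    @classmethod
    def ideal(cls, bound_B: float = math.inf) -> "ModelParams":
        """Noise-free parameters for which a(T) = #right - #left exactly.

        The neutral values are lam = 0 (no drift) and phi = 1 (the per-click
        adaptation jump (phi - 1) C vanishes), with all noise, lapse and bias
        terms at zero and balanced input gain.
        """
        return cls(bound_B=bound_B)

    @classmethod
    def symmetric(
        cls,
        lam: float = 0.0,
        sigma2_a: float = 0.0,
        sigma2_s: float = 0.0,
        bound_B: float = math.inf,
        phi: float = 1.0,
        tau_phi: float = 0.05,
        bias_thresh: float = 0.0,
        lapse: float = 0.0,
    ) -> "ModelParams":
        """Left/right symmetric model: equal sensory noise, symmetric lapse,
        balanced gain.  ``lapse`` is the total lapse kappa = kappa_C + kappa_I."""
        return cls(
            lam=lam,
            sigma2_a=sigma2_a,
            sigma2_s_ipsi=sigma2_s,
            sigma2_s_contra=sigma2_s,
            bound_B=bound_B,
            phi=phi,
            tau_phi=tau_phi,
            bias_thresh=bias_thresh,
            lapse_total=lapse,
            lapse_biased=0.0,
            input_gain=0.5,
        )

    # -- vector conversions --------------------------------------------
    def internal_vector(self) -> np.ndarray:
        """11-vector in :data:`INTERNAL_ORDER` (lapse as kappa_C, kappa_I)."""
        return np.array(
            [
                self.lam,
                self.sigma2_a,
                self.sigma2_s_ipsi,
                self.sigma2_s_contra,
                self.bound_B,
                self.phi,
                self.tau_phi,
                self.bias_thresh,
                self.kappa_C,
                self.kappa_I,
                self.input_gain,
            ]
        )

    @classmethod
    def from_internal_vector(cls, v: np.ndarray) -> "ModelParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (11,):
            raise ValueError("expected an 11-vector")
        kC, kI = v[8], v[9]
        return cls(
            lam=v[0],
            sigma2_a=v[1],
            sigma2_s_ipsi=v[2],
            sigma2_s_contra=v[3],
            bound_B=v[4],
            phi=v[5],
            tau_phi=v[6],
            bias_thresh=v[7],
            lapse_total=kC + kI,
            lapse_biased=kC - kI,
            input_gain=v[10],
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(d[k]) for k in CANONICAL_ORDER})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)
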