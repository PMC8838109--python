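"""Motional models: order parameters from (and back to) geometry.

Three standard fast-motion models connect a C-H dipolar order parameter
to motional geometry:

* small-amplitude axially symmetric wobble, S = 1 - (3/2) <theta^2>,
  with theta the root-mean-square angular fluctuation;
* discrete N-site jumps, S = sum_ij p_i p_j P2(cos theta_ij) over the
  pairwise inter-orientation angles and equilibrium populations;
* fast uniaxial rotation, S = P2(cos beta) for a C-H vector at angle
  beta to the rotation axis (the classic -1/3 at the tetrahedral angle).

Angles are degrees at the interface and radians internally. A helper
classifies whether a motion is fast enough (tau_c below ~40 us) to
average one-bond dipolar couplings at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "WobbleModel",
    "JumpModel",
    "UniaxialModel",
    "wobble_S2",
    "wobble_angle",
    "jump_S2",
    "uniaxial_S",
    "classify_averaging",
    "p2",
]

#: default correlation-time threshold for dipolar averaging, s (~40 us)
AVERAGING_TAU_THRESHOLD = 4.0e-5

#: validity bound of the small-amplitude wobble expansion, degrees
WOBBLE_VALIDITY_DEG = 30.0


def p2(x):
    """Second Legendre polynomial P2(x) = (3 x^2 - 1) / 2."""
    x = np.asarray(x, dtype=float)
    out = 0.5 * (3.0 * x * x - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WobbleModel:
    """Small-amplitude wobble; theta_rms in degrees."""

    theta_rms: float

    def __post_init__(self):
        if self.theta_rms < 0:
            raise InvalidParameterError("theta_rms must be >= 0")
        if self.theta_rms > WOBBLE_VALIDITY_DEG:
            warnings.warn(
                f"theta_rms = {self.theta_rms:.1f} deg exceeds the small-amplitude "
                f"validity window ({WOBBLE_VALIDITY_DEG:.0f} deg)", stacklevel=3)

    @property
    def s2(self) -> float:
        return wobble_S2(self.theta_rms)


@dataclass(frozen=True)
class JumpModel:
    """N discrete orientations: populations p_i and pairwise angles (degrees)."""

    populations: tuple
    angles: tuple  # N x N symmetric matrix, theta_ii = 0

    def __post_init__(self):
        p = np.asarray(self.populations, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise InvalidParameterError("populations must be non-negative and sum to 1")
        if a.shape != (len(p), len(p)):
            raise InvalidParameterError("angle matrix must be N x N")
        if np.any(np.abs(np.diag(a)) > 1e-9):
            raise InvalidParameterError("diagonal inter-orientation angles must be 0")
        if np.any(np.abs(a - a.T) > 1e-9):
            raise InvalidParameterError("angle matrix must be symmetric")

    @classmethod
    def from_json(cls, path) -> "JumpModel":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["populations"]), tuple(map(tuple, d["angles"])))

    @property
    def s2(self) -> float:
        return jump_S2(self)


@dataclass(frozen=True)
class UniaxialModel:
    """Fast uniaxial rotation; beta = C-H vs axis angle, degrees."""

    beta: float

    def __post_init__(self):
        if not 0.0 <= self.beta <= 90.0:
            raise InvalidParameterError("beta must lie in [0, 90] degrees")

    @property
    def s(self) -> float:
        return uniaxial_S(self)


def wobble_S2(theta_rms_deg: float) -> float:
    """Order parameter of a small-amplitude wobble: 1 - (3/2) <theta^2>.

    theta_rms in degrees; results below 0 are floored at 0 with a warning
    (the expansion has left its validity window there anyway).
    """
    if theta_rms_deg < 0:
        raise InvalidParameterError("theta_rms must be >= 0")
    if theta_rms_deg > WOBBLE_VALIDITY_DEG:
        warnings.warn(
            f"theta_rms = {theta_rms_deg:.1f} deg exceeds the small-amplitude "
            f"validity window ({WOBBLE_VALIDITY_DEG:.0f} deg)", stacklevel=2)
    theta = math.radians(theta_rms_deg)
    s2 = 1.0 - 1.5 * theta * theta
    if s2 < 0.0:
        warnings.warn("wobble order parameter floored at 0", stacklevel=2)
        return 0.0
    return s2


def wobble_angle(s2: float) -> float:
    """Inverse of wobble_S2: theta_rms in degrees from an order parameter."""
    if not 0.0 < s2 <= 1.0:
        raise InvalidParameterError("S must lie in (0, 1]")
    theta = math.sqrt(2.0 * (1.0 - s2) / 3.0)
    return math.degrees(theta)


def jump_S2(model_or_populations, angles=None) -> float:
    """Order parameter of discrete N-site jumps.

    S = sum_{i,j} p_i p_j P2(cos theta_ij); accepts a JumpModel or
    (populations, angle matrix in degrees).
    """
    model = (model_or_populations if isinstance(model_or_populations, JumpModel)
             else JumpModel(tuple(model_or_populations), tuple(map(tuple, angles))))
    p = np.asarray(model.populations, dtype=float)
    theta = np.radians(np.asarray(model.angles, dtype=float))
    return float(p @ p2(np.cos(theta)) @ p)


def uniaxial_S(model_or_beta) -> float:
    """Fast uniaxial rotation average S = P2(cos beta); sign retained.

    |S| is what a (sign-blind) Pake splitting measures.
    """
    beta = (model_or_beta.beta if isinstance(model_or_beta, UniaxialModel)
            else UniaxialModel(float(model_or_beta)).beta)
    return p2(math.cos(math.radians(beta)))


def classify_averaging(tau_c: float,
                       threshold: float = AVERAGING_TAU_THRESHOLD) -> str:
    """'averaged' if tau_c < threshold (default 40 us), else 'static'.

    Motions faster than the inverse dipolar linewidth average one-bond
    C-H couplings; the boundary value itself counts as static.
    """
    if tau_c <= 0:
        raise InvalidParameterError("tau_c must be positive")
    return "averaged" if tau_c < threshold else "static"
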