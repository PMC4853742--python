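"""Transverse flow profile past a residue centred in the channel.

The flow between the molecular surface and the channel wall is modelled by a
parabolic (Poiseuille-like) profile in the proximal coordinate r_>: no slip
at the molecular surface (r_> = 0), no slip at the wall, and maximum bulk
speed exactly at r_b = (R - r_o)/2, halfway between surface and wall.  Only
the dimensionless ratio v(r_>)/v_bulk enters the effective-radius balance;
the bulk speed itself is a configuration parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CHANNEL_RADIUS_A, DEFAULT_V_BULK_M_PER_S

__all__ = ["VelocityProfile", "velocity_ratio"]


@dataclass(frozen=True)
class VelocityProfile:
    """Dimensionless transverse velocity ratio profile for one residue.

    ``r_o`` is the residue's mean surface radius, ``R`` the channel radius
    (both angstrom); the bulk point sits at ``r_b = (R - r_o) / 2`` from the
    surface.
    """

    r_o: float
    R: float = DEFAULT_CHANNEL_RADIUS_A
    v_bulk: float = DEFAULT_V_BULK_M_PER_S

    def __post_init__(self):
        if not (0.0 < self.r_o < self.R):
            raise ValueError("need 0 < r_o < R")
        if self.v_bulk <= 0:
            raise ValueError("v_bulk must be positive")

    @property
    def r_b(self) -> float:
        return (self.R - self.r_o) / 2.0

    def ratio(self, r_gt) -> np.ndarray | float:
        return velocity_ratio(self, r_gt)


def velocity_ratio(p: VelocityProfile, r_gt) -> np.ndarray | float:
    """v(r_>)/v_bulk: 1 - ((r - r_b)/r_b)^2 on [0, 2 r_b], clipped to [0, 1].

    Zero at the surface and beyond 2 r_b; exactly 1 at r_b.
    """
    r = np.asarray(r_gt, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_gt must be non-negative")
    ratio = 1.0 - ((r - p.r_b) / p.r_b) ** 2
    ratio = np.clip(ratio, 0.0, 1.0)
    ratio = np.where(r > 2.0 * p.r_b, 0.0, ratio)
    if np.isscalar(r_gt):
        return float(ratio)
    return ratio
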