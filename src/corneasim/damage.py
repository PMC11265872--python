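"""Keratoconus damage model.

Disease progression is represented as a prescribed, symmetric reduction of the
stiffness of the load-carrying elements, localized at the corneal apex.  The
damage fraction depends on the reference Y coordinate,

    D(Y) = Dmax * (1 - (Y / Ymax)^xi),

with even exponent ``xi`` controlling how flat the profile is near the centre
(larger ``xi`` keeps the damage near ``Dmax`` over a wider region).  Damage
reduces the lamellar (family 1) and diagonal (family 3) stiffness linearly,
``K -> (1 - D) K``; the radial crosslinks (family 2) are never damaged, since
their role is to keep the lamellae spaced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidDamageError

__all__ = ["DamageSpec", "damage_profile", "apply_damage"]


@dataclass(frozen=True)
class DamageSpec:
    """Parameters of the apex-centred damage profile.

    Attributes
    ----------
    Dmax : float
        Peak damage fraction at Y = 0, in [0, 1).
    xi : int
        Even localization exponent >= 2.
    Y_max : float
        Reference Y where the anterior surface meets the limbus
        (``R_A sin(Phi_star)``), same length unit as Y.
    """

    Dmax: float
    xi: int
    Y_max: float

    def __post_init__(self):
        if not (0.0 <= self.Dmax < 1.0):
            raise InvalidDamageError(f"Dmax must be in [0, 1), got {self.Dmax}")
        if self.xi < 2 or self.xi % 2 != 0:
            raise InvalidDamageError(f"xi must be an even integer >= 2, got {self.xi}")
        if self.Y_max <= 0:
            raise InvalidDamageError(f"Y_max must be positive, got {self.Y_max}")


def damage_profile(Y, spec: DamageSpec):
    """Damage fraction at reference coordinate(s) ``Y``.

    Points with ``|Y| > Y_max`` (outside the anterior chord) are clamped to
    zero damage with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    d = spec.Dmax * (1.0 - (Y / spec.Y_max) ** spec.xi)
    if np.any(d < 0):
        warnings.warn(
            "damage profile evaluated outside |Y| <= Y_max; clamping to zero",
            stacklevel=2,
        )
        d = np.clip(d, 0.0, None)
    if d.ndim == 0:
        return float(d)
    return d


def apply_damage(K1, K3, d):
    """Reduce lamellar and diagonal stiffness by the damage fraction ``d``.

    Returns ``((1-d)*K1, (1-d)*K3)``.  The radial stiffness K2 is deliberately
    not an argument: it is never modified.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d >= 1):
        raise InvalidDamageError("damage fraction must lie in [0, 1)")
    if d.ndim == 0:
        d = float(d)
    return (1.0 - d) * K1, (1.0 - d) * K3
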