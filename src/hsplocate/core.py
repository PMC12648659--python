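"""Hansen and Hildebrand solubility-parameter arithmetic.

Hansen solubility parameters (HSPs) locate a substance at a point
(δD, δP, δH) in a 3D "Hansen space", splitting the cohesive energy density
into dispersion, dipolar and hydrogen-bonding contributions, each in
MPa^1/2. Affinity between two substances is measured by the Hansen
distance

    R = sqrt(4·(ΔδD)² + (ΔδP)² + (ΔδH)²),

an anisotropic Euclidean distance whose dispersion axis is weighted by 4
(equivalently, doubled before taking an ordinary Euclidean norm — see
:func:`to_scaled_space`). Smaller R means better solvent–solute
compatibility. The Hildebrand total parameter δT collapses the three
components into one: δT² = δD² + δP² + δH².

This module is the metric layer shared by the database, the locator and the
reporting code. All quantities are in MPa^1/2; no unit conversion is
performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence, Union

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "HspVector",
    "NegativeComponentWarning",
    "hansen_distance",
    "component_deltas",
    "hildebrand_total",
    "hildebrand_delta",
    "to_scaled_space",
    "HANSEN_SCALE",
]

#: Per-axis scaling that turns the Hansen distance into a plain Euclidean
#: norm: doubling δD accounts for the factor 4 under the square root.
HANSEN_SCALE = np.array([2.0, 1.0, 1.0])


class NegativeComponentWarning(UserWarning):
    """A Hansen component is negative.

    Physically meaningless for a real substance, but tolerated (with this
    warning) so intermediate constructions in synthetic tests can exist;
    database validation treats it as an error.
    """


@dataclass(frozen=True)
class HspVector:
    """A point in Hansen space: (δD, δP, δH) in MPa^1/2.

    Components must be finite. Negative components warn rather than raise
    (see :class:`NegativeComponentWarning`).
    """

    dD: float
    dP: float
    dH: float

    def __post_init__(self) -> None:
        for name in ("dD", "dP", "dH"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise InvalidInputError(f"HSP component {name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)
        if min(self.dD, self.dP, self.dH) < 0.0:
            warnings.warn(
                f"negative Hansen component in ({self.dD}, {self.dP}, {self.dH})",
                NegativeComponentWarning,
                stacklevel=2,
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.dD, self.dP, self.dH])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "HspVector":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,):
            raise InvalidInputError(f"expected 3 components, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def __iter__(self) -> Iterator[float]:
        yield self.dD
        yield self.dP
        yield self.dH


HspLike = Union[HspVector, Sequence[float]]


def as_hsp(x: HspLike) -> HspVector:
    """Coerce a 3-sequence to :class:`HspVector`, validating on the way."""
    if isinstance(x, HspVector):
        return x
    return HspVector.from_array(x)


def hansen_distance(a: HspLike, b: HspLike) -> float:
    """Hansen distance R between two points, MPa^1/2.

    R = sqrt(4·(a.dD − b.dD)² + (a.dP − b.dP)² + (a.dH − b.dH)²); symmetric,
    non-negative, zero iff the points coincide. The factor 4 reflects the
    empirical observation that mismatch in dispersion interactions
    discriminates solvents twice as strongly per MPa^1/2 as the other axes.
    """
    a = as_hsp(a)
    b = as_hsp(b)
    return math.sqrt(
        4.0 * (a.dD - b.dD) ** 2 + (a.dP - b.dP) ** 2 + (a.dH - b.dH) ** 2
    )


def component_deltas(a: HspLike, b: HspLike) -> tuple[float, float, float]:
    """Per-axis absolute differences (ΔδD, ΔδP, ΔδH), MPa^1/2 each.

    The decomposition of R used to reason about *which* interaction
    (dispersion, dipolar, hydrogen bonding) drives an affinity mismatch.
    """
    a = as_hsp(a)
    b = as_hsp(b)
    return (abs(a.dD - b.dD), abs(a.dP - b.dP), abs(a.dH - b.dH))


def hildebrand_total(h: HspLike) -> float:
    """Hildebrand total solubility parameter δT = sqrt(δD² + δP² + δH²)."""
    h = as_hsp(h)
    return math.sqrt(h.dD**2 + h.dP**2 + h.dH**2)


def hildebrand_delta(dT1: float, dT2: float) -> float:
    """Absolute Hildebrand difference |δT(1) − δT(2)|, MPa^1/2."""
    for v in (dT1, dT2):
        if not math.isfinite(v):
            raise InvalidInputError(f"Hildebrand parameter must be finite, got {v!r}")
        if v < 0:
            raise InvalidInputError(f"Hildebrand parameter must be non-negative, got {v!r}")
    return abs(float(dT1) - float(dT2))


def to_scaled_space(h: HspLike) -> np.ndarray:
    """Map (δD, δP, δH) to (2δD, δP, δH).

    An isometry from Hansen geometry to ordinary Euclidean geometry: the
    Euclidean distance between mapped points equals the Hansen distance of
    the originals exactly. Useful for convex-hull and median arguments that
    assume a genuine norm.
    """
    return as_hsp(h).as_array() * HANSEN_SCALE
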