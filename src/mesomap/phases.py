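"""Mesophase reflection libraries and lattice-parameter rules.

Each lyotropic liquid-crystalline phase relevant to SPC/GDO depots is
described by the ratios of its allowed Bragg reflections to the first
reflection, together with the rule mapping the first-reflection position
q1 to a lattice parameter:

* ``Fd3m``  — reverse micellar cubic (face-centred); reflections
  (111), (220), (311), (222), (400), (331), (422), (511)/(333), i.e.
  spacing ratios sqrt(3, 8, 11, 12, 16, 19, 24, 27)/sqrt(3);
  a = 2*pi*sqrt(3)/q111.
* ``Pm3n``  — primitive micellar cubic; (110), (200), (210), (211),
  (220), (310): sqrt(2, 4, 5, 6, 8, 10)/sqrt(2); a = 2*pi*sqrt(2)/q110.
* ``H2``    — reverse hexagonal; (10), (11), (20), (21): 1, sqrt(3), 2,
  sqrt(7); a = 4*pi/(sqrt(3)*q10).
* ``lamellar`` — 1, 2, 3; d = 2*pi/q1.
* ``isotropic`` — the L2 reverse micellar liquid; no reflections (a
  classification fallback, never a fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PhasePattern",
    "PHASE_LIBRARY",
    "get_phase",
    "cubic_q",
    "FD3M_HKL",
    "FD3M_WINDOW",
]

#: Miller indices of the allowed Fd3m reflections tracked here.
FD3M_HKL: tuple[tuple[int, int, int], ...] = (
    (1, 1, 1), (2, 2, 0), (3, 1, 1), (2, 2, 2),
    (4, 0, 0), (3, 3, 1), (4, 2, 2), (5, 1, 1),
)

#: Search window (in 1/Angstrom) for the Fd3m (111) reflection.  The
#: highest peak inside this interval is taken as (111).
FD3M_WINDOW: tuple[float, float] = (0.058, 0.085)


def cubic_q(a: float, hkl: Sequence[int]) -> float:
    """Position of a cubic reflection, q = 2*pi*sqrt(h^2+k^2+l^2)/a."""
    h, k, l = hkl
    return 2.0 * math.pi * math.sqrt(h * h + k * k + l * l) / a


@dataclass(frozen=True)
class PhasePattern:
    """Reflection-ratio table and lattice rule for one mesophase.

    ``reflection_ratios`` are q_i/q_1 starting at exactly 1.0 and
    strictly increasing; ``labels`` name the corresponding (hkl) / (hk)
    planes.  ``lattice_from_q1`` maps the observed first-reflection
    position (1/Angstrom) to a lattice parameter (Angstrom); ``q1_from_
    lattice`` is its inverse, used by the forward simulator.
    """

    name: str
    reflection_ratios: tuple[float, ...]
    labels: tuple[str, ...]
    lattice_from_q1: Optional[Callable[[float], float]] = field(
        default=None, repr=False)
    q1_from_lattice: Optional[Callable[[float], float]] = field(
        default=None, repr=False)

    def __post_init__(self) -> None:
        r = self.reflection_ratios
        if r:
            if abs(r[0] - 1.0) > 1e-12:
                raise ValueError(f"{self.name}: ratios must start at 1")
            if np.any(np.diff(r) <= 0):
                raise ValueError(f"{self.name}: ratios must increase")
            if len(r) != len(self.labels):
                raise ValueError(f"{self.name}: labels/ratios mismatch")

    @property
    def has_reflections(self) -> bool:
        return len(self.reflection_ratios) > 0

    def peak_positions(self, lattice: float) -> np.ndarray:
        """All reflection positions (1/Angstrom) for a given lattice."""
        if not self.has_reflections:
            return np.empty(0)
        q1 = self.q1_from_lattice(lattice)
        return q1 * np.asarray(self.reflection_ratios)


def _sqrt_ratios(ns: Sequence[int]) -> tuple[float, ...]:
    n0 = ns[0]
    return tuple(math.sqrt(n / n0) for n in ns)


_FD3M = PhasePattern(
    name="Fd3m",
    reflection_ratios=_sqrt_ratios([3, 8, 11, 12, 16, 19, 24, 27]),
    labels=("111", "220", "311", "222", "400", "331", "422", "511"),
    lattice_from_q1=lambda q1: 2.0 * math.pi * math.sqrt(3.0) / q1,
    q1_from_lattice=lambda a: 2.0 * math.pi * math.sqrt(3.0) / a,
)

_PM3N = PhasePattern(
    name="Pm3n",
    reflection_ratios=_sqrt_ratios([2, 4, 5, 6, 8, 10]),
    labels=("110", "200", "210", "211", "220", "310"),
    lattice_from_q1=lambda q1: 2.0 * math.pi * math.sqrt(2.0) / q1,
    q1_from_lattice=lambda a: 2.0 * math.pi * math.sqrt(2.0) / a,
)

_H2 = PhasePattern(
    name="H2",
    reflection_ratios=(1.0, math.sqrt(3.0), 2.0, math.sqrt(7.0)),
    labels=("10", "11", "20", "21"),
    lattice_from_q1=lambda q1: 4.0 * math.pi / (math.sqrt(3.0) * q1),
    q1_from_lattice=lambda a: 4.0 * math.pi / (math.sqrt(3.0) * a),
)

_LAM = PhasePattern(
    name="lamellar",
    reflection_ratios=(1.0, 2.0, 3.0),
    labels=("001", "002", "003"),
    lattice_from_q1=lambda q1: 2.0 * math.pi / q1,
    q1_from_lattice=lambda d: 2.0 * math.pi / d,
)

_ISO = PhasePattern(name="isotropic", reflection_ratios=(), labels=())

#: Library order also sets the tie-break order during indexing.
PHASE_LIBRARY: tuple[PhasePattern, ...] = (_FD3M, _PM3N, _H2, _LAM, _ISO)

_BY_NAME = {p.name: p for p in PHASE_LIBRARY}


def get_phase(name: str) -> PhasePattern:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown phase {name!r}; known: {sorted(_BY_NAME)}") from None
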