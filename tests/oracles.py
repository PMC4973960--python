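"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the encoder oracle
works in 50-digit decimal arithmetic straight from the defining formulas,
the distance oracles come from closed-form geometry identities.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal, getcontext

getcontext().prec = 50

_SQRT2 = Decimal(2).sqrt()
_LAM = Decimal(360)


def _nint(x: Decimal) -> int:
    """Nearest integer, ties away from zero (inputs here are non-negative)."""
    return int(x.to_integral_value(rounding=ROUND_HALF_UP))


def grid_oracle(sigma) -> tuple[int, int, int]:
    """(lam_prime, rz_min, rz_max) in extended precision."""
    sig = Decimal(repr(float(sigma)))
    lam_prime = _nint(_SQRT2 * _LAM * sig)
    rz_min = _nint(_LAM * sig / _SQRT2)
    return lam_prime, rz_min, rz_min + lam_prime * lam_prime


def encode_oracle(phi: float, psi: float, sigma) -> int:
    """Integer Ramachandran number via brute-force decimal evaluation."""
    lam_prime, rz_min, rz_max = grid_oracle(sigma)
    sig = Decimal(repr(float(sigma)))
    wa = Decimal(repr((float(phi) + 180.0) % 360.0 - 180.0))
    wb = Decimal(repr((float(psi) + 180.0) % 360.0 - 180.0))
    x = (wa - wb + _LAM) * sig / _SQRT2
    y = (wa + wb + _LAM) * sig / _SQRT2
    rz = _nint(x) + lam_prime * _nint(y)
    return min(max(rz, rz_min), rz_max)


def one_four_distance(r12, r23, r34, theta123, theta234, torsion) -> float:
    """Closed-form 1-4 distance of a 4-atom chain (angles in degrees)."""
    t2 = math.radians(theta123)
    t3 = math.radians(theta234)
    tau = math.radians(torsion)
    d2 = (
        r12 * r12
        + r23 * r23
        + r34 * r34
        - 2 * r12 * r23 * math.cos(t2)
        - 2 * r23 * r34 * math.cos(t3)
        + 2 * r12 * r34 * (math.cos(t2) * math.cos(t3) - math.sin(t2) * math.sin(t3) * math.cos(tau))
    )
    return math.sqrt(d2)


def rg_double_loop(points) -> float:
    """Radius of gyration via the pairwise-distance identity (O(N^2) brute force)."""
    n = len(points)
    total = 0.0
    for i in range(n):
        for j in range(n):
            dx = points[i][0] - points[j][0]
            dy = points[i][1] - points[j][1]
            dz = points[i][2] - points[j][2]
            total += dx * dx + dy * dy + dz * dz
    return math.sqrt(total / (2.0 * n * n))
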