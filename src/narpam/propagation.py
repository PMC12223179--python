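"""Sonar-equation utilities: seawater absorption, transmission loss, detection range.

The maximum range at which a narwhal echolocation click can be retained by
the detector is the range ``r`` at which the received level drops to the
retention threshold::

    SL - TL(r) = RL_threshold,   TL(r) = 20 log10(r) + alpha * r/1000

with spherical spreading and a frequency-dependent absorption coefficient
``alpha`` (dB/km).  Absorption follows the Ainslie & McColm (1998)
simplification of the Francois-Garrison model: a boric-acid term, a
magnesium-sulfate term, and a pure-water viscosity term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "PropagationParams",
    "absorption_db_per_km",
    "transmission_loss",
    "max_detection_range",
]


@dataclass(frozen=True)
class PropagationParams:
    """Inputs to the click detection-range calculation.

    Defaults are the study-site conditions: a 215 dB_pp click source level,
    the 120 dB_pp retention threshold, 20 kHz propagation frequency, and the
    deployment-depth water properties (1 degC, 35 PSU, pH 8, 660 m).
    """

    source_level_db_pp: float = 215.0
    threshold_db_pp: float = 120.0
    freq_khz: float = 20.0
    temp_c: float = 1.0
    salinity_psu: float = 35.0
    ph: float = 8.0
    depth_m: float = 660.0

    def __post_init__(self) -> None:
        if not self.source_level_db_pp > self.threshold_db_pp:
            raise ValueError("source level must exceed the detection threshold")
        if not self.freq_khz > 0:
            raise ValueError("freq_khz must be positive")


def absorption_db_per_km(
    freq_khz: float,
    temp_c: float = 1.0,
    salinity_psu: float = 35.0,
    ph: float = 8.0,
    depth_m: float = 660.0,
) -> float:
    """Seawater sound absorption coefficient in dB/km (Ainslie & McColm 1998).

    Three additive contributions, each a relaxation (or viscous) term:

    * boric acid:       ``0.106 * f1 f^2/(f1^2+f^2) * exp((pH-8)/0.56)``
    * magnesium sulfate:``0.52 (1+T/43)(S/35) * f2 f^2/(f2^2+f^2) * exp(-D/6)``
    * pure water:       ``0.00049 f^2 * exp(-(T/27 + D/17))``

    with relaxation frequencies ``f1 = 0.78 sqrt(S/35) exp(T/26)`` and
    ``f2 = 42 exp(T/17)`` (kHz), temperature ``T`` in degC, salinity ``S``
    in PSU, and depth ``D`` in km.

    Parameters are validated against the physically plausible ranges of the
    parametrisation; out-of-range input raises ``ValueError`` naming the
    offending parameter.
    """
    if not 0 < freq_khz <= 1000:
        raise ValueError(f"freq_khz={freq_khz} outside (0, 1000]")
    if not -2 <= temp_c <= 30:
        raise ValueError(f"temp_c={temp_c} outside [-2, 30]")
    if not 0 <= salinity_psu <= 45:
        raise ValueError(f"salinity_psu={salinity_psu} outside [0, 45]")
    if not 7 <= ph <= 9:
        raise ValueError(f"ph={ph} outside [7, 9]")
    if not 0 <= depth_m <= 11_000:
        raise ValueError(f"depth_m={depth_m} outside [0, 11000]")

    f = freq_khz
    t = temp_c
    s = salinity_psu
    d_km = depth_m / 1000.0

    f1 = 0.78 * math.sqrt(s / 35.0) * math.exp(t / 26.0)
    f2 = 42.0 * math.exp(t / 17.0)

    boric = 0.106 * (f1 * f**2) / (f1**2 + f**2) * math.exp((ph - 8.0) / 0.56)
    mgso4 = (
        0.52
        * (1.0 + t / 43.0)
        * (s / 35.0)
        * (f2 * f**2)
        / (f2**2 + f**2)
        * math.exp(-d_km / 6.0)
    )
    water = 0.00049 * f**2 * math.exp(-(t / 27.0 + d_km / 17.0))
    return boric + mgso4 + water


def transmission_loss(range_m: float, alpha_db_per_km: float) -> float:
    """One-way transmission loss: spherical spreading plus absorption.

    ``TL = 20 log10(r) + alpha * r/1000`` in dB re the level at 1 m.
    """
    if range_m <= 0:
        raise ValueError("range_m must be positive")
    return 20.0 * math.log10(range_m) + alpha_db_per_km * range_m / 1000.0


def max_detection_range(params: PropagationParams) -> float:
    """Range in metres at which the received level equals the threshold.

    Solves ``SL - TL(r) = threshold`` by bracketed root-finding to 1 m
    tolerance.  TL is strictly increasing in range, so the root is unique.
    """
    alpha = absorption_db_per_km(
        params.freq_khz, params.temp_c, params.salinity_psu, params.ph, params.depth_m
    )
    budget = params.source_level_db_pp - params.threshold_db_pp

    def excess(r_m: float) -> float:
        return budget - transmission_loss(r_m, alpha)

    lo, hi = 1.0, 1.0e7
    if excess(lo) <= 0:
        raise ValueError("threshold reached inside 1 m; no physical bracket")
    return float(brentq(excess, lo, hi, xtol=1.0))
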