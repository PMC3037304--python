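"""Reporting-precision helpers.

Survey tables round percentages half away from zero, except the SSR/EST
frequency column, which truncates (see docs/methods.md); both live here so
every table uses the same convention.
"""

import math

_EPS = 1e-9  # guards against float noise just below a .5 or integer boundary


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (12.345 -> 12.35, -0.5 -> -1)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5 + _EPS), x) / scale


def round_int_half_away(x: float) -> int:
    return int(round_half_away(x, 0))


def trunc2(x: float) -> float:
    """Truncate toward zero at 2 decimals (2.4182 -> 2.41)."""
    return math.copysign(math.floor(abs(x) * 100.0 + _EPS), x) / 100.0
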