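"""Small numeric helpers shared across modules."""
from __future__ import annotations

import math


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (ties to even, as float round)."""
    if sig < 1:
        raise ValueError("need at least one significant figure")
    if x == 0 or not math.isfinite(x):
        return x
    digits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, digits)


def trunc_sig(x: float, sig: int) -> float:
    """Truncate toward zero at ``sig`` significant figures."""
    if sig < 1:
        raise ValueError("need at least one significant figure")
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - sig + 1)
    return math.trunc(x / factor) * factor
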