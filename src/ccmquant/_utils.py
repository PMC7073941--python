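"""Small shared numeric helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np


def round_sig(x: float, n_digits: int = 3) -> float:
    """Round ``x`` to ``n_digits`` significant figures (0 stays 0).

    Rounds the shortest decimal representation half-to-even, matching how
    tabulated values are conventionally rounded (1.225e-13 -> 1.22e-13);
    formatting the raw binary float would tip such midpoints upward.
    """
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(float(x)))
    quantum = Decimal(1).scaleb(d.adjusted() - (n_digits - 1))
    return float(d.quantize(quantum, rounding=ROUND_HALF_EVEN))


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV.

    cv = 0 returns exact ones so noiseless configurations invert bit-exactly.
    """
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)
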