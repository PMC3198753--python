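"""Shared numeric helpers: half-up rounding, percentages, seeded substreams."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = ["round_half_up", "pct", "substream"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round to `ndigits` decimals with ties away from zero (half-up).

    Python's builtin round() is banker's rounding; printed survey tables
    round 0.05 up, so percentages must too.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """One-decimal half-up percentage; raises on zero denominator."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


# Fixed stream tags: every stochastic operation draws from its own substream
# of the single user seed, so adding draws to one stage never perturbs another.
STREAMS = {
    "background_docs": 11,
    "participants": 23,
    "responses": 37,
    "audit_sample": 53,
}


def substream(seed: int, tag: str) -> np.random.Generator:
    """Independent generator for (seed, operation); deterministic contract."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), STREAMS[tag]]))
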