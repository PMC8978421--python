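"""Small shared helpers: presentation rounding and seed management."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

#: Upper bound for seeds handed to external callers / configs.
_SEED_MOD = 2**31


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as survey report tables are printed.

    Python's built-in round() uses banker's rounding (10.25 -> 10.2); report
    tables in official statistics round half up (10.25 -> 10.3), and the
    reconstruction of printed aggregates depends on it.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a master seed.

    Uses numpy's SeedSequence spawning so that per-stage random streams are
    statistically independent and a stage can be re-run in isolation.
    """
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % _SEED_MOD) for child in ss.spawn(n)]


def weighted_share(values, weights, category) -> float:
    """Weighted share of ``values == category``."""
    values = np.asarray(values)
    weights = np.asarray(weights, dtype=float)
    return float(weights[values == category].sum() / weights.sum())
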