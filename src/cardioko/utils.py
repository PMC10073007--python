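"""Small shared helpers."""

from __future__ import annotations

import zlib

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (not banker's rounding).

    Percentages in reports are rounded this way to one decimal place, so
    20/43 -> 46.5 and 43/57 -> 75.4.
    """
    scale = 10.0**ndigits
    scaled = x * scale
    # nudge by one ulp so values that are exactly representable at .5 round up
    return float(np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)) / scale


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def table_rng(seed: int, table_name: str) -> np.random.Generator:
    """One independent RNG stream per output table.

    The stream is keyed by (seed, crc32 of the table name) so adding a new
    table to a bundle never perturbs the draws of existing tables.
    """
    return np.random.default_rng([int(seed), zlib.crc32(table_name.encode())])
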