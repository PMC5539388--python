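"""EMA daily-diary response categories.

The once-daily diary asks for minutes of moderate- and (separately)
vigorous-intensity activity over the past 24 hours using 8 ordered response
options in 10-minute increments: 0-9, 10-19, ..., 60-69, and >=70 minutes.
Scoring assigns each category the mean value of its span (e.g. the 20-29
minute category scores 24.5 min); the open-ended top category is assigned
its lower bound of 70 minutes by default.
"""

from __future__ import annotations

import numbers

import numpy as np

#: width of each closed response bin in minutes
EMA_BIN_WIDTH = 10
#: number of response options; the last one is open-ended (">= 70 min")
EMA_N_CATEGORIES = 8
#: minutes assigned to the open-ended top category (its lower bound)
EMA_TOP_CATEGORY_MINUTES = 70.0


def ema_midpoints(
    top_category_minutes: float = EMA_TOP_CATEGORY_MINUTES,
) -> tuple[float, ...]:
    """Midpoint scoring table for the 8 diary categories.

    Categories 1..7 span ``[10(k-1), 10k - 1]`` minutes and score the mean of
    that span, ``10(k-1) + 4.5``; the open-ended category 8 scores
    ``top_category_minutes``.
    """
    closed = tuple(
        (EMA_BIN_WIDTH * (k - 1) + (EMA_BIN_WIDTH * k - 1)) / 2.0
        for k in range(1, EMA_N_CATEGORIES)
    )
    return closed + (float(top_category_minutes),)


def bin_ema_minutes(minutes: float) -> int:
    """Map a non-negative number of minutes to its diary category (1..8).

    Bins are {0-9, 10-19, ..., 60-69, >=70}; anything at or above 70 minutes
    is top-coded into category 8.

    Raises
    ------
    ValueError
        If ``minutes`` is negative or not finite.
    """
    if not isinstance(minutes, numbers.Real) or not np.isfinite(minutes):
        raise ValueError(f"minutes must be a finite real number, got {minutes!r}")
    if minutes < 0:
        raise ValueError(f"minutes must be >= 0, got {minutes!r}")
    return int(min(minutes // EMA_BIN_WIDTH, EMA_N_CATEGORIES - 1)) + 1
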