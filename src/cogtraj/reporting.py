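"""Small reporting utilities for count/share tables.

These reproduce the arithmetic behind "n (%)" table cells: group shares of a
total, rounded to a fixed number of decimals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent_shares", "group_share_table", "format_count_percent"]


def percent_shares(counts, total=None, decimals: int = 1) -> np.ndarray:
    """Percentages of ``counts`` out of ``total`` (default: their sum)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    tot = float(c.sum()) if total is None else float(total)
    if tot <= 0:
        raise ValueError("total must be positive")
    return np.round(100.0 * c / tot, decimals)


def group_share_table(sizes: dict, total=None, decimals: int = 1) -> pd.DataFrame:
    """n and % per named group, as printed in cohort tables."""
    names = list(sizes)
    counts = [sizes[k] for k in names]
    pct = percent_shares(counts, total=total, decimals=decimals)
    return pd.DataFrame({"group": names, "n": counts, "percent": pct})


def format_count_percent(count: int, total: int, decimals: int = 1) -> str:
    pct = percent_shares([count], total=total, decimals=decimals)[0]
    return f"{count} ({pct:.{decimals}f})"
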