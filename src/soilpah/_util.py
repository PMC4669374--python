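"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .exceptions import SchemaError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as report tables conventionally do.

    Python's built-in ``round`` is banker's rounding (2.5 -> 2); printed
    tables in this domain use half-up (2.5 -> 3), so all report formatting
    goes through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def require_columns(df: pd.DataFrame, required: list[str], source: str = "input") -> None:
    """Raise :class:`SchemaError` naming every missing column."""
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{source}: missing required column(s) {missing}; found {list(df.columns)}"
        )
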