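"""Scoring of three clinical stroke-rehabilitation instruments.

* Berg Balance Scale (BBS): 14 items scored 0-4, total 0-56; higher is
  better balance.
* Fugl-Meyer motor assessment (FMA): items graded 0-2, 33 upper-limb items
  (max 66) and 17 lower-limb items (max 34), total max 100; higher is
  better motor function.
* Functional Independence Measure (FIM): 18 items scored 1-7 — 13 motor
  (max 91) and 5 cognitive (max 35) — total 18-126, mapped to eight ordered
  dependence categories.

Only item counts and score ranges are enforced here; the instruments'
item-level clinical wording is not reproduced.  Input CSVs carry one
assessment per row with labeled item columns (``berg_01`` .. ``berg_14``,
``fma_upper_01`` .. , ``fma_lower_01`` .. , ``fim_motor_01`` .. ,
``fim_cog_01`` ..); missing items are an error, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "BergResponse", "FMAResponse", "FIMResponse",
    "berg_total", "fma_total", "fim_total", "fim_category",
    "FIM_CATEGORIES", "score_csv",
]

FIM_CATEGORIES = (
    "completely independent",
    "basically independent",
    "conditionally independent/extremely lightly dependent",
    "mildly dependent",
    "moderately dependent",
    "heavily dependent",
    "extremely dependent",
    "completely dependent",
)

# (lower bound, upper bound, category) — partitions [18, 126] exactly
_FIM_BANDS = (
    (126, 126, FIM_CATEGORIES[0]),
    (108, 125, FIM_CATEGORIES[1]),
    (90, 107, FIM_CATEGORIES[2]),
    (72, 89, FIM_CATEGORIES[3]),
    (54, 71, FIM_CATEGORIES[4]),
    (36, 53, FIM_CATEGORIES[5]),
    (19, 35, FIM_CATEGORIES[6]),
    (18, 18, FIM_CATEGORIES[7]),
)


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> list[int]:
    items = list(items)
    if len(items) != n:
        raise ValidationError(f"{name}: expected {n} items, got {len(items)}")
    out = []
    for i, v in enumerate(items, start=1):
        if v != int(v) or not (lo <= int(v) <= hi):
            raise ValidationError(
                f"{name} item {i}: score {v!r} outside integer range [{lo}, {hi}]"
            )
        out.append(int(v))
    return out


@dataclass(frozen=True)
class BergResponse:
    """14 balance items, each 0-4."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "items", tuple(_check_items(self.items, 14, 0, 4, "berg"))
        )


@dataclass(frozen=True)
class FMAResponse:
    """33 upper-limb and 17 lower-limb motor items, each graded 0-2."""

    upper: tuple[int, ...]
    lower: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "upper", tuple(_check_items(self.upper, 33, 0, 2, "fma_upper"))
        )
        object.__setattr__(
            self, "lower", tuple(_check_items(self.lower, 17, 0, 2, "fma_lower"))
        )


@dataclass(frozen=True)
class FIMResponse:
    """13 motor and 5 cognitive items, each 1-7."""

    motor: tuple[int, ...]
    cognitive: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "motor", tuple(_check_items(self.motor, 13, 1, 7, "fim_motor"))
        )
        object.__setattr__(
            self, "cognitive",
            tuple(_check_items(self.cognitive, 5, 1, 7, "fim_cog")),
        )


def berg_total(r: BergResponse) -> int:
    """Berg Balance Scale total, 0-56."""
    return sum(r.items)


def fma_total(r: FMAResponse) -> tuple[int, int, int]:
    """(upper subtotal <= 66, lower subtotal <= 34, total <= 100)."""
    up, lo = sum(r.upper), sum(r.lower)
    return up, lo, up + lo


def fim_total(r: FIMResponse) -> tuple[int, int, int]:
    """(motor subtotal <= 91, cognitive subtotal <= 35, total in [18, 126])."""
    mo, co = sum(r.motor), sum(r.cognitive)
    return mo, co, mo + co


def fim_category(total: int) -> str:
    """Dependence category for a FIM total; monotone in the total."""
    if total != int(total) or not (18 <= int(total) <= 126):
        raise ValidationError(f"FIM total {total!r} outside [18, 126]")
    total = int(total)
    for lo, hi, cat in _FIM_BANDS:
        if lo <= total <= hi:
            return cat
    raise AssertionError("unreachable: bands partition [18, 126]")


def _row_items(row: pd.Series, prefix: str, n: int) -> list[int]:
    cols = [f"{prefix}_{i:02d}" for i in range(1, n + 1)]
    missing = [c for c in cols if c not in row.index or pd.isna(row[c])]
    if missing:
        raise ValidationError(f"missing item columns: {missing}")
    return [row[c] for c in cols]


def score_csv(path_or_df) -> pd.DataFrame:
    """Score a CSV (or DataFrame) of item responses, one assessment per row.

    Returns a frame with berg/FMA/FIM subtotals, totals, and the FIM
    dependence category.  All item columns must be present for every
    instrument being scored.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    out = []
    for _, row in df.iterrows():
        rec: dict = {}
        if "subject" in row.index:
            rec["subject"] = row["subject"]
        if any(c.startswith("berg_") for c in df.columns):
            rec["berg_total"] = berg_total(BergResponse(_row_items(row, "berg", 14)))
        if any(c.startswith("fma_") for c in df.columns):
            up, lo, tot = fma_total(FMAResponse(
                _row_items(row, "fma_upper", 33), _row_items(row, "fma_lower", 17)
            ))
            rec.update(fma_upper=up, fma_lower=lo, fma_total=tot)
        if any(c.startswith("fim_") for c in df.columns):
            mo, co, tot = fim_total(FIMResponse(
                _row_items(row, "fim_motor", 13), _row_items(row, "fim_cog", 5)
            ))
            rec.update(fim_motor=mo, fim_cognitive=co, fim_total=tot,
                       fim_category=fim_category(tot))
        out.append(rec)
    return pd.DataFrame(out)
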