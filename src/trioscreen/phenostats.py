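"""Descriptive group-comparison arithmetic for behavioral and histology data.

The operations here are the printed-number summaries used to report motor
decline and Purkinje-cell loss: percent reduction of a test-group mean
relative to a reference (wild-type) mean, raw mean differences, and cell-
loss percentages from count pairs.  Rounding mirrors reporting precision:
integer percent for behavioral reductions (half away from zero), one
decimal for cell loss.  Inferential statistics (ANOVA, t-tests, CIs) are
out of scope — raw per-animal data are not part of this package's inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GroupSummary",
    "percent_reduction",
    "mean_difference",
    "cell_loss_percent",
    "read_group_table",
    "write_comparisons",
]


@dataclass(frozen=True)
class GroupSummary:
    """A labelled group mean with its sample size."""

    label: str
    mean: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")


def _round_half_away(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_reduction(reference: float, test: float) -> int:
    """Percent reduction of ``test`` relative to ``reference``, integer-rounded.

    100 * (reference - test) / reference, rounded half away from zero.
    Negative results mean the test group exceeds the reference.
    """
    if reference <= 0:
        raise ValueError("percent_reduction requires a positive reference mean")
    return int(_round_half_away(100.0 * (reference - test) / reference, 0))


def mean_difference(reference: float, test: float) -> float:
    """Reference mean minus test mean, in the input units (antisymmetric)."""
    return reference - test


def cell_loss_percent(wt_count: int | float, mut_count: int | float) -> float:
    """Percent cell loss in mutants relative to wild type, one decimal."""
    if wt_count <= 0:
        raise ValueError("cell_loss_percent requires a positive wild-type count")
    return _round_half_away(100.0 * (wt_count - mut_count) / wt_count, 1)


def read_group_table(path: str | Path) -> list[GroupSummary]:
    """Read a (label, mean, n) TSV of group summaries."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str}, comment="#")
    for col in ("label", "mean", "n"):
        if col not in df.columns:
            raise ValueError(f"{path}: group table lacks column {col!r}")
    return [
        GroupSummary(label=r.label, mean=float(r.mean), n=int(r.n))
        for r in df.itertuples(index=False)
    ]


def write_comparisons(
    reference: GroupSummary, test: GroupSummary, path: str | Path
) -> pd.DataFrame:
    """Write the standard reference-vs-test comparison rows as TSV."""
    rows = pd.DataFrame(
        [
            {
                "comparison": f"percent_reduction({reference.label} vs {test.label})",
                "value": percent_reduction(reference.mean, test.mean),
            },
            {
                "comparison": f"mean_difference({reference.label} vs {test.label})",
                "value": mean_difference(reference.mean, test.mean),
            },
        ]
    )
    rows.to_csv(path, sep="\t", index=False)
    return rows
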