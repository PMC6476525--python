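"""Polysome-gradient fraction analysis.

mRNA abundances measured by qPCR across the 14 fractions of a 10-50% sucrose
gradient are normalized to percentages of the per-mRNA total, then summarised
by a heavy-fraction share (percentage at or beyond a configurable heavy-start
index) and a weighted mean fraction index.  Higher-index fractions hold
heavier polysomes, so an mRNA whose mass sits further right is inferred to be
more actively translated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FractionProfile",
    "PolysomeSummary",
    "PolysomeError",
    "N_FRACTIONS",
    "normalize_fractions",
    "shift_summary",
    "compare_conditions",
]

N_FRACTIONS = 14
DEFAULT_HEAVY_START = 8


class PolysomeError(ValueError):
    """Raised on malformed fraction data."""


@dataclass(frozen=True)
class FractionProfile:
    """Per-mRNA abundances over the gradient, raw and percentage-normalized."""

    mrna: str
    condition: str
    fractions: tuple[float, ...]
    percentages: tuple[float, ...]

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class PolysomeSummary:
    mrna: str
    condition: str
    heavy_share: float  # percent of signal in fractions >= heavy_start
    mean_fraction_index: float  # in [1, n_fractions]
    heavy_start: int


def normalize_fractions(
    raw,
    *,
    mrna: str = "mrna",
    condition: str = "condition",
    n_fractions: int = N_FRACTIONS,
) -> FractionProfile:
    """Convert raw fraction abundances to percentages of their sum.

    ``percentages[i] = 100 * raw[i] / sum(raw)``; order is preserved.  The
    fraction count defaults to the 14-fraction gradient protocol but is
    configurable for other gradients.
    """
    arr = np.asarray(raw, dtype=float).ravel()
    if arr.size != n_fractions:
        raise PolysomeError(f"expected {n_fractions} fractions, got {arr.size}")
    if np.any(arr < 0):
        raise PolysomeError("fraction abundances must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise PolysomeError("total abundance across fractions must be positive")
    pct = 100.0 * arr / total
    return FractionProfile(mrna, condition, tuple(arr.tolist()), tuple(pct.tolist()))


def shift_summary(profile: FractionProfile, heavy_start: int = DEFAULT_HEAVY_START) -> PolysomeSummary:
    """Summarise a profile by heavy-fraction share and mean fraction index.

    ``heavy_share`` sums the percentages of fractions ``heavy_start..n`` (1-based,
    inclusive); ``mean_fraction_index`` is the percentage-weighted mean
    position, between 1 and the fraction count.
    """
    n = profile.n_fractions
    if not (1 <= heavy_start <= n):
        raise PolysomeError(f"heavy_start {heavy_start} outside [1, {n}]")
    pct = np.asarray(profile.percentages)
    heavy = float(pct[heavy_start - 1 :].sum())
    mean_idx = float(np.dot(np.arange(1, n + 1), pct) / 100.0)
    return PolysomeSummary(profile.mrna, profile.condition, heavy, mean_idx, heavy_start)


def compare_conditions(
    a: FractionProfile,
    b: FractionProfile,
    heavy_start: int = DEFAULT_HEAVY_START,
) -> tuple[float, float]:
    """Difference of summaries between two conditions of the same mRNA.

    Returns ``(delta_heavy_share, delta_mean_index)`` computed as ``a - b``:
    positive values mean condition ``a`` sits in heavier polysome fractions.
    """
    if a.mrna != b.mrna:
        raise PolysomeError(f"cannot compare different mRNAs: {a.mrna!r} vs {b.mrna!r}")
    if a.n_fractions != b.n_fractions:
        raise PolysomeError("profiles have different fraction counts")
    sa = shift_summary(a, heavy_start)
    sb = shift_summary(b, heavy_start)
    return (sa.heavy_share - sb.heavy_share, sa.mean_fraction_index - sb.mean_fraction_index)


def read_fraction_table(path) -> list[FractionProfile]:
    """Read a tidy TSV (mrna, condition, fraction_index, abundance) into profiles."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (mrna, cond), grp in df.groupby(["mrna", "condition"], sort=False):
        grp = grp.sort_values("fraction_index")
        profiles.append(
            normalize_fractions(
                grp["abundance"].to_numpy(), mrna=str(mrna), condition=str(cond),
                n_fractions=len(grp),
            )
        )
    return profiles
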