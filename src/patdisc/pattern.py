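"""The pattern model {P, S, r} and its noise-tolerant matching.

A pattern is a subset of attributes P with one value per attribute S and a
matching-ratio threshold r in (0, 1].  A record matches when at least
``r * w`` of its w pattern cells equal the pattern values; missing cells
count as mismatches, which is how the model tolerates noisy repository
data.  The threshold test uses the exact integer form
``matched_count >= ceil(r * w)`` so trained thresholds k/w behave
identically to the floating comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .data_model import MISSING, Dataset, Record, TargetSpec

__all__ = ["Pattern", "ConfusionCounts", "match", "evaluate", "matched_counts"]

_EPS = 1e-9


@dataclass(frozen=True)
class Pattern:
    """attrs P, values S, matching-ratio threshold r."""

    attrs: tuple[str, ...]
    values: tuple[str, ...]
    r: float

    def __post_init__(self):
        if len(self.attrs) != len(self.values) or not self.attrs:
            raise ValueError("need equally many attributes and values, at least one")
        if len(set(self.attrs)) != len(self.attrs):
            raise ValueError("pattern attributes must be distinct")
        if not 0 < self.r <= 1:
            raise ValueError("matching ratio threshold r must be in (0, 1]")

    @property
    def w(self) -> int:
        return len(self.attrs)

    @property
    def required_matches(self) -> int:
        """Smallest integer k with k/w >= r."""
        return max(1, math.ceil(self.r * self.w - _EPS))

    def to_line(self) -> str:
        """Human-readable rule, e.g. ``PCI = Yes, CRP = Abnormal ; r = 2/3 (67%)``."""
        pairs = ", ".join(f"{a} = {v}" for a, v in zip(self.attrs, self.values))
        frac = Fraction(self.required_matches, self.w)
        return f"{pairs} ; r = {frac.numerator}/{frac.denominator} ({self.r:.0%})"

    def to_dict(self) -> dict:
        return {"attrs": list(self.attrs), "values": list(self.values), "r": self.r}

    @classmethod
    def from_dict(cls, d: dict) -> "Pattern":
        return cls(attrs=tuple(d["attrs"]), values=tuple(d["values"]), r=float(d["r"]))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def match(pattern: Pattern, record: Record) -> tuple[bool, int]:
    """Does the record match the pattern?  Returns (matched, matched_count).

    MISSING never equals any value (two MISSINGs do not match either).
    """
    count = 0
    for a, v in zip(pattern.attrs, pattern.values):
        if a not in record.values:
            raise KeyError(f"pattern attribute {a!r} absent from record")
        cell = record.values[a]
        if cell is not MISSING and cell == v:
            count += 1
    return count >= pattern.required_matches, count


def matched_counts(pattern: Pattern, dataset: Dataset) -> np.ndarray:
    """Vectorized per-record matched-cell counts over a whole dataset."""
    counts = np.zeros(dataset.n, dtype=np.int64)
    for a, v in zip(pattern.attrs, pattern.values):
        if a not in dataset.df.columns:
            raise KeyError(f"pattern attribute {a!r} absent from dataset")
        col = dataset.df[a]
        counts += np.fromiter(
            ((c is not MISSING and c == v) for c in col), dtype=bool, count=dataset.n
        )
    return counts


def evaluate(pattern: Pattern, dataset: Dataset, target: TargetSpec) -> ConfusionCounts:
    """Confusion counts of the pattern as a classifier on a labeled dataset."""
    if dataset.n == 0:
        raise ValueError("empty dataset")
    predicted = matched_counts(pattern, dataset) >= pattern.required_matches
    actual = dataset.positive_mask(target)
    return ConfusionCounts(
        TP=int((predicted & actual).sum()),
        FP=int((predicted & ~actual).sum()),
        TN=int((~predicted & ~actual).sum()),
        FN=int((~predicted & actual).sum()),
    )
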