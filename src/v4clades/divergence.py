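"""Pairwise identity over aligned V4 sequences and OTU-threshold lumping.

Closely related clades can be indistinguishable at a fixed OTU clustering
threshold: if any cross-clade pair of sequences is at least as similar as
the threshold, greedy OTU construction can merge ("lump") the clades. This
module quantifies that risk from a reference alignment and clade labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .formats_io import GAP, Alignment

GAP_MODES = ("all_columns", "ungapped_pair_columns")


class UndefinedIdentityError(ValueError):
    """No comparable columns between two sequences (all-gap overlap)."""


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round half-up to ``ndigits`` decimals, as printed in reports (99.35 -> 99.4)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent_identity(a: str, b: str, gap_mode: str = "ungapped_pair_columns") -> float:
    """Percent identity between two aligned sequences (full precision).

    ``all_columns``: 100 x matches / alignment length, gaps compared like
    characters. ``ungapped_pair_columns``: columns where either sequence has
    a gap are dropped from numerator and denominator.
    """
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}, got {gap_mode!r}")
    if len(a) != len(b):
        raise ValueError(f"aligned sequences of unequal length: {len(a)} vs {len(b)}")
    a = a.upper()
    b = b.upper()
    if gap_mode == "all_columns":
        matches = sum(x == y for x, y in zip(a, b))
        total = len(a)
    else:
        pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
        if not pairs:
            raise UndefinedIdentityError("no gap-free columns shared by the pair")
        matches = sum(x == y for x, y in pairs)
        total = len(pairs)
    return 100.0 * matches / total


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix over alignment members."""

    ids: tuple[str, ...]
    values: np.ndarray  # full precision, percent
    gap_mode: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("identity matrix diagonal must be 100")

    def value(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        vals = self.values
        if rounded:
            vals = np.vectorize(round_pct)(vals)
        return pd.DataFrame(vals, index=self.ids, columns=self.ids)


def identity_matrix(alignment: Alignment, gap_mode: str = "ungapped_pair_columns") -> IdentityMatrix:
    """All-pairs :func:`percent_identity` over an alignment (>= 2 sequences)."""
    if len(alignment) < 2:
        raise ValueError("identity matrix needs at least 2 sequences")
    n = len(alignment)
    vals = np.full((n, n), 100.0)
    recs = alignment.records
    for i, j in combinations(range(n), 2):
        pid = percent_identity(recs[i].sequence, recs[j].sequence, gap_mode)
        vals[i, j] = vals[j, i] = pid
    return IdentityMatrix(alignment.ids, vals, gap_mode)


@dataclass(frozen=True)
class CladeIdentitySummary:
    """Between-clade max/mean and within-clade min identity, in percent.

    ``within_min`` is ``None`` for singleton clades (the statistic is absent,
    not zero).
    """

    between: Mapping[tuple[str, str], dict]  # (cladeA, cladeB) sorted -> {max, mean}
    within_min: Mapping[str, float | None]


def clade_identity_summary(
    matrix: IdentityMatrix, labels: Mapping[str, str]
) -> CladeIdentitySummary:
    """Summarize an identity matrix by clade labels (id -> clade)."""
    missing = [i for i in matrix.ids if i not in labels]
    if missing:
        raise KeyError(f"unlabelled sequences: {missing}")
    clades = sorted(set(labels[i] for i in matrix.ids))
    members = {c: [i for i in matrix.ids if labels[i] == c] for c in clades}
    between: dict[tuple[str, str], dict] = {}
    for ca, cb in combinations(clades, 2):
        vals = [matrix.value(i, j) for i in members[ca] for j in members[cb]]
        between[(ca, cb)] = {"max": max(vals), "mean": float(np.mean(vals))}
    within_min: dict[str, float | None] = {}
    for c in clades:
        pairs = list(combinations(members[c], 2))
        within_min[c] = min(matrix.value(i, j) for i, j in pairs) if pairs else None
    return CladeIdentitySummary(between, within_min)


@dataclass(frozen=True)
class LumpingReport:
    """Which clade pairs a fixed-identity OTU threshold cannot separate.

    A pair is lumped when the *maximum* between-clade identity reaches the
    threshold (single linkage: one cross-pair at or above the threshold is
    enough for greedy OTU clustering to merge the clades).
    """

    threshold_pct: float
    pairs: Mapping[tuple[str, str], dict]  # {max_between_identity, lumped}

    @property
    def lumped_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(p for p, d in self.pairs.items() if d["lumped"])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "clade_a": a,
                "clade_b": b,
                "max_between_identity": round_pct(d["max_between_identity"]),
                "lumped": d["lumped"],
            }
            for (a, b), d in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows)


def otu_lumping(summary: CladeIdentitySummary, threshold_pct: float = 99.0) -> LumpingReport:
    """Evaluate clade discriminability at an OTU identity threshold."""
    pairs = {
        pair: {
            "max_between_identity": stats["max"],
            "lumped": stats["max"] >= threshold_pct,
        }
        for pair, stats in summary.between.items()
    }
    return LumpingReport(threshold_pct, pairs)
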