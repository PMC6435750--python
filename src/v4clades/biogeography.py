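"""Relative abundance, presence/prevalence and the habitat band summary.

Read counts are only a semi-quantitative proxy of abundance, so everything
here is expressed relative to the per-sample total of the group under study
(percent of group reads), samples with too few group reads are excluded,
and a taxon counts as "present" in a sample only above a relative-abundance
floor (default 1% of group reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("v4clades")

#: |latitude| cut-offs: polar >= 66.5, subpolar >= 55, temperate >= 35,
#: tropical below. Conventional oceanographic values, not taken from any
#: published table — the habitat bands themselves are standard, their
#: numeric edges are this package's choice.
DEFAULT_BAND_EDGES = (66.5, 55.0, 35.0)
BANDS = ("polar", "subpolar", "temperate", "tropical")


def filter_samples(meta: pd.DataFrame, min_group_reads: int = 100) -> pd.DataFrame:
    """Retain samples with ``group_total_reads >= min_group_reads`` (inclusive)."""
    kept = meta[meta["group_total_reads"] >= min_group_reads]
    logger.info(
        "filter_samples: %d of %d samples at >=%d group reads",
        len(kept), len(meta), min_group_reads,
    )
    return kept


@dataclass(frozen=True)
class AbundanceTable:
    """Percent of group reads per (taxon or ASV) x sample."""

    percents: pd.DataFrame  # rows = taxon/asv, columns = samples
    min_group_reads: int

    def __post_init__(self) -> None:
        vals = self.percents.to_numpy()
        if ((vals < 0) | (vals > 100 + 1e-9)).any():
            raise ValueError("abundances must be percentages in [0, 100]")


def pool_by_taxon(counts: pd.DataFrame, labels: Mapping[str, str]) -> pd.DataFrame:
    """Sum ASV-level counts into taxon-level counts (pooling before thresholding)."""
    missing = [i for i in counts.index if i not in labels]
    if missing:
        raise KeyError(f"unlabelled ASVs: {missing}")
    return counts.groupby([labels[i] for i in counts.index]).sum()


def relative_abundance(
    counts: pd.DataFrame,
    group_totals: pd.Series,
    min_group_reads: int = 100,
) -> AbundanceTable:
    """Percent of group reads for each row of ``counts``, per sample.

    ``group_totals`` gives the per-sample total reads of the whole group;
    samples must be pre-filtered (a zero total among the columns of
    ``counts`` is an error) and the totals must be at least the per-sample
    sum of the counted rows.
    """
    samples = list(counts.columns)
    missing = [s for s in samples if s not in group_totals.index]
    if missing:
        raise KeyError(f"samples without a group total: {missing}")
    totals = group_totals.loc[samples].astype(float)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise ValueError(f"retained samples with zero group total: {zero}")
    colsums = counts.sum(axis=0).astype(float)
    over = colsums[colsums > totals + 1e-9].index.tolist()
    if over:
        raise ValueError(f"counts exceed the group total in samples: {over}")
    percents = counts.astype(float).div(totals, axis=1) * 100.0
    return AbundanceTable(percents, min_group_reads)


def presence_mask(table: AbundanceTable, threshold_pct: float = 1.0) -> pd.DataFrame:
    """Present iff relative abundance >= ``threshold_pct`` (1.0% exactly is present)."""
    return table.percents >= threshold_pct


def prevalence(mask: pd.DataFrame) -> pd.Series:
    """Number of samples in which each taxon is present."""
    out = mask.sum(axis=1).astype(int)
    out.name = "n_samples_present"
    return out


def assign_band(latitude: float, band_edges: Sequence[float] = DEFAULT_BAND_EDGES) -> str:
    """Latitudinal band of a sample, by absolute latitude (hemispheres folded)."""
    polar, subpolar, temperate = band_edges
    if not polar > subpolar > temperate > 0:
        raise ValueError(f"band edges must decrease and stay positive: {band_edges}")
    alat = abs(latitude)
    if alat > 90:
        raise ValueError(f"latitude out of range: {latitude}")
    if alat >= polar:
        return "polar"
    if alat >= subpolar:
        return "subpolar"
    if alat >= temperate:
        return "temperate"
    return "tropical"


def habitat_summary(
    mask: pd.DataFrame,
    meta: pd.DataFrame,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
) -> pd.DataFrame:
    """Per-taxon presence counts and occupied latitude bands.

    One row per taxon: ``n_samples_present``, one boolean column per band,
    and ``med_sea``/``lagoon`` flags taken from metadata columns of those
    names when present (never inferred from coordinates).
    """
    rows = []
    flag_cols = [c for c in ("med_sea", "lagoon") if c in meta.columns]
    for taxon, present in mask.iterrows():
        samples = [s for s in mask.columns if present[s]]
        missing = [s for s in samples if s not in meta.index or pd.isna(meta.loc[s, "latitude"])]
        if missing:
            raise KeyError(f"no latitude for present samples {missing} of taxon {taxon!r}")
        bands = {assign_band(meta.loc[s, "latitude"], band_edges) for s in samples}
        row = {"taxon": taxon, "n_samples_present": len(samples)}
        for band in BANDS:
            row[band] = band in bands
        for col in flag_cols:
            row[col] = bool(meta.loc[samples, col].any()) if samples else False
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")
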