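"""Quality filtering, exact dereplication into ASVs, and cross-dataset checks.

An ASV (amplicon single variant) is the representative of a set of strictly
identical reads — no clustering, no denoising. Two independently processed
renditions of the same samples can then cross-validate each other: a major
ASV in one dataset is confirmed when the other dataset contains a strictly
identical sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import IUPAC_CODES, GAP, SeqRecord

logger = logging.getLogger("v4clades")

_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")


class NormalizationError(ValueError):
    """Sequence contains a character outside the IUPAC nucleotide alphabet."""


@dataclass(frozen=True)
class Asv:
    """One amplicon single variant: a unique sequence with per-sample counts."""

    asv_id: str
    sequence: str
    counts: Mapping[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class AsvTable:
    """Unique sequences x samples read-count matrix for one dataset."""

    dataset_label: str
    asvs: tuple[Asv, ...]

    def __post_init__(self) -> None:
        seqs = [a.sequence for a in self.asvs]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"duplicate sequences in AsvTable {self.dataset_label!r}")
        ids = [a.asv_id for a in self.asvs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate asv_ids in AsvTable {self.dataset_label!r}")
        for a in self.asvs:
            if any(c < 0 for c in a.counts.values()):
                raise ValueError(f"negative count in ASV {a.asv_id}")

    @property
    def total_reads(self) -> int:
        return sum(a.total_reads for a in self.asvs)

    @property
    def sequences(self) -> frozenset[str]:
        return frozenset(a.sequence for a in self.asvs)

    def __len__(self) -> int:
        return len(self.asvs)

    def __iter__(self):
        return iter(self.asvs)

    def get(self, asv_id: str) -> Asv:
        for a in self.asvs:
            if a.asv_id == asv_id:
                return a
        raise KeyError(asv_id)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (rows = asv_id, columns = samples)."""
        samples = sorted({s for a in self.asvs for s in a.counts})
        data = {
            a.asv_id: {s: int(a.counts.get(s, 0)) for s in samples} for a in self.asvs
        }
        df = pd.DataFrame.from_dict(data, orient="index", columns=samples).fillna(0)
        df.index.name = "asv_id"
        return df.astype(int)


@dataclass(frozen=True)
class FilterLog:
    """Before/after bookkeeping of a read quality filter."""

    n_input: int
    n_kept: int
    n_removed_ambiguous: int
    n_removed_short: int

    def __post_init__(self) -> None:
        assert self.n_kept + self.n_removed_ambiguous + self.n_removed_short == self.n_input


def quality_filter(
    reads: Iterable[SeqRecord],
    min_len: int = 300,
    ambiguity: str = "N",
) -> tuple[list[SeqRecord], FilterLog]:
    """Keep reads without ambiguities and strictly longer than ``min_len``.

    ``ambiguity="N"`` removes reads containing N/n only (the study's filter);
    ``ambiguity="any"`` removes reads containing any IUPAC ambiguity code.
    Reads failing both tests are counted under the ambiguity reason.
    """
    if ambiguity not in ("N", "any"):
        raise ValueError(f"ambiguity must be 'N' or 'any', got {ambiguity!r}")
    bad = _IUPAC_AMBIGUOUS if ambiguity == "any" else frozenset("N")
    kept: list[SeqRecord] = []
    n_amb = n_short = 0
    n_input = 0
    for rec in reads:
        n_input += 1
        if set(rec.sequence.upper()) & bad:
            n_amb += 1
        elif len(rec.sequence) <= min_len:
            n_short += 1
        else:
            kept.append(rec)
    log = FilterLog(n_input, len(kept), n_amb, n_short)
    logger.info(
        "quality_filter: %d reads in, %d kept, %d removed (ambiguity), %d removed (<=%d bp)",
        log.n_input, log.n_kept, log.n_removed_ambiguous, log.n_removed_short, min_len,
    )
    return kept, log


_RNA_TO_DNA = str.maketrans({"U": "T", "u": "T"})


def normalize(sequence: str) -> str:
    """Canonical form of a sequence: uppercase, U->T, gaps removed.

    Idempotent. Raises :class:`NormalizationError` on non-IUPAC characters.
    """
    out = sequence.translate(_RNA_TO_DNA).upper().replace(GAP, "").replace(".", "")
    bad = set(out) - IUPAC_CODES
    if bad:
        raise NormalizationError(f"non-IUPAC characters {sorted(bad)} in sequence")
    return out


def dereplicate(
    reads: Iterable[tuple[SeqRecord, str]],
    dataset_label: str,
    id_prefix: str = "ASV",
) -> AsvTable:
    """Collapse identical sequences into ASVs with per-sample read counts.

    Reads must already be quality-filtered and normalized. ASV ids are
    ``ASV_<dataset>_<rank>`` with rank by descending total reads, ties broken
    by sequence lexicographic order; total reads are conserved.
    """
    counts: dict[str, dict[str, int]] = {}
    n_reads = 0
    for rec, sample in reads:
        n_reads += 1
        per_sample = counts.setdefault(rec.sequence, {})
        per_sample[sample] = per_sample.get(sample, 0) + 1
    ranked = sorted(
        counts.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )
    asvs = tuple(
        Asv(f"{id_prefix}_{dataset_label}_{rank:05d}", seq, per_sample)
        for rank, (seq, per_sample) in enumerate(ranked, start=1)
    )
    table = AsvTable(dataset_label, asvs)
    assert table.total_reads == n_reads, "read-count conservation violated"
    logger.info(
        "dereplicate[%s]: %d reads -> %d ASVs", dataset_label, n_reads, len(asvs)
    )
    return table


def select_major(table: AsvTable, min_reads: int = 200) -> AsvTable:
    """Subset to ASVs with total reads >= ``min_reads`` (inclusive).

    Order is by descending total reads; original asv_ids are kept.
    """
    kept = tuple(
        sorted(
            (a for a in table.asvs if a.total_reads >= min_reads),
            key=lambda a: (-a.total_reads, a.sequence),
        )
    )
    logger.info(
        "select_major[%s]: %d of %d ASVs at >=%d reads",
        table.dataset_label, len(kept), len(table.asvs), min_reads,
    )
    return AsvTable(table.dataset_label, kept)


@dataclass(frozen=True)
class Confirmation:
    """Cross-dataset verdict for one ASV."""

    asv_id: str
    confirmed: bool
    matches: tuple[str, ...]  # asv_ids in the other dataset


def cross_confirm(
    major: AsvTable, other: AsvTable, mode: str = "exact"
) -> list[Confirmation]:
    """Flag each ASV of ``major`` that the ``other`` dataset corroborates.

    ``exact``: confirmed iff a strictly identical sequence exists in
    ``other``. ``containment``: confirmed iff either sequence is a substring
    of the other (tolerates trimming differences between pipelines).
    """
    if mode not in ("exact", "containment"):
        raise ValueError(f"mode must be 'exact' or 'containment', got {mode!r}")
    out = []
    for a in major.asvs:
        if mode == "exact":
            matches = tuple(b.asv_id for b in other.asvs if b.sequence == a.sequence)
        else:
            matches = tuple(
                b.asv_id
                for b in other.asvs
                if a.sequence in b.sequence or b.sequence in a.sequence
            )
        out.append(Confirmation(a.asv_id, bool(matches), matches))
    n_conf = sum(c.confirmed for c in out)
    logger.info(
        "cross_confirm[%s vs %s, %s]: %d/%d confirmed",
        major.dataset_label, other.dataset_label, mode, n_conf, len(out),
    )
    return out


def group_reads_by_taxon(
    table: AsvTable, labels: Mapping[str, str]
) -> dict[str, int]:
    """Sum total reads per taxon over the ASVs of ``table``.

    Every ASV in the table must be labelled; sums conserve the table total.
    """
    missing = [a.asv_id for a in table.asvs if a.asv_id not in labels]
    if missing:
        raise KeyError(f"unlabelled ASVs: {missing}")
    out: dict[str, int] = {}
    for a in table.asvs:
        out[labels[a.asv_id]] = out.get(labels[a.asv_id], 0) + a.total_reads
    assert sum(out.values()) == table.total_reads
    return out


def confirmations_to_frame(confirmations: Sequence[Confirmation]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "asv_id": [c.asv_id for c in confirmations],
            "confirmed": [c.confirmed for c in confirmations],
            "matches": [",".join(c.matches) for c in confirmations],
        }
    )
    return df.set_index("asv_id")
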