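"""Readers/writers for the external formats the pipeline touches.

All on-disk formats are plain text: FASTA (optionally aligned), TSV read-count
tables (rows = sequence ids, columns = samples), TSV sample metadata, newick
trees with optional node supports, and a flat ``key=value`` configuration
dialect. Alignment columns are reported 1-based everywhere the package talks
to the outside world.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("v4clades")

#: IUPAC nucleotide one-letter codes (DNA + U for RNA input).
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")
GAP = "-"
_ALLOWED = IUPAC_CODES | {GAP}


class FormatError(ValueError):
    """A file violates the contract of its format."""


class AlignmentShapeError(FormatError):
    """Sequences expected to be aligned have unequal lengths."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence, possibly gapped when aligned.

    Case is preserved on read; normalization (upper-casing, degapping,
    U->T) is a separate, explicit operation in :mod:`v4clades.asv_core`.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if set(self.sequence.upper()) - _ALLOWED:  # single C-level pass
            for pos, ch in enumerate(self.sequence, start=1):
                if ch.upper() not in _ALLOWED:
                    raise FormatError(
                        f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length sequences.

    ``length`` is the number of columns; column positions in reports are
    1-based.
    """

    records: tuple[SeqRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment with no sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"unequal sequence lengths in alignment: {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def column(self, position: int) -> str:
        """Characters of the 1-based column ``position``, in record order."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside alignment of length {self.length}")
        return "".join(r.sequence[position - 1] for r in self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PipelineConfig:
    """The numeric knobs of the pipeline, defaulting to the study's values.

    min_asv_reads
        Major-ASV selection floor; inclusive (an ASV with exactly this many
        reads is kept).
    min_sample_group_reads
        Per-sample floor on total group (e.g. Mamiellophyceae) reads;
        inclusive.
    presence_threshold_pct
        Relative abundance (percent of group reads) at or above which a taxon
        counts as present in a sample.
    min_bootstrap
        ML bootstrap percentage a clade's defining edge must strictly exceed.
    otu_identity_threshold_pct
        OTU clustering identity threshold used in the lumping analysis.
    """

    min_asv_reads: int = 200
    min_sample_group_reads: int = 100
    presence_threshold_pct: float = 1.0
    min_bootstrap: float = 70.0
    otu_identity_threshold_pct: float = 99.0
    random_seed: int = 42

    def __post_init__(self) -> None:
        if self.min_asv_reads < 0 or self.min_sample_group_reads < 0:
            raise ValueError("read thresholds must be non-negative")
        for name in ("presence_threshold_pct", "min_bootstrap", "otu_identity_threshold_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be within [0, 100], got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key=value`` config file; unknown keys are errors."""
        known = {f.name: f.type for f in fields(cls)}
        overrides: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = (p.strip() for p in line.partition("="))
            if key not in known:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            overrides[key] = int(value) if key.endswith(("reads", "seed")) else float(value)
        return replace(cls(), **overrides)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, aligned: bool = False):
    """Read a FASTA file.

    Returns a list of :class:`SeqRecord`, or an :class:`Alignment` when
    ``aligned`` is set (all sequences must then be of equal length).
    Records are preserved verbatim, in file order.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq)))
    if aligned:
        return Alignment(tuple(records))
    return records


def write_fasta(records: Iterable[SeqRecord] | Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV read-count table (rows = sequence ids, columns = samples).

    Missing cells are read as 0. Cells must be non-negative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sequence id {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=int)
    for col in df.columns:
        for row, cell in df[col].items():
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
                out.loc[row, col] = 0
                continue
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {row!r}, column {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} at row {row!r}, column {col!r}"
                )
            out.loc[row, col] = value
    out.index.name = df.index.name or "sequence_id"
    return out.astype(int)


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "sequence_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample_id, latitude, longitude, group_total_reads.

    Optional boolean columns (e.g. ``med_sea``, ``lagoon``) are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "latitude", "longitude", "group_total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    if ((df["latitude"] < -90) | (df["latitude"] > 90)).any():
        raise FormatError(f"{path}: latitude outside [-90, 90]")
    if ((df["longitude"] < -180) | (df["longitude"] > 180)).any():
        raise FormatError(f"{path}: longitude outside [-180, 180]")
    if (df["group_total_reads"] < 0).any():
        raise FormatError(f"{path}: negative group_total_reads")
    return df.set_index("sample_id")


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path, scale: str = "percent"):
    """Read a newick tree, keeping internal-node support labels as numbers.

    ``scale`` declares how supports are to be interpreted: ``"percent"``
    (ML bootstrap, 0-100) or ``"probability"`` (Bayesian posterior, 0-1).
    The parser itself preserves whatever number is stored.
    """
    from .clade_criteria import SupportedTree

    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    return SupportedTree.from_dendropy(tree, scale=scale)


def parse_newick(newick: str, scale: str = "percent"):
    """As :func:`read_newick`, from a newick string."""
    from .clade_criteria import SupportedTree

    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"newick parse error: {exc}") from exc
    return SupportedTree.from_dendropy(tree, scale=scale)


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
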