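"""The published major-ASV table (packaged data) and loaders for it.

``data/major_asvs.tsv`` is a plain-text transcription of the printed table
of major Mamiellophyceae ASVs from the two OSD 2014 datasets (LGC and LW):
ASV code, taxonomic assignment, genus and total read count. The printed
table carries no sequences, so the :class:`~v4clades.asv_core.AsvTable`
built from it uses deterministic placeholder sequences — unique, valid,
and obviously synthetic — which is sufficient for every read-count
operation (taxon grouping, major-ASV selection).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .asv_core import Asv, AsvTable

_TOTAL_SAMPLE = "total"


def load_major_asv_frame() -> pd.DataFrame:
    """The packaged major-ASV table as a DataFrame."""
    with resources.files("v4clades.data").joinpath("major_asvs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _placeholder_sequence(rank: int, length: int = 30) -> str:
    """Deterministic unique ACGT string encoding the rank in base 4."""
    bases = "ACGT"
    digits = []
    r = rank
    for _ in range(length):
        digits.append(bases[r % 4])
        r //= 4
    return "".join(reversed(digits))


def load_major_asv_tables() -> tuple[dict[str, AsvTable], dict[str, str]]:
    """Published table as per-dataset AsvTables plus an asv_id -> taxon map.

    Counts sit in a single pseudo-sample ``"total"`` since the printed table
    reports per-dataset totals only.
    """
    df = load_major_asv_frame()
    labels = dict(zip(df["asv_id"], df["taxon"]))
    tables: dict[str, AsvTable] = {}
    for dataset, sub in df.groupby("dataset"):
        asvs = tuple(
            Asv(row.asv_id, _placeholder_sequence(i), {_TOTAL_SAMPLE: int(row.reads)})
            for i, row in enumerate(sub.itertuples(), start=1)
        )
        tables[dataset] = AsvTable(dataset, asvs)
    return tables, labels


def genus_labels() -> dict[str, str]:
    df = load_major_asv_frame()
    return dict(zip(df["asv_id"], df["genus"]))
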