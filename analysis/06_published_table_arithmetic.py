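#!/usr/bin/env python
"""Reproduce the read-count arithmetic of the published major-ASV table.

Loads the packaged transcription of the published LGC/LW major-ASV table,
re-derives the per-taxon and per-genus read sums and the major-ASV count at
the 200-read selection floor, and writes them under results/published/.
"""

from pathlib import Path

import pandas as pd

import v4clades as v
from v4clades.published import genus_labels, load_major_asv_tables

OUT = Path(__file__).resolve().parent.parent / "results" / "published"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    tables, taxon = load_major_asv_tables()
    genus = genus_labels()

    for dataset, table in tables.items():
        by_taxon = v.group_reads_by_taxon(table, taxon)
        by_genus = v.group_reads_by_taxon(table, genus)
        n_major = len(v.select_major(table, 200))
        pd.Series(by_taxon, name="reads").rename_axis("taxon").sort_values(
            ascending=False
        ).to_csv(OUT / f"reads_by_taxon_{dataset}.tsv", sep="\t")
        pd.Series(by_genus, name="reads").rename_axis("genus").sort_values(
            ascending=False
        ).to_csv(OUT / f"reads_by_genus_{dataset}.tsv", sep="\t")
        print(f"{dataset}: {len(table)} ASVs, {table.total_reads} reads, "
              f"{n_major} major at the 200-read floor")

    lgc_taxon = v.group_reads_by_taxon(tables["LGC"], taxon)
    lgc_genus = v.group_reads_by_taxon(tables["LGC"], genus)
    print("LGC Ostreococcus lucimarinus reads:", lgc_taxon["Ostreococcus lucimarinus"])
    print("LGC Mantoniella genus reads:", lgc_genus["Mantoniella"])
    print("LGC Micromonas clade B5 reads:", lgc_taxon["Micromonas clade B5"])
    print("LGC Ostreococcus clade B reads:", lgc_taxon["Ostreococcus clade B"])
    print(f"wrote per-taxon and per-genus read tables to {OUT}")


if __name__ == "__main__":
    main()
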