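#!/usr/bin/env python
"""Relative abundance, prevalence and the latitudinal habitat summary.

Pools dataset-A ASV counts into clades via the signature assignments,
filters stations at the 100-group-read floor, computes percent-of-group
abundances, applies the 1% presence rule, and summarizes each clade's
occupied latitude bands. Writes tables under results/biogeography/.
"""

import importlib.util
from pathlib import Path

import pandas as pd

import v4clades as v

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("simulate_step", HERE / "01_simulate.py")
simulate_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(simulate_step)

OUT = HERE.parent / "results" / "biogeography"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    aln, labels, truth, meta, props, sims = simulate_step.simulate()

    table = v.dereplicate(sims["A"].reads, "A")
    major = v.select_major(table, 200)
    profiles = v.discover_signatures(aln, labels)
    clade_of = {
        a.asv_id: v.classify_by_signature(a.sequence, profiles).clade for a in major
    }
    counts = v.pool_by_taxon(major.to_frame(), clade_of)

    retained = v.filter_samples(meta, 100)
    print(f"stations retained at >=100 group reads: {len(retained)}/{len(meta)}")
    counts = counts.reindex(columns=retained.index, fill_value=0)
    abundance = v.relative_abundance(counts, retained["group_total_reads"])
    abundance.percents.round(2).to_csv(OUT / "relative_abundance_pct.tsv", sep="\t")

    mask = v.presence_mask(abundance, 1.0)
    prev = v.prevalence(mask)
    prev.to_csv(OUT / "prevalence.tsv", sep="\t")
    print("stations with >=1% of group reads, per clade:", prev.to_dict())

    summary = v.habitat_summary(mask, retained)
    summary.to_csv(OUT / "habitat_summary.tsv", sep="\t")
    niches = {c: n.band for c, n in truth.sample_niches.items()}
    print("planted niche bands:", niches)
    occupied = {
        t: [b for b in ("polar", "subpolar", "temperate", "tropical") if summary.loc[t, b]]
        for t in summary.index if t in niches
    }
    print("recovered occupied bands:", occupied)
    print(f"wrote abundance, prevalence and habitat tables to {OUT}")


if __name__ == "__main__":
    main()
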