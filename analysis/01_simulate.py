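#!/usr/bin/env python
"""Generate the synthetic two-dataset V4 survey used by the downstream steps.

Five clades over a 341-column V4-like reference alignment (2 diagnostic
columns each, 3 haplotypes per clade), 60 stations on a latitudinal
gradient with mean depth 1500 group reads, and two independently drawn read
datasets (A/B) at a 0.5% per-base error rate. Writes the reference
alignment, clade labels, station metadata and the planted truth tables
under results/synthetic/; the raw reads stay in memory for the later steps,
which regenerate them from the same seed.
"""

from pathlib import Path

import pandas as pd

import v4clades as v
from v4clades.signatures import profiles_to_frame

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def simulate(seed: int = SEED):
    aln, labels, truth = v.gen_reference_clades(seed=seed)
    meta, props = v.gen_samples(truth, n_samples=60, depth_mean=1500, seed=seed)
    sims = v.gen_reads(truth, props, meta, error_rate=0.005, seed=seed)
    return aln, labels, truth, meta, props, sims


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    aln, labels, truth, meta, props, sims = simulate()

    v.write_fasta(aln, OUT / "reference_aligned.fasta")
    pd.Series(labels, name="clade").rename_axis("sequence_id").to_csv(
        OUT / "clade_labels.tsv", sep="\t"
    )
    v.write_sample_metadata(meta, OUT / "sample_metadata.tsv")
    props.rename_axis("clade").to_csv(OUT / "true_proportions.tsv", sep="\t")
    diag = pd.DataFrame(
        [
            {"clade": c, "column": col, "character": ch}
            for c, s in truth.diagnostic_positions.items()
            for col, ch in sorted(s)
        ]
    )
    diag.to_csv(OUT / "planted_signatures.tsv", sep="\t", index=False)

    print(f"clades: {len(truth.clades)}, alignment: {aln.length} columns")
    print(f"planted diagnostic columns per clade: "
          f"{ {c: len(s) for c, s in truth.diagnostic_positions.items()} }")
    print(f"stations: {len(meta)}, mean depth {meta['group_total_reads'].mean():.0f}")
    for label, sim in sims.items():
        print(f"dataset {label}: {len(sim.reads)} reads")
    print(f"wrote reference, labels, metadata and truth to {OUT}")


if __name__ == "__main__":
    main()
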