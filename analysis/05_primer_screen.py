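#!/usr/bin/env python
"""In-silico qPCR screening of a synthetic assay against synthetic targets.

Builds a synthetic primer/probe set with a perfectly matching reference
amplicon, then a "novel clade" target carrying planted substitutions: one
in the forward site (at its 3' end), one in the probe site and two in the
reverse site — the mismatch pattern under which an assay designed for known
clades can fail to detect a newly delineated one. All sequences here are
synthetic. Writes the mismatch report under results/primers/.
"""

from pathlib import Path

import v4clades as v
from v4clades.primer_screen import reports_to_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "primers"

FORWARD = "GCCATTCGAACTGTGAT"
PROBE = "CCTACCGGACTAGGAT"
REVERSE_SITE = "GTACTGGACCTTAACGGA"  # sense strand of the reverse-primer site


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    pset = v.PrimerSet("SYN-I", FORWARD, PROBE, v.reverse_complement(REVERSE_SITE))
    reference = FORWARD + "ACGTACGT" + PROBE + "TTGCAAGG" + REVERSE_SITE

    novel = list(reference)
    novel[len(FORWARD) - 1] = "A"          # forward 3'-terminal base
    novel[len(FORWARD) + 8 + 2] = "G"      # probe position 3
    novel[-16] = "C"                       # two substitutions in the reverse site
    novel[-12] = "T"
    targets = {"known_clade_synthetic": reference,
               "novel_clade_synthetic": "".join(novel)}

    reports = [
        v.evaluate_primer_set(pset, seq, target_id=name, three_prime_window=3)
        for name, seq in targets.items()
    ]
    frame = reports_to_frame(reports)
    frame.to_csv(OUT / "mismatch_report.tsv", sep="\t", index=False)
    for rep in reports:
        counts = {k: r.mismatch_count for k, r in rep.oligos.items()}
        flags = [k for k, r in rep.oligos.items() if r.three_prime_flag]
        print(f"{rep.set_name} vs {rep.target_id}: per-oligo {counts}, "
              f"total {rep.total}, 3'-flagged: {flags or 'none'}")
    print(f"wrote mismatch report to {OUT}")


if __name__ == "__main__":
    main()
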