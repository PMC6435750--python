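"""In-silico qPCR primer/probe screening against target sequences.

Oligo binding is modelled as ungapped sliding-window placement: each oligo
is slid along the (sense or reverse-complemented) target, degenerate IUPAC
bases match by base-set intersection, and the best site is the one with the
fewest mismatches (ties resolved leftmost). Mismatches falling in the
3'-terminal window of a primer are flagged separately because they are the
ones most likely to abolish amplification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .signatures import IUPAC_SETS


class InvalidIUPACError(ValueError):
    pass


def _base_set(code: str) -> frozenset[str]:
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise InvalidIUPACError(f"invalid IUPAC code {code!r}") from None


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect.

    Degenerate-vs-degenerate comparisons count as matches whenever any
    concrete pairing is compatible (permissive convention).
    """
    return bool(_base_set(a) & _base_set(b))


_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    seq = sequence.upper()
    for ch in seq:
        if ch not in IUPAC_SETS:
            raise InvalidIUPACError(f"invalid IUPAC code {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BindingSite:
    """Best placement of one oligo on a target."""

    oligo: str
    orientation: str  # "sense" | "antisense"
    start: int  # 1-based position of the oligo 5' end on the scanned strand
    mismatch_positions: tuple[int, ...]  # 1-based from the oligo 5' end

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)

    def three_prime_flag(self, window: int = 3) -> bool:
        """Any mismatch within the 3'-terminal ``window`` bases of the oligo."""
        return any(p > len(self.oligo) - window for p in self.mismatch_positions)


def locate_and_count(oligo: str, target: str, orientation: str = "sense") -> BindingSite:
    """Slide an oligo along a normalized, ungapped target and score mismatches.

    ``antisense`` compares the oligo against the reverse complement of the
    target (the convention for a reverse primer written 5'->3'). The best
    site minimizes mismatches; ties go to the leftmost site.
    """
    if orientation not in ("sense", "antisense"):
        raise ValueError(f"orientation must be 'sense' or 'antisense', got {orientation!r}")
    oligo = oligo.upper()
    strand = target.upper() if orientation == "sense" else reverse_complement(target)
    if len(oligo) > len(strand):
        raise ValueError(
            f"oligo of length {len(oligo)} longer than target of length {len(strand)}"
        )
    oligo_sets = [_base_set(c) for c in oligo]
    best: tuple[int, int, tuple[int, ...]] | None = None  # (count, start, positions)
    for start in range(len(strand) - len(oligo) + 1):
        mism = tuple(
            i + 1
            for i, oset in enumerate(oligo_sets)
            if not (oset & _base_set(strand[start + i]))
        )
        if best is None or len(mism) < best[0]:
            best = (len(mism), start, mism)
            if not mism:
                break
    count, start, positions = best
    return BindingSite(oligo, orientation, start + 1, positions)


@dataclass(frozen=True)
class PrimerSet:
    """A qPCR assay: forward primer, hydrolysis probe, reverse primer (all 5'->3')."""

    name: str
    forward: str
    probe: str
    reverse: str

    def __post_init__(self) -> None:
        for role in ("forward", "probe", "reverse"):
            oligo = getattr(self, role)
            if not oligo:
                raise ValueError(f"{self.name}: empty {role} oligo")
            for ch in oligo.upper():
                if ch not in IUPAC_SETS:
                    raise InvalidIUPACError(
                        f"{self.name} {role}: invalid IUPAC code {ch!r}"
                    )


@dataclass(frozen=True)
class OligoResult:
    role: str
    binding_site_found: bool
    site: BindingSite | None
    three_prime_flag: bool | None

    @property
    def mismatch_count(self) -> int | None:
        return self.site.mismatch_count if self.site else None


@dataclass(frozen=True)
class MismatchReport:
    """Per-oligo mismatch profile of one primer set against one target."""

    set_name: str
    target_id: str
    oligos: Mapping[str, OligoResult]  # keys: forward, probe, reverse
    probe_orientation: str

    @property
    def total(self) -> int | None:
        counts = [r.mismatch_count for r in self.oligos.values()]
        if any(c is None for c in counts):
            return None
        return sum(counts)


def evaluate_primer_set(
    pset: PrimerSet,
    target: str,
    target_id: str = "target",
    three_prime_window: int = 3,
) -> MismatchReport:
    """Score a primer/probe set against one normalized target sequence.

    Forward primer and probe are evaluated sense, the reverse primer
    antisense. The probe is additionally tried antisense; the orientation
    with fewer mismatches is reported (hydrolysis probes may be designed on
    either strand). An unplaceable oligo yields
    ``binding_site_found=False`` with absent counts.
    """
    plan = [("forward", pset.forward, "sense"), ("reverse", pset.reverse, "antisense")]
    results: dict[str, OligoResult] = {}
    for role, oligo, orientation in plan:
        try:
            site = locate_and_count(oligo, target, orientation)
        except ValueError:
            results[role] = OligoResult(role, False, None, None)
            continue
        results[role] = OligoResult(role, True, site, site.three_prime_flag(three_prime_window))

    probe_orientation = "sense"
    try:
        probe_site = locate_and_count(pset.probe, target, "sense")
        anti = locate_and_count(pset.probe, target, "antisense")
        if anti.mismatch_count < probe_site.mismatch_count:
            probe_site, probe_orientation = anti, "antisense"
        results["probe"] = OligoResult(
            "probe", True, probe_site, probe_site.three_prime_flag(three_prime_window)
        )
    except ValueError:
        results["probe"] = OligoResult("probe", False, None, None)

    ordered = {k: results[k] for k in ("forward", "probe", "reverse")}
    return MismatchReport(pset.name, target_id, ordered, probe_orientation)


def read_primer_sets(path: str | Path) -> list[PrimerSet]:
    """Read primer sets from a TSV with columns name, forward, probe, reverse."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "forward", "probe", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing primer-set columns {sorted(missing)}")
    return [
        PrimerSet(r["name"], r["forward"], r["probe"], r["reverse"])
        for _, r in df.iterrows()
    ]


def reports_to_frame(reports: Sequence[MismatchReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for role, res in rep.oligos.items():
            rows.append(
                {
                    "set": rep.set_name,
                    "target": rep.target_id,
                    "oligo": role,
                    "binding_site_found": res.binding_site_found,
                    "mismatches": res.mismatch_count,
                    "mismatch_positions": ",".join(map(str, res.site.mismatch_positions))
                    if res.site
                    else "",
                    "three_prime_flag": res.three_prime_flag,
                    "total": rep.total,
                }
            )
    return pd.DataFrame(rows)
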