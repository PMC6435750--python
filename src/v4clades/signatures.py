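"""Diagnostic alignment signatures: discovery and clade assignment.

A signature is an alignment column at which every member of a clade carries
a character that no member of any other clade carries. A handful of such
fixed positions is enough to assign a query amplicon to a clade without
building a tree — mirroring how reference alignments of the V4 region show
"clear signatures" separating closely related picophytoplankton clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .formats_io import GAP, Alignment, SeqRecord

logger = logging.getLogger("v4clades")

#: IUPAC code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Concrete states a diagnostic character may take (gap is a real state:
#: indel signatures are visible in reference alignments).
_CANDIDATE_STATES = "ACGT-"


def _carries(observed: str, candidate: str) -> bool:
    """True if a sequence character is compatible with a candidate state.

    A member whose IUPAC ambiguity code covers the candidate base counts as
    carrying it (conservative: ambiguous references suppress diagnostics
    rather than create them). Gap is compatible only with gap.
    """
    observed = observed.upper()
    if candidate == GAP or observed == GAP:
        return observed == candidate
    try:
        return candidate in IUPAC_SETS[observed]
    except KeyError:
        raise ValueError(f"invalid IUPAC character {observed!r}") from None


@dataclass(frozen=True)
class SignaturePosition:
    column: int  # 1-based alignment column
    character: str
    exclusivity: str  # "strict" | "majority"


@dataclass(frozen=True)
class SignatureProfile:
    """The diagnostic (column, character) set of one clade, columns ascending."""

    clade: str
    positions: tuple[SignaturePosition, ...]

    def __post_init__(self) -> None:
        cols = [p.column for p in self.positions]
        if cols != sorted(cols):
            raise ValueError("signature positions must be sorted by column")

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(p.column for p in self.positions)


def discover_signatures(
    alignment: Alignment,
    labels: Mapping[str, str],
    mode: str = "strict",
    min_within_fraction: float = 0.9,
    allow_gap: bool = True,
) -> list[SignatureProfile]:
    """Find diagnostic alignment positions for every labelled clade.

    strict mode: a (column, character) is diagnostic for clade C iff all
    members of C carry the character there and no member of any other clade
    does. majority mode relaxes the within-clade requirement to
    ``min_within_fraction`` of members, still demanding zero carriers
    outside. Deterministic; returns one profile per clade (possibly empty),
    clades sorted by name.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"mode must be 'strict' or 'majority', got {mode!r}")
    missing = [r.id for r in alignment if r.id not in labels]
    if missing:
        raise KeyError(f"unlabelled sequences: {missing}")
    clades = sorted(set(labels[r.id] for r in alignment))
    if len(clades) < 2:
        raise ValueError("signature discovery needs at least 2 clades")
    members = {c: [r for r in alignment if labels[r.id] == c] for c in clades}
    for c, mem in members.items():
        if not mem:
            raise ValueError(f"clade {c!r} has no members")
    states = _CANDIDATE_STATES if allow_gap else _CANDIDATE_STATES.replace(GAP, "")

    profiles = []
    for clade in clades:
        inside = members[clade]
        outside = [r for c in clades if c != clade for r in members[c]]
        positions = []
        for col in range(1, alignment.length + 1):
            for state in states:
                n_in = sum(_carries(r.sequence[col - 1], state) for r in inside)
                if mode == "strict":
                    if n_in < len(inside):
                        continue
                elif n_in / len(inside) < min_within_fraction:
                    continue
                if any(_carries(r.sequence[col - 1], state) for r in outside):
                    continue
                positions.append(SignaturePosition(col, state, mode))
        profiles.append(SignatureProfile(clade, tuple(positions)))
        logger.info(
            "discover_signatures[%s]: %d diagnostic positions", clade, len(positions)
        )
    return profiles


@dataclass(frozen=True)
class SignatureAssignment:
    """Outcome of signature-based classification of one query."""

    query_id: str
    clade: str  # clade name, "unassigned" or "ambiguous"
    matched: int
    total: int
    per_clade: Mapping[str, tuple[int, int]]  # clade -> (matched, total)
    conflicts: tuple[int, ...]  # columns contradicting the winning clade


def classify_by_signature(
    query: SeqRecord | str,
    profiles: Sequence[SignatureProfile],
    min_match_fraction: float = 1.0,
) -> SignatureAssignment:
    """Assign an aligned query sequence to a clade by its signatures.

    The query must be in the same coordinate system as the reference
    alignment the profiles came from. The winner is the unique clade with
    the best match fraction at or above ``min_match_fraction``; a tie is
    reported as "ambiguous" (never broken), no qualifying clade as
    "unassigned". Clades with empty profiles cannot win.
    """
    qid = query.id if isinstance(query, SeqRecord) else "query"
    seq = query.sequence if isinstance(query, SeqRecord) else query
    max_col = max((p.column for prof in profiles for p in prof.positions), default=0)
    if len(seq) < max_col:
        raise ValueError(
            f"query {qid!r} of length {len(seq)} shorter than signature column {max_col}"
        )
    per_clade: dict[str, tuple[int, int]] = {}
    fractions: dict[str, float] = {}
    for prof in profiles:
        total = len(prof.positions)
        matched = sum(
            _carries(seq[p.column - 1], p.character) for p in prof.positions
        )
        per_clade[prof.clade] = (matched, total)
        if total > 0:
            fractions[prof.clade] = matched / total
    qualifying = {c: f for c, f in fractions.items() if f >= min_match_fraction}
    if not qualifying:
        return SignatureAssignment(qid, "unassigned", 0, 0, per_clade, ())
    best = max(qualifying.values())
    winners = sorted(c for c, f in qualifying.items() if f == best)
    if len(winners) > 1:
        return SignatureAssignment(qid, "ambiguous", 0, 0, per_clade, ())
    winner = winners[0]
    matched, total = per_clade[winner]
    prof = next(p for p in profiles if p.clade == winner)
    conflicts = tuple(
        p.column for p in prof.positions if not _carries(seq[p.column - 1], p.character)
    )
    return SignatureAssignment(qid, winner, matched, total, per_clade, conflicts)


def signature_report(
    profiles: Sequence[SignatureProfile], window: tuple[int, int]
) -> pd.DataFrame:
    """Tabulate diagnostic columns within a 1-based inclusive column window.

    Rows are diagnostic columns, one column per clade; blank cells mean the
    clade has no diagnostic character there.
    """
    start, end = window
    if start < 1 or end < start:
        raise ValueError(f"empty or invalid window {window}")
    clades = [p.clade for p in profiles]
    cols = sorted(
        {p.column for prof in profiles for p in prof.positions if start <= p.column <= end}
    )
    data = {c: ["" for _ in cols] for c in clades}
    for prof in profiles:
        for p in prof.positions:
            if start <= p.column <= end:
                data[prof.clade][cols.index(p.column)] = p.character
    df = pd.DataFrame(data, index=pd.Index(cols, name="column"))
    return df


def profiles_to_frame(profiles: Sequence[SignatureProfile]) -> pd.DataFrame:
    rows = [
        {"clade": prof.clade, "column": p.column, "character": p.character,
         "exclusivity": p.exclusivity}
        for prof in profiles
        for p in prof.positions
    ]
    return pd.DataFrame(rows, columns=["clade", "column", "character", "exclusivity"])
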