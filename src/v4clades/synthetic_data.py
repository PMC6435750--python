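"""Synthetic two-dataset amplicon study with planted, recoverable truth.

The generator emulates the statistical structure the rest of the pipeline
assumes about a coastal V4 metabarcoding survey:

* K clades whose aligned reference sequences differ by a few fixed,
  strictly exclusive diagnostic columns (alignment lengths in the
  ~330-370 bp range typical of the V4 region);
* a small amount of intra-clade haplotype variation at non-diagnostic
  columns;
* samples on a latitudinal gradient, each clade occupying one latitude
  band with some occupancy probability, and within-sample compositions
  drawn from a low-concentration Dirichlet so that one or two clades
  dominate a sample (clades rarely co-occur);
* two read datasets ("A" and "B") drawn from the *same* true haplotypes
  but with independent sequencing-error draws, mimicking two independently
  processed renditions of the same water samples;
* independent per-base substitution errors that create spurious
  low-count sequence variants.

Every generator is deterministic given its seed and returns the ground
truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biogeography import BANDS, DEFAULT_BAND_EDGES
from .formats_io import Alignment, SeqRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class CladeNiche:
    """Rectangular latitudinal niche: a band plus an occupancy probability."""

    band: str
    occupancy: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must be a probability")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic study."""

    clades: dict[str, str]  # clade -> consensus aligned sequence
    diagnostic_positions: dict[str, frozenset[tuple[int, str]]]
    haplotypes: dict[str, tuple[str, ...]]  # clade -> member (aligned) sequences
    sample_niches: dict[str, CladeNiche]
    true_abundances: pd.DataFrame | None  # clade x sample proportions
    error_rate: float
    seed: int

    def haplotype_sequences(self) -> dict[str, str]:
        """Flat map haplotype id -> ungapped sequence."""
        out = {}
        for clade, seqs in self.haplotypes.items():
            for i, s in enumerate(seqs):
                out[f"{clade}_h{i + 1}"] = s.replace("-", "")
        return out


def gen_reference_clades(
    k: int = 5,
    columns: int = 341,
    n_diag: int = 2,
    members_per_clade: int = 3,
    intra_variants: int = 1,
    seed: int = 42,
) -> tuple[Alignment, dict[str, str], SyntheticTruth]:
    """Generate a clade-labelled reference alignment with planted signatures.

    Each of the ``k`` clades receives ``n_diag`` exclusive diagnostic
    columns: all its members carry a character there that no other clade's
    member carries, so planted positions are *exactly* the strictly
    diagnostic ones. For k=2 the single non-focal clade is made polymorphic
    at a focal clade's diagnostic columns (a fixed state there would be a
    mirror signature of the non-focal clade); for k>=3 the other clades
    keep the shared consensus base, which cannot be exclusive to any one of
    them. Intra-clade variation (``intra_variants`` private substitutions
    per non-prototype member) is placed at globally unique non-diagnostic
    columns.

    Returns (alignment, labels id->clade, truth). The alignment is ungapped,
    so aligned and read coordinate systems coincide.
    """
    if k < 2:
        raise ValueError("need at least 2 clades")
    if n_diag < 1:
        raise ValueError("need at least 1 diagnostic column per clade")
    if members_per_clade < 2:
        raise ValueError(
            "members_per_clade must be >= 2: with singleton clades, private "
            "variant columns would become spurious strict signatures"
        )
    n_variant_cols = k * (members_per_clade - 1) * intra_variants
    if k * n_diag + n_variant_cols >= columns:
        raise ValueError(
            f"infeasible: {k}x{n_diag} diagnostic + {n_variant_cols} variant "
            f"columns do not fit in {columns} columns"
        )
    rng = np.random.default_rng(seed)
    consensus = rng.choice(list(_BASES), size=columns)
    clade_names = [f"clade_{chr(ord('A') + i)}" for i in range(k)]

    special = rng.choice(columns, size=k * n_diag + n_variant_cols, replace=False)
    diag_cols = {
        c: sorted(special[i * n_diag : (i + 1) * n_diag].tolist())
        for i, c in enumerate(clade_names)
    }
    variant_cols = list(special[k * n_diag :])

    # per-clade prototype rows, then per-member states at diagnostic columns
    proto = {c: consensus.copy() for c in clade_names}
    member_seqs = {
        c: [consensus.copy() for _ in range(members_per_clade)] for c in clade_names
    }
    diagnostic_positions: dict[str, set[tuple[int, str]]] = {c: set() for c in clade_names}
    for clade in clade_names:
        for col in diag_cols[clade]:
            base = consensus[col]
            diag_char, alt = rng.choice(
                [b for b in _BASES if b != base], size=2, replace=False
            )
            for m in member_seqs[clade]:
                m[col] = diag_char
            proto[clade][col] = diag_char
            # with k=2 a state fixed in the single non-focal clade would be a
            # mirror signature of that clade, so split its members between
            # two background states; with k>=3 the shared consensus base is
            # carried by several clades and cannot be diagnostic, and keeping
            # it fixed preserves the clades' phylogenetic coherence
            for other in clade_names:
                if other == clade:
                    continue
                for j, m in enumerate(member_seqs[other]):
                    m[col] = base if (k > 2 or j % 2 == 0) else alt
                proto[other][col] = base
            diagnostic_positions[clade].add((int(col) + 1, str(diag_char)))

    # private intra-clade variants at globally unique columns
    vi = 0
    for clade in clade_names:
        for member_idx in range(1, members_per_clade):
            for _ in range(intra_variants):
                col = variant_cols[vi]
                vi += 1
                current = member_seqs[clade][member_idx][col]
                member_seqs[clade][member_idx][col] = rng.choice(
                    [b for b in _BASES if b != current]
                )

    records = []
    labels: dict[str, str] = {}
    haplotypes: dict[str, tuple[str, ...]] = {}
    for clade in clade_names:
        seqs = tuple("".join(m) for m in member_seqs[clade])
        haplotypes[clade] = seqs
        for i, s in enumerate(seqs):
            hid = f"{clade}_h{i + 1}"
            records.append(SeqRecord(hid, s))
            labels[hid] = clade

    # cycle niches through the latitude bands, shared occupancy default
    niches = {
        c: CladeNiche(BANDS[i % len(BANDS)], 0.9) for i, c in enumerate(clade_names)
    }
    truth = SyntheticTruth(
        clades={c: "".join(proto[c]) for c in clade_names},
        diagnostic_positions={c: frozenset(v) for c, v in diagnostic_positions.items()},
        haplotypes=haplotypes,
        sample_niches=niches,
        true_abundances=None,
        error_rate=0.0,
        seed=seed,
    )
    return Alignment(tuple(records)), labels, truth


def gen_samples(
    truth: SyntheticTruth,
    n_samples: int = 100,
    lat_range: tuple[float, float] = (-75.0, 75.0),
    depth_mean: float = 5000.0,
    seed: int = 42,
    concentration: float = 0.3,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw sample metadata and true per-sample clade proportions.

    Latitudes are uniform over ``lat_range``; a clade can occur only in
    samples whose band matches its niche, with its occupancy probability.
    Among occupying clades the composition is Dirichlet(``concentration``)
    — small values make one or two clades dominate, emulating the observed
    rarity of co-occurrence. Group totals are Poisson around ``depth_mean``
    (floored at 1 read). If no clade occupies a sample, one band-matching
    clade (or, failing that, a random clade) is forced so proportions sum
    to 1.
    """
    from .biogeography import assign_band

    if n_samples < 1:
        raise ValueError("need at least 1 sample")
    rng = np.random.default_rng(seed)
    clades = list(truth.clades)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    lats = rng.uniform(lat_range[0], lat_range[1], size=n_samples)
    lons = rng.uniform(-180.0, 180.0, size=n_samples)
    depths = np.maximum(1, rng.poisson(depth_mean, size=n_samples))

    props = pd.DataFrame(0.0, index=clades, columns=sample_ids)
    for s, lat in zip(sample_ids, lats):
        band = assign_band(lat, band_edges)
        occupying = [
            c
            for c in clades
            if truth.sample_niches[c].band == band
            and rng.random() < truth.sample_niches[c].occupancy
        ]
        if not occupying:
            matching = [c for c in clades if truth.sample_niches[c].band == band]
            occupying = [matching[0] if matching else clades[rng.integers(len(clades))]]
        alpha = np.full(len(occupying), concentration)
        props.loc[occupying, s] = rng.dirichlet(alpha)

    meta = pd.DataFrame(
        {
            "latitude": lats,
            "longitude": lons,
            "group_total_reads": depths.astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return meta, props


@dataclass
class ReadSimResult:
    """Reads of one simulated dataset plus its realized composition."""

    dataset_label: str
    reads: list[tuple[SeqRecord, str]]  # (read record, sample id)
    clade_counts: pd.DataFrame  # clade x sample realized read counts
    haplotype_counts: pd.DataFrame  # haplotype id x sample realized counts


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def _emit_reads(
    hseq: str, m: int, error_rate: float, rng: np.random.Generator, chunk: int = 20000
) -> list[str]:
    """``m`` copies of a haplotype with independent per-base substitutions.

    Each base mutates with probability ``error_rate`` to one of the three
    other bases, uniformly. Vectorized over byte arrays so deep simulations
    stay cheap.
    """
    if m == 0:
        return []
    if error_rate == 0:
        return [hseq] * m
    base_idx = _BASE_LUT[np.frombuffer(hseq.encode(), dtype=np.uint8)]
    out: list[str] = []
    for start in range(0, m, chunk):
        mm = min(chunk, m - start)
        mask = rng.random((mm, len(hseq))) < error_rate
        arr = np.tile(base_idx, (mm, 1))
        nmut = int(mask.sum())
        if nmut:
            arr[mask] = (arr[mask] + rng.integers(1, 4, size=nmut, dtype=np.uint8)) % 4
        rows = _BASE_BYTES[arr]
        out.extend(row.tobytes().decode() for row in rows)
    return out


def gen_reads(
    truth: SyntheticTruth,
    proportions: pd.DataFrame,
    meta: pd.DataFrame,
    error_rate: float = 0.0,
    seed: int = 42,
    dataset_labels: tuple[str, str] = ("A", "B"),
) -> dict[str, ReadSimResult]:
    """Simulate the two independently sequenced datasets.

    Per sample, ``group_total_reads`` reads are drawn multinomially across
    clades (by the true proportions) and uniformly across each clade's
    haplotypes; both datasets share the identical true haplotype sequences
    but take independent count and error draws. Errors are independent
    per-base substitutions at ``error_rate`` (no indels).
    """
    if not 0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    clades = list(proportions.index)
    hap_by_clade = {
        c: [(f"{c}_h{i + 1}", s.replace("-", "")) for i, s in enumerate(truth.haplotypes[c])]
        for c in clades
    }
    root = np.random.default_rng(seed)
    out: dict[str, ReadSimResult] = {}
    for label in dataset_labels:
        rng = np.random.default_rng(root.integers(2**31))
        reads: list[tuple[SeqRecord, str]] = []
        clade_counts = pd.DataFrame(0, index=clades, columns=proportions.columns)
        hap_ids = [h for c in clades for h, _ in hap_by_clade[c]]
        hap_counts = pd.DataFrame(0, index=hap_ids, columns=proportions.columns)
        for sample in proportions.columns:
            depth = int(meta.loc[sample, "group_total_reads"])
            p = proportions[sample].to_numpy(dtype=float)
            if p.sum() <= 0:
                continue
            n_clade = rng.multinomial(depth, p / p.sum())
            r = 0
            for c, n in zip(clades, n_clade):
                if n == 0:
                    continue
                clade_counts.loc[c, sample] += int(n)
                haps = hap_by_clade[c]
                n_hap = rng.multinomial(n, np.full(len(haps), 1.0 / len(haps)))
                for (hid, hseq), m in zip(haps, n_hap):
                    if m == 0:
                        continue
                    hap_counts.loc[hid, sample] += int(m)
                    for seq in _emit_reads(hseq, int(m), error_rate, rng):
                        reads.append(
                            (SeqRecord(f"{label}_{sample}_r{r + 1:06d}", seq), sample)
                        )
                        r += 1
        out[label] = ReadSimResult(label, reads, clade_counts, hap_counts)
    return out
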