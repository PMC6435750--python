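import numpy as np
import pytest

import v4clades as v


def profile_map(profiles):
    return {p.clade: {(q.column, q.character) for q in p.positions} for p in profiles}


class TestDiscovery:
    def test_hand_enumerated_two_clades(self, toy_clades):
        aln, labels = toy_clades
        got = profile_map(v.discover_signatures(aln, labels))
        assert got == {"X": {(3, "G")}, "Y": {(3, "C")}}

    def test_identical_clades_have_no_signatures(self):
        aln = v.Alignment(tuple(v.SeqRecord(f"s{i}", "ACGTA") for i in range(4)))
        labels = {"s0": "X", "s1": "X", "s2": "Y", "s3": "Y"}
        got = profile_map(v.discover_signatures(aln, labels))
        assert got == {"X": set(), "Y": set()}

    @pytest.mark.parametrize("k,n_diag", [(2, 1), (3, 2), (5, 2)])
    def test_recovers_planted_columns_exactly(self, k, n_diag):
        aln, labels, truth = v.gen_reference_clades(
            k=k, columns=80, n_diag=n_diag, seed=11
        )
        got = profile_map(v.discover_signatures(aln, labels))
        assert got == {c: set(s) for c, s in truth.diagnostic_positions.items()}

    def test_order_and_renaming_invariance(self):
        aln, labels, _ = v.gen_reference_clades(k=3, columns=60, seed=3)
        got = profile_map(v.discover_signatures(aln, labels))
        rng = np.random.default_rng(0)
        perm = list(aln.records)
        rng.shuffle(perm)
        renamed = v.Alignment(tuple(v.SeqRecord(f"z_{r.id}", r.sequence) for r in perm))
        relabels = {f"z_{rid}": c for rid, c in labels.items()}
        got2 = profile_map(v.discover_signatures(renamed, relabels))
        assert got == got2

    def test_adding_member_only_shrinks_position_sets(self, toy_clades):
        aln, labels = toy_clades
        before = profile_map(v.discover_signatures(aln, labels))
        extra = v.SeqRecord("x3", "ACGTT")  # new X member, polymorphic col 5
        aln2 = v.Alignment(aln.records + (extra,))
        labels2 = dict(labels, x3="X")
        after = profile_map(v.discover_signatures(aln2, labels2))
        for clade in before:
            assert after[clade] <= before[clade]

    def test_gap_is_a_legitimate_diagnostic_state(self):
        aln = v.Alignment(
            (
                v.SeqRecord("x1", "AC-TA"), v.SeqRecord("x2", "AC-TA"),
                v.SeqRecord("y1", "ACGTA"), v.SeqRecord("y2", "ACGTA"),
            )
        )
        labels = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
        got = profile_map(v.discover_signatures(aln, labels))
        assert got["X"] == {(3, "-")}
        got_nogap = profile_map(v.discover_signatures(aln, labels, allow_gap=False))
        assert got_nogap["X"] == set()

    def test_ambiguity_code_counts_as_carrier(self, toy_clades):
        # an R (=A/G) in clade Y at the diagnostic column of X kills X's signature
        aln, labels = toy_clades
        recs = list(aln.records)
        recs[2] = v.SeqRecord("y1", "ACRTA")
        got = profile_map(v.discover_signatures(v.Alignment(tuple(recs)), labels))
        assert got["X"] == set()

    def test_empty_clade_rejected(self, toy_clades):
        aln, labels = toy_clades
        with pytest.raises((ValueError, KeyError)):
            v.discover_signatures(aln, {k: "X" for k in labels})

    def test_majority_mode_tolerates_minority_deviation(self):
        recs = tuple(
            v.SeqRecord(f"x{i}", "ACGTA") for i in range(4)
        ) + (v.SeqRecord("x4", "ACTTA"),) + tuple(
            v.SeqRecord(f"y{i}", "ACCTA") for i in range(3)
        )
        labels = {r.id: ("X" if r.id.startswith("x") else "Y") for r in recs}
        aln = v.Alignment(recs)
        strict = profile_map(v.discover_signatures(aln, labels))
        assert strict["X"] == set()
        maj = profile_map(
            v.discover_signatures(aln, labels, mode="majority", min_within_fraction=0.75)
        )
        assert (3, "G") in maj["X"]


class TestClassification:
    def test_round_trip_members_classify_home(self):
        aln, labels, _ = v.gen_reference_clades(k=4, columns=100, seed=9)
        profiles = v.discover_signatures(aln, labels)
        for rec in aln:
            res = v.classify_by_signature(rec, profiles)
            assert res.clade == labels[rec.id]
            assert res.matched == res.total and not res.conflicts

    def test_novel_state_is_unassigned(self, toy_clades):
        aln, labels = toy_clades
        profiles = v.discover_signatures(aln, labels)
        assert v.classify_by_signature("ACTTA", profiles).clade == "unassigned"

    def test_shared_profiles_tie_is_ambiguous(self):
        from v4clades.signatures import SignaturePosition, SignatureProfile

        pos = (SignaturePosition(2, "C", "strict"),)
        profiles = [SignatureProfile("P", pos), SignatureProfile("Q", pos)]
        assert v.classify_by_signature("ACGT", profiles).clade == "ambiguous"

    def test_query_shorter_than_signature_column_rejected(self, toy_clades):
        aln, labels = toy_clades
        profiles = v.discover_signatures(aln, labels)
        with pytest.raises(ValueError, match="shorter"):
            v.classify_by_signature("AC", profiles)

    def test_accuracy_degrades_monotonically_with_error_rate(self):
        aln, labels, truth = v.gen_reference_clades(k=5, columns=341, seed=21)
        profiles = v.discover_signatures(aln, labels)
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        accuracies = []
        for e in (0.0, 0.01, 0.05):
            hits = trials = 0
            for clade, proto in truth.clades.items():
                arr = np.array(list(proto))
                for _ in range(200):
                    seq = arr.copy()
                    mask = rng.random(len(seq)) < e
                    if mask.any():
                        seq[mask] = bases[rng.integers(0, 4, mask.sum())]
                    res = v.classify_by_signature("".join(seq), profiles)
                    hits += res.clade == clade
                    trials += 1
            accuracies.append(hits / trials)
        assert accuracies[0] == 1.0
        assert accuracies[0] >= accuracies[1] >= accuracies[2]


class TestReport:
    def test_window_restricts_columns(self):
        aln, labels, truth = v.gen_reference_clades(k=3, columns=50, n_diag=2, seed=2)
        profiles = v.discover_signatures(aln, labels)
        all_cols = sorted({p.column for pr in profiles for p in pr.positions})
        full = v.signature_report(profiles, (1, 50))
        assert list(full.index) == all_cols
        lo, hi = all_cols[0], all_cols[-1]
        windowed = v.signature_report(profiles, (lo, hi - 1))
        assert list(windowed.index) == [c for c in all_cols if c < hi]

    def test_window_without_diagnostics_is_empty(self, toy_clades):
        aln, labels = toy_clades
        profiles = v.discover_signatures(aln, labels)
        assert v.signature_report(profiles, (1, 1)).empty

    def test_invalid_window_rejected(self, toy_clades):
        aln, labels = toy_clades
        profiles = v.discover_signatures(aln, labels)
        with pytest.raises(ValueError):
            v.signature_report(profiles, (5, 4))
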