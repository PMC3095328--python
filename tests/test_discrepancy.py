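"""Discrepancy census: anchored alignment, classification, run census, rate.

The alignment oracle here is an independent, unanchored global
affine-gap dynamic program (score only), written against the same
scoring scheme the package declares.
"""

from collections import Counter

import numpy as np
import pytest

from bacpool import discrepancy, simdata
from bacpool.discrepancy import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    align_locus,
    build_report,
    classify,
    rate,
    run_census,
)

NEG = -1e18


def gotoh_score(a, b):
    """Unanchored global affine alignment score (independent oracle)."""
    n, m = len(a), len(b)
    M = np.full(m + 1, NEG); X = np.full(m + 1, NEG); Y = np.full(m + 1, NEG)
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        Mp, Xp, Yp = M.copy(), X.copy(), Y.copy()
        M[:] = NEG; X[:] = NEG; Y[:] = NEG
        X[0] = GAP_OPEN + (i - 1) * GAP_EXTEND
        for j in range(1, m + 1):
            s = MATCH if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else MISMATCH
            M[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            X[j] = max(Mp[j] + GAP_OPEN, Xp[j] + GAP_EXTEND, Yp[j] + GAP_OPEN)
            Y[j] = max(M[j - 1] + GAP_OPEN, Y[j - 1] + GAP_EXTEND, X[j - 1] + GAP_OPEN)
    return max(M[m], X[m], Y[m])


def random_dna(n, seed, gc=0.4):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestAlignLocus:
    def test_identical_sequences_no_differences(self):
        seq = random_dna(1000, 1)
        aln = align_locus(seq, seq)
        assert aln.ref_aln == aln.test_aln == seq
        assert not aln.excluded.any()
        assert classify(aln, seq) == []

    def test_n_masked_interval_excluded(self):
        ref = random_dna(2000, 2)
        test = ref[:900] + "N" * 100 + ref[1000:]
        aln = align_locus(ref, test)
        assert aln.excluded_ref_intervals() == [(900, 1000)]
        recs = classify(aln, ref)
        assert [r.kind for r in recs] == ["n_gap_excluded"]

    def test_unrelated_sequences_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            align_locus(random_dna(500, 3), random_dna(500, 4, gc=0.6))

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_unanchored_oracle(self, seed):
        """On short near-identical pairs, the anchored path reaches the
        optimum of a full dynamic program with the same scoring."""
        rng = np.random.default_rng(seed + 100)
        ref = random_dna(400, seed)
        test = list(ref)
        for _ in range(4):  # a few substitutions and small indels
            p = int(rng.integers(50, 350))
            op = rng.integers(0, 3)
            if op == 0:
                test[p] = "ACGT"[(("ACGT".index(test[p])) + 1) % 4]
            elif op == 1:
                test[p] = ""
            else:
                test[p] = test[p] + "ACGT"[int(rng.integers(0, 4))]
        test = "".join(test)
        aln = align_locus(ref, test)
        assert aln.score == gotoh_score(ref, test)

    def test_planted_events_isolated(self):
        ref = simdata.make_accuracy_locus(length=30_000, n_long_runs=8,
                                          n_dinuc=1, dinuc_units=(15,), seed=6)
        prof = simdata.ErrorProfile(seed=2, n_gap_rate=5.0,
                                    dinucleotide_perturb_prob=1.0)
        test, events = simdata.inject_errors(ref, prof)
        recs = classify(align_locus(ref, test), ref)
        planted = Counter(e.kind for e in events if e.kind != "n_gap")
        found = Counter(r.kind for r in recs if r.kind not in ("n_gap_excluded",))
        assert found == planted
        assert sorted(r.ref_pos for r in recs if r.kind == "homopolymer") == sorted(
            e.position for e in events if e.kind == "homopolymer"
        )


class TestClassify:
    def test_homopolymer_contraction_record(self):
        ref = "CGTG" * 40 + "A" * 14 + "TCGC" * 40
        test = "CGTG" * 40 + "A" * 13 + "TCGC" * 40
        recs = classify(align_locus(ref, test), ref)
        assert len(recs) == 1
        r = recs[0]
        assert r.kind == "homopolymer"
        assert (r.ref_motif, r.ref_run_len, r.test_run_len, r.delta_bp) == ("A", 14, 13, -1)

    def test_dinucleotide_array_change(self):
        flank_l = random_dna(300, 7)
        flank_r = random_dna(300, 8)
        ref = flank_l + "GA" * 21 + flank_r
        # consensus keeps the array but with extra filler and an N stretch,
        # the signature of a collapsed repeat region
        test = flank_l + "GA" * 21 + "GTAGTACGTAC" + "N" * 23 + "GA" * 6 + flank_r
        recs = classify(align_locus(ref, test), ref)
        kinds = Counter(r.kind for r in recs)
        assert kinds["dinucleotide_repeat"] == 1
        assert kinds.get("homopolymer", 0) == 0
        di = next(r for r in recs if r.kind == "dinucleotide_repeat")
        assert di.ref_motif in ("GA", "AG")

    def test_point_substitution(self):
        ref = random_dna(600, 9)
        pos = 300
        repl = "A" if ref[pos] != "A" else "G"
        # guard against touching a run: force unique context
        test = ref[:pos] + repl + ref[pos + 1 :]
        recs = classify(align_locus(ref, test), ref)
        subs = [r for r in recs if r.kind == "substitution"]
        assert len(subs) == 1 and subs[0].ref_pos == pos

    def test_no_column_double_counted(self):
        ref = simdata.make_accuracy_locus(length=20_000, n_long_runs=6,
                                          n_dinuc=1, seed=3)
        test, _ = simdata.inject_errors(
            ref, simdata.ErrorProfile(seed=5, n_gap_rate=5.0)
        )
        aln = align_locus(ref, test)
        recs = classify(aln, ref)
        n_diff_cols = sum(
            1 for rc, tc, ex in zip(aln.ref_aln, aln.test_aln, aln.excluded)
            if rc != tc and not ex
        )
        covered = sum(
            abs(r.delta_bp) if r.kind in ("homopolymer", "dinucleotide_repeat", "other_indel")
            else 1
            for r in recs if r.kind not in ("n_gap_excluded",)
        )
        assert covered == n_diff_cols


class TestRunCensus:
    def test_small_example(self):
        census = run_census("AAAACCCCC", [])
        assert census.run_counts["A/T"] == {4: 1}
        assert census.run_counts["C/G"] == {5: 1}

    def test_no_discrepancies_in_short_runs(self):
        """Error profiles that only touch runs >= 11 leave every run <= 10
        clean in the census."""
        ref = simdata.make_accuracy_locus(length=40_000, n_long_runs=10,
                                          n_short_runs=40, n_dinuc=0, seed=12)
        test, events = simdata.inject_errors(
            ref, simdata.ErrorProfile(seed=8, n_gap_rate=0.0,
                                      dinucleotide_perturb_prob=0.0)
        )
        recs = classify(align_locus(ref, test), ref)
        census = run_census(ref, recs)
        for cls in ("A/T", "C/G"):
            assert sum(n for l, n in census.discrepant_counts[cls].items() if l <= 10) == 0
        # and the per-length discrepant counts equal the planted counts
        planted = Counter(e.ref_len for e in events if e.kind == "homopolymer")
        found = Counter()
        for cls in ("A/T", "C/G"):
            found.update(census.discrepant_counts[cls])
        assert found == planted

    def test_record_must_reference_a_run(self):
        rec = discrepancy.DiscrepancyRecord("homopolymer", 999, "A", 5, "A", 4, -1)
        with pytest.raises(ValueError, match="no run"):
            run_census("AAATTT", [rec])

    def test_report_binning(self):
        ref = "A" * 5 + "C" + "T" * 12 + "G" * 6 + "A" * 3
        census = run_census(ref, [])
        rows = census.report_rows()
        assert ("A/T", "<=10", 2, 0) in rows
        assert ("A/T", "12", 1, 0) in rows
        assert ("C/G", "5-7", 1, 0) in rows


class TestRate:
    def test_printed_arithmetic(self):
        assert rate(98_716, 15, 2) == 1.7

    def test_edge_cases(self):
        assert rate(10_000, 0, 0) == 0.0
        assert rate(10_000, 5, 0) == 5.0
        with pytest.raises(ValueError):
            rate(0, 1, 0)

    def test_counts_only_repeat_classes(self):
        recs = [
            discrepancy.DiscrepancyRecord("substitution", 0, "A", 1, "C", 1, 0),
            discrepancy.DiscrepancyRecord("homopolymer", 5, "T", 12, "T", 11, -1),
        ]
        assert rate(10_000, recs) == 1.0


def test_build_report_end_to_end():
    ref = simdata.make_accuracy_locus(length=30_000, n_long_runs=8, n_dinuc=2, seed=21)
    test, events = simdata.inject_errors(
        ref, simdata.ErrorProfile(seed=22, n_gap_rate=5.0)
    )
    rep = build_report(ref, test)
    assert rep.ref_length == len(ref)
    assert rep.n_stretches == sum(1 for e in events if e.kind == "n_gap")
    n_expected = sum(1 for e in events if e.kind in ("homopolymer", "dinucleotide_repeat"))
    assert rep.homopolymer_discrepancies + rep.dinucleotide_discrepancies == n_expected
    assert rep.rate_per_10kb == rate(len(ref), n_expected, 0)
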