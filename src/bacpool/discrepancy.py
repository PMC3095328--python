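"""Sanger-vs-pyrosequencing discrepancy census for a shared locus.

Two versions of the same region (a finished reference and an assembly
consensus that may contain N stretches) are globally aligned with an
anchored strategy: exact shared 31-mers that are unique in both sequences
are chained co-linearly and the gaps between consecutive anchors are
closed with an affine-gap dynamic program (match +1, mismatch -2, first
gap base -4, each further gap base -1).  Columns falling in N stretches of
the test sequence are excluded from the census.

Differences are then classified the way a finishing team reads them:
length changes in mononucleotide runs (homopolymers, the dominant
pyrosequencing error mode), length changes inside perfect dinucleotide
tandem arrays, point substitutions, and other indels.  The summary rate
counts only the homopolymer and dinucleotide classes, per 10 kb of
reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._util import base_runs, round_half_up
from .asmetrics import gap_stats
from .simdata import _dinucleotide_arrays

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4   # cost of the first base of a gap
GAP_EXTEND = -1  # cost of each subsequent base

ANCHOR_K = 31
DINUC_MIN_UNITS = 6
NEG_INF = float("-inf")


@dataclass
class LocusAlignment:
    ref_aln: str
    test_aln: str
    excluded: np.ndarray  # bool per column
    score: float
    ref_len: int
    test_len: int

    def __post_init__(self) -> None:
        assert len(self.ref_aln) == len(self.test_aln) == len(self.excluded)

    def ref_positions(self) -> np.ndarray:
        """Ref coordinate of each column (position of the ref char, or of
        the next ref char for gap-in-ref columns)."""
        isref = np.frombuffer(self.ref_aln.encode(), dtype=np.uint8) != ord("-")
        return np.cumsum(isref) - isref.astype(int)

    def excluded_ref_intervals(self) -> list[tuple[int, int]]:
        """Maximal excluded stretches as ref-coordinate intervals."""
        pos = self.ref_positions()
        out = []
        i, n = 0, len(self.excluded)
        while i < n:
            if self.excluded[i]:
                j = i
                while j < n and self.excluded[j]:
                    j += 1
                lo = int(pos[i])
                hi = int(pos[j - 1]) + (1 if self.ref_aln[j - 1] != "-" else 0)
                out.append((lo, max(hi, lo)))
                i = j
            else:
                i += 1
        return out


@dataclass
class DiscrepancyRecord:
    kind: str                 # homopolymer | dinucleotide_repeat | substitution |
                              # other_indel | n_gap_excluded
    ref_pos: int
    ref_motif: str
    ref_run_len: int
    test_motif: str
    test_run_len: int
    delta_bp: int
    excluded_interval: tuple[int, int] | None = None


@dataclass
class RunCensus:
    run_counts: dict = field(default_factory=dict)        # class -> {len: n}
    discrepant_counts: dict = field(default_factory=dict)  # class -> {len: n}
    discrepant_motifs: dict = field(default_factory=dict)  # (class, len) -> [motif]

    def report_rows(self) -> list[tuple[str, str, int, int]]:
        """Table view: (class, length-bin, total runs, discrepant runs);
        A/T lengths <= 10 and C/G lengths 5-7 are binned together."""
        rows = []
        for cls in ("A/T", "C/G"):
            counts = self.run_counts.get(cls, {})
            disc = self.discrepant_counts.get(cls, {})
            if cls == "A/T":
                binned = sum(n for l, n in counts.items() if l <= 10)
                dbinned = sum(n for l, n in disc.items() if l <= 10)
                if binned:
                    rows.append((cls, "<=10", binned, dbinned))
                longs = sorted(l for l in counts if l > 10)
            else:
                binned = sum(n for l, n in counts.items() if 5 <= l <= 7)
                dbinned = sum(n for l, n in disc.items() if 5 <= l <= 7)
                if binned:
                    rows.append((cls, "5-7", binned, dbinned))
                longs = sorted(l for l in counts if l > 7)
            for l in longs:
                rows.append((cls, str(l), counts[l], disc.get(l, 0)))
        return rows


@dataclass
class AccuracyReport:
    ref_length: int
    n_stretches: int
    n_stretch_bp: int
    n_stretch_pct: float
    homopolymer_discrepancies: int
    dinucleotide_discrepancies: int
    rate_per_10kb: float
    records: list[DiscrepancyRecord] = field(default_factory=list)
    census: RunCensus | None = None


def _gotoh(a: str, b: str) -> tuple[str, str, float]:
    """Global affine-gap alignment of two (short) segments.

    Gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND.  N mismatches
    every base including N.  Ties resolved deterministically
    (diagonal > gap-in-b > gap-in-a).
    """
    n, m = len(a), len(b)
    if n == 0:
        return "-" * m, b, (GAP_OPEN + (m - 1) * GAP_EXTEND if m else 0.0)
    if m == 0:
        return a, "-" * n, GAP_OPEN + (n - 1) * GAP_EXTEND

    def sub(x: str, y: str) -> int:
        return MATCH if (x == y and x != "N") else MISMATCH

    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                          X[i, j - 1] + GAP_OPEN)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    score = [M[i, j], X[i, j], Y[i, j]][state]
    ra, rb = [], []
    while i > 0 or j > 0:
        if state == 0:
            s = sub(a[i - 1], b[j - 1])
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            ra.append(a[i - 1]); rb.append(b[j - 1])
            i -= 1; j -= 1
        elif state == 1:
            cand = [M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                    Y[i - 1, j] + GAP_OPEN]
            state = int(np.argmax(cand))
            ra.append(a[i - 1]); rb.append("-")
            i -= 1
        else:
            cand = [M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                    X[i, j - 1] + GAP_OPEN]
            state = [0, 2, 1][int(np.argmax(cand))]
            ra.append("-"); rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), float(score)


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        if kmer in seen:
            dup.add(kmer)
        else:
            seen[kmer] = i
    for kmer in dup:
        del seen[kmer]
    return seen


def _chain_anchors(ref: str, test: str, k: int) -> list[tuple[int, int, int]]:
    """Co-linear chain of shared unique k-mers, merged into maximal exact
    blocks (ref_start, test_start, length)."""
    uref = _unique_kmer_positions(ref, k)
    utest = _unique_kmer_positions(test, k)
    matches = sorted(
        (pr, utest[kmer]) for kmer, pr in uref.items() if kmer in utest
    )
    if not matches:
        return []
    # longest strictly-increasing subsequence on the test coordinate
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(matches)
    for idx, (_, pt) in enumerate(matches):
        pos = bisect.bisect_left(tails, pt)
        if pos == len(tails):
            tails.append(pt)
            tails_idx.append(idx)
        else:
            tails[pos] = pt
            tails_idx[pos] = idx
        parent[idx] = tails_idx[pos - 1] if pos > 0 else -1
    chain = []
    at = tails_idx[-1]
    while at != -1:
        chain.append(matches[at])
        at = parent[at]
    chain.reverse()
    # merge into exact blocks; drop anchors conflicting with the running block
    blocks: list[list[int]] = []
    for pr, pt in chain:
        if blocks:
            r0, t0, ln = blocks[-1]
            if pr - pt == r0 - t0 and pr <= r0 + ln:
                blocks[-1][2] = pr + k - r0
                continue
            if pr < r0 + ln or pt < t0 + ln:
                continue
        blocks.append([pr, pt, k])
    return [tuple(b) for b in blocks]


def align_locus(ref: str, test: str, k: int = ANCHOR_K) -> LocusAlignment:
    """Anchored global alignment of a reference locus and a test consensus.

    Raises ``ValueError`` (with a rough identity estimate) when no shared
    unique k-mer anchors exist, i.e. the sequences look unrelated.
    """
    if not ref or not test:
        raise ValueError("both sequences must be non-empty")
    ref = ref.upper()
    test = test.upper()
    blocks = _chain_anchors(ref, test, k)
    if not blocks:
        import edlib

        d = edlib.align(ref, test, task="distance")["editDistance"]
        ident = 100.0 * (1 - d / max(len(ref), len(test)))
        raise ValueError(
            f"no shared unique {k}-mer anchors; sequences look unrelated "
            f"(approx. identity {ident:.1f}%)"
        )
    ra_parts: list[str] = []
    ta_parts: list[str] = []
    score = 0.0
    pr = pt = 0
    for r0, t0, ln in blocks:
        if r0 > pr or t0 > pt:
            sa, sb, s = _gotoh(ref[pr:r0], test[pt:t0])
            ra_parts.append(sa)
            ta_parts.append(sb)
            score += s
        ra_parts.append(ref[r0 : r0 + ln])
        ta_parts.append(test[t0 : t0 + ln])
        score += MATCH * ln
        pr, pt = r0 + ln, t0 + ln
    if pr < len(ref) or pt < len(test):
        sa, sb, s = _gotoh(ref[pr:], test[pt:])
        ra_parts.append(sa)
        ta_parts.append(sb)
        score += s
    ref_aln = "".join(ra_parts)
    test_aln = "".join(ta_parts)
    excluded = np.frombuffer(test_aln.encode(), dtype=np.uint8) == ord("N")
    # pull flanking indel columns of an N stretch into the excluded zone
    exc = excluded.copy()
    n = len(exc)
    for i in range(n):
        if not exc[i] and (test_aln[i] == "-" or ref_aln[i] == "-"):
            if (i > 0 and exc[i - 1]) or (i + 1 < n and excluded[i + 1]):
                exc[i] = True
    return LocusAlignment(ref_aln, test_aln, exc, score, len(ref), len(test))


def _find_run(ref: str, pos: int, base: str) -> tuple[int, int] | None:
    """Maximal run of ``base`` in ref touching position ``pos`` (leftmost
    attribution: the run ending at pos is preferred over one starting
    after it)."""
    n = len(ref)
    for p in (pos - 1, pos):
        if 0 <= p < n and ref[p] == base:
            s = p
            while s > 0 and ref[s - 1] == base:
                s -= 1
            e = p + 1
            while e < n and ref[e] == base:
                e += 1
            return s, e
    return None


def classify(alignment: LocusAlignment, ref: str | None = None) -> list[DiscrepancyRecord]:
    """Classify alignment differences into discrepancy records.

    Difference columns are grouped into blocks (bridging excluded
    columns), each block becoming one homopolymer or dinucleotide-repeat
    record when the evidence supports it, otherwise per-column
    substitution/other_indel records.  Every maximal excluded stretch is
    additionally reported as an ``n_gap_excluded`` record.
    """
    if ref is None:
        ref = alignment.ref_aln.replace("-", "")
    records: list[DiscrepancyRecord] = []
    for lo, hi in alignment.excluded_ref_intervals():
        records.append(
            DiscrepancyRecord(
                kind="n_gap_excluded", ref_pos=lo, ref_motif="N",
                ref_run_len=hi - lo, test_motif="N", test_run_len=hi - lo,
                delta_bp=0, excluded_interval=(lo, hi),
            )
        )

    ra, ta = alignment.ref_aln, alignment.test_aln
    exc = alignment.excluded
    pos = alignment.ref_positions()
    n = len(ra)
    is_diff = np.fromiter(
        ((ra[i] != ta[i]) and not exc[i] for i in range(n)), dtype=bool, count=n
    )
    dinuc_arrays = _dinucleotide_arrays(ref, DINUC_MIN_UNITS)

    # group difference columns, merging runs separated only by excluded cols
    blocks: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if is_diff[i]:
            j = i
            end = i + 1
            while j + 1 < n and (is_diff[j + 1] or exc[j + 1]):
                j += 1
                if is_diff[j]:
                    end = j + 1
            blocks.append((i, end))
            i = j + 1
        else:
            i += 1

    for lo, hi in blocks:
        cols = range(lo, hi)
        ins = [ta[c] for c in cols if ra[c] == "-" and not exc[c]]
        dels = [ra[c] for c in cols if ta[c] == "-" and not exc[c]]
        mism = [c for c in cols if ra[c] != "-" and ta[c] != "-" and ra[c] != ta[c] and not exc[c]]
        r_lo, r_hi = int(pos[lo]), int(pos[hi - 1]) + (1 if ra[hi - 1] != "-" else 0)
        indel_chars = set(ins) | set(dels)

        if not mism and len(indel_chars) == 1 and "N" not in indel_chars:
            base = indel_chars.pop()
            run = _find_run(ref, r_lo, base)
            if run is not None and run[1] - run[0] >= 2:
                s, e = run
                ref_run = e - s
                delta = len(ins) - len(dels)
                records.append(
                    DiscrepancyRecord(
                        kind="homopolymer", ref_pos=s, ref_motif=base,
                        ref_run_len=ref_run, test_motif=base,
                        test_run_len=ref_run + delta, delta_bp=delta,
                    )
                )
                continue

        hit = next(
            (arr for arr in dinuc_arrays if arr[0] <= r_hi + 1 and r_lo <= arr[1] + 1),
            None,
        )
        if hit is not None:
            s, e, unit = hit
            # delta over the whole block, excluded columns included (the
            # test-side N filler is part of the repeat-region difference)
            t_len = sum(1 for c in cols if ta[c] != "-")
            r_len = sum(1 for c in cols if ra[c] != "-")
            records.append(
                DiscrepancyRecord(
                    kind="dinucleotide_repeat", ref_pos=s, ref_motif=unit,
                    ref_run_len=e - s, test_motif=unit,
                    test_run_len=(e - s) + (t_len - r_len),
                    delta_bp=t_len - r_len,
                )
            )
            continue

        # fall back to per-column records
        c = lo
        while c < hi:
            if exc[c] or ra[c] == ta[c]:
                c += 1
            elif ra[c] != "-" and ta[c] != "-":
                records.append(
                    DiscrepancyRecord(
                        kind="substitution", ref_pos=int(pos[c]), ref_motif=ra[c],
                        ref_run_len=1, test_motif=ta[c], test_run_len=1, delta_bp=0,
                    )
                )
                c += 1
            else:
                d = c
                while d < hi and not exc[d] and (ra[d] == "-" or ta[d] == "-"):
                    d += 1
                ins_n = sum(1 for x in range(c, d) if ra[x] == "-")
                del_n = sum(1 for x in range(c, d) if ta[x] == "-")
                records.append(
                    DiscrepancyRecord(
                        kind="other_indel", ref_pos=int(pos[c]),
                        ref_motif=ref[int(pos[c]) : int(pos[c]) + del_n] or "-",
                        ref_run_len=del_n,
                        test_motif="".join(ta[x] for x in range(c, d) if ra[x] == "-") or "-",
                        test_run_len=ins_n, delta_bp=ins_n - del_n,
                    )
                )
                c = d
    return records


def run_census(ref: str, records: list[DiscrepancyRecord]) -> RunCensus:
    """Count maximal mononucleotide runs of the reference per base class
    and length, joining homopolymer discrepancy records to their runs."""
    census = RunCensus(
        run_counts={"A/T": Counter(), "C/G": Counter()},
        discrepant_counts={"A/T": Counter(), "C/G": Counter()},
        discrepant_motifs={},
    )
    run_index: dict[int, tuple[int, str]] = {}
    for s, e, base in base_runs(ref):
        cls = "A/T" if base in "AT" else "C/G"
        census.run_counts[cls][e - s] += 1
        run_index[s] = (e - s, base)
    for rec in records:
        if rec.kind != "homopolymer":
            continue
        if rec.ref_pos not in run_index:
            raise ValueError(
                f"record at ref position {rec.ref_pos} references no run in ref"
            )
        length, base = run_index[rec.ref_pos]
        cls = "A/T" if base in "AT" else "C/G"
        census.discrepant_counts[cls][length] += 1
        motif = f"({cls if length > 0 else base})_{rec.test_run_len}"
        census.discrepant_motifs.setdefault((cls, length), []).append(motif)
    return census


def rate(ref_length: int, records: list[DiscrepancyRecord] | int,
         n_dinucleotide: int | None = None) -> float:
    """Discrepancies per 10 kb, one decimal (half-up).

    Counts only homopolymer and dinucleotide-repeat records.  May also be
    called with explicit counts: ``rate(ref_length, n_homopolymer,
    n_dinucleotide)``.
    """
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    if isinstance(records, int):
        n = records + (n_dinucleotide or 0)
    else:
        n = sum(1 for r in records if r.kind in ("homopolymer", "dinucleotide_repeat"))
    return round_half_up(10_000.0 * n / ref_length, 1)


def build_report(ref: str, test: str) -> AccuracyReport:
    """End-to-end accuracy assessment of a test consensus vs a reference."""
    aln = align_locus(ref, test)
    records = classify(aln, ref)
    census = run_census(ref, records)
    gs = gap_stats(test)
    n_homo = sum(1 for r in records if r.kind == "homopolymer")
    n_di = sum(1 for r in records if r.kind == "dinucleotide_repeat")
    return AccuracyReport(
        ref_length=len(ref),
        n_stretches=gs.n_stretches,
        n_stretch_bp=gs.total_gap_bp,
        n_stretch_pct=gs.gap_fraction_pct,
        homopolymer_discrepancies=n_homo,
        dinucleotide_discrepancies=n_di,
        rate_per_10kb=rate(len(ref), records),
        records=records,
        census=census,
    )
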