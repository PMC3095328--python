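"""Assembly summary statistics: N50, gap (N-stretch) accounting, totals.

The N50 convention used is "the largest length L such that sequences of
length >= L together contain at least half of the assembly's bases".
Report views truncate means to integers and percentages to the printed
precision; machine fields keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import gc_percent, n_runs, round_half_up, trunc_div


@dataclass
class GapStats:
    stretches: list[tuple[int, int]]  # (start, end) 0-based half-open
    total_gap_bp: int
    gap_fraction_pct: float  # report view, one decimal

    @property
    def n_stretches(self) -> int:
        return len(self.stretches)


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    mean_bp: int              # truncated, report view
    mean_bp_exact: float
    n50_bp: int
    largest_bp: int
    n_gap_stretches: int
    gap_bp: int
    gap_fraction_pct: float
    non_n_bp: int
    gc_percent: float
    coverage_x: float | None = None


def n50(lengths) -> int:
    """Largest L such that sequences of length >= L hold >= half the bases."""
    lengths = list(lengths)
    if not lengths:
        raise ValueError("n50 of an empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= half:
            return L
    raise AssertionError("unreachable")


def gap_stats(seq: str) -> GapStats:
    """Census of maximal N runs; fraction is percent of total length."""
    stretches = n_runs(seq)
    total = sum(e - s for s, e in stretches)
    frac = round_half_up(100.0 * total / len(seq), 1) if seq else 0.0
    return GapStats(stretches=stretches, total_gap_bp=total, gap_fraction_pct=frac)


def summarize(records, total_read_bp: int | None = None) -> AssemblyStats:
    """Aggregate statistics over assembled records.

    ``coverage_x`` is total read bp divided by assembly bp when the read
    total is supplied.
    """
    records = list(records)
    if not records:
        raise ValueError("summarize needs at least one record")
    lengths = [len(r) for r in records]
    total = sum(lengths)
    gap_bp = 0
    stretch_count = 0
    for r in records:
        gs = gap_stats(r.sequence)
        gap_bp += gs.total_gap_bp
        stretch_count += gs.n_stretches
    non_n = total - gap_bp
    gc = gc_percent("".join(r.sequence for r in records))
    return AssemblyStats(
        n_sequences=len(records),
        total_bp=total,
        mean_bp=trunc_div(total, len(records)),
        mean_bp_exact=total / len(records),
        n50_bp=n50(lengths),
        largest_bp=max(lengths),
        n_gap_stretches=stretch_count,
        gap_bp=gap_bp,
        gap_fraction_pct=round_half_up(100.0 * gap_bp / total, 1),
        non_n_bp=non_n,
        gc_percent=gc,
        coverage_x=(total_read_bp / total) if total_read_bp else None,
    )


def report_mean(total_bp: int, n: int) -> int:
    """Report-view mean size from totals (truncated, never rounded)."""
    return trunc_div(total_bp, n)


def mean_read_size(total_read_bp: int, n_reads: int) -> int:
    """Average read size as printed in run-summary tables (truncated)."""
    return trunc_div(total_read_bp, n_reads)
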