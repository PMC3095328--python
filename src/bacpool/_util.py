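"""Small shared helpers: sequence utilities and report-precision rules.

All report tables in this package distinguish the *machine* value (full
floating-point precision) from the *report view* (the truncated or
half-up-rounded figure a summary table prints).  The helpers here are the
single implementation of those precision rules.
"""

from __future__ import annotations

import math
import re
from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True) -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T[,N]}."""
    seq = seq.upper()
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    return seq


_N_RUN = re.compile(r"N+")


def n_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of N as 0-based half-open ``(start, end)`` intervals."""
    return [(m.start(), m.end()) for m in _N_RUN.finditer(seq)]


def base_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal single-base runs as ``(start, end, base)``; skips N runs."""
    out = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] != "N":
            out.append((i, j, seq[i]))
        i = j
    return out


def gc_percent(seq: str) -> float:
    """GC percent over non-N bases (0.0 on an all-N or empty string)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def trunc_div(total: int, n: int) -> int:
    """Integer mean by truncation, the convention of the report tables."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(total // n)


def trunc_pct(value: float, decimals: int) -> float:
    """Truncate (never round) a percentage to ``decimals`` places."""
    factor = 10**decimals
    return math.floor(value * factor) / factor


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` places (report rule)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
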