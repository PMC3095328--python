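"""Annotation census: SSR detection, gene-model summaries, TE accounting.

The SSR detector re-implements the classic perfect-microsatellite search:
maximal perfect arrays of primitive 1-6 bp units, with class-specific
minimum array lengths (mono 10 bp, di/tri 12 bp, tetra 16 bp, penta
20 bp, hexa 24 bp).  N breaks arrays; a region qualifying under several
unit lengths is reported once, at the smallest unit.

Report-precision conventions (full-precision values are kept alongside):
gene density and EST-support percentages round half-up to one decimal;
SSR percent and kb-per-SSR use the non-N length as denominator; TE
percents use the total analyzed length and are truncated — two decimals
below 1%, one decimal at 1% and above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import gc_percent, revcomp, round_half_up, trunc_pct
from .seqio import DNA_TE_FAMILIES, RETRO_TE_FAMILIES, TE_FAMILIES

#: minimum total array length (bp) per repeat-unit length
DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}


@dataclass
class SsrRecord:
    scaffold_id: str
    start: int
    end: int
    motif: str       # canonical unit (min rotation of unit / revcomp unit)
    unit: str        # unit as encountered
    unit_count: int

    @property
    def total_bp(self) -> int:
        return self.end - self.start


def _canonical_motif(unit: str) -> str:
    rots = [unit[i:] + unit[:i] for i in range(len(unit))]
    rc = revcomp(unit)
    rots += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rots)


def _is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def find_ssrs(
    seq: str,
    scaffold_id: str = "seq",
    thresholds: dict[int, int] | None = None,
) -> list[SsrRecord]:
    """Maximal perfect SSR arrays above the class minimum lengths.

    Arrays are whole-unit: extending a reported array by one unit in
    either direction breaks perfection.  Overlapping candidates are
    suppressed left-to-right, preferring the smaller unit.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    n = len(seq)
    candidates: list[tuple[int, int, int]] = []  # (start, end, k)
    for k, min_bp in thresholds.items():
        if min_bp < 2 * k:  # need at least two units to be a repeat
            min_bp = 2 * k
        i = 0
        while i + k < n:
            unit = seq[i : i + k]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            j = i + k
            while j < n and seq[j] != "N" and seq[j] == seq[j - k]:
                j += 1
            total = j - i
            units = total // k
            if units >= 2 and units * k >= min_bp:
                candidates.append((i, i + units * k, k))
                i = j - k + 1  # a later maximal array must start past here
            else:
                i += 1
    out: list[SsrRecord] = []
    last_end = -1
    for start, end, k in sorted(candidates, key=lambda c: (c[0], c[2], -(c[1] - c[0]))):
        if start < last_end:
            continue
        unit = seq[start : start + k]
        out.append(
            SsrRecord(
                scaffold_id=scaffold_id, start=start, end=end,
                motif=_canonical_motif(unit), unit=unit, unit_count=(end - start) // k,
            )
        )
        last_end = end
    return out


# -- gene summaries ----------------------------------------------------------

def gene_density_per_100kb(n_genes: int, total_bp: int) -> float:
    """Genes per 100 kb of total (N-inclusive) sequence, one decimal."""
    return round_half_up(1e5 * n_genes / total_bp, 1)


def est_support_percent(n_supported: int, n_genes: int) -> float:
    return round_half_up(100.0 * n_supported / n_genes, 1)


@dataclass
class AnnotationSummary:
    total_bp: int
    non_n_bp: int
    n_genes: int
    n_genes_est_supported: int
    est_support_pct: float
    gene_density: float          # per 100 kb, report view
    mean_exon_bp: float
    mean_intron_bp: float
    exons_per_gene: float
    pct_intron_in_coding: float  # per-gene mean
    mean_protein_aa: float
    gc_percent: float
    density_sd: float            # across scaffolds
    gc_sd: float
    per_scaffold: dict = field(default_factory=dict)


def summarize_genes(genes, scaffolds) -> AnnotationSummary:
    """Gene-model summary over annotated scaffolds (TE models excluded)."""
    genes = [g for g in genes if not g.te_flag]
    if not genes:
        raise ValueError("no protein-coding gene models to summarize")
    total_bp = sum(len(s) for s in scaffolds)
    all_seq = "".join(s.sequence for s in scaffolds)
    non_n = total_bp - all_seq.count("N")

    exon_lens = [l for g in genes for l in g.exon_lengths]
    intron_lens = [l for g in genes for l in g.intron_lengths]
    pct_intron = [
        100.0 * sum(g.intron_lengths) / (sum(g.intron_lengths) + sum(g.exon_lengths))
        for g in genes
    ]
    n_sup = sum(1 for g in genes if g.est_support)

    per_scaffold = {}
    densities, gcs = [], []
    for s in scaffolds:
        n_here = sum(1 for g in genes if g.scaffold_id == s.id)
        d = 1e5 * n_here / len(s)
        gc = gc_percent(s.sequence)
        per_scaffold[s.id] = {"n_genes": n_here, "density": d, "gc": gc}
        densities.append(d)
        gcs.append(gc)

    return AnnotationSummary(
        total_bp=total_bp,
        non_n_bp=non_n,
        n_genes=len(genes),
        n_genes_est_supported=n_sup,
        est_support_pct=est_support_percent(n_sup, len(genes)),
        gene_density=gene_density_per_100kb(len(genes), total_bp),
        mean_exon_bp=float(np.mean(exon_lens)),
        mean_intron_bp=float(np.mean(intron_lens)) if intron_lens else 0.0,
        exons_per_gene=len(exon_lens) / len(genes),
        pct_intron_in_coding=float(np.mean(pct_intron)),
        mean_protein_aa=float(np.mean([g.protein_length for g in genes])),
        gc_percent=gc_percent(all_seq),
        density_sd=float(np.std(densities, ddof=1)) if len(densities) > 1 else 0.0,
        gc_sd=float(np.std(gcs, ddof=1)) if len(gcs) > 1 else 0.0,
        per_scaffold=per_scaffold,
    )


# -- SSR summary -------------------------------------------------------------

@dataclass
class SsrSummary:
    count: int
    total_bp: int
    percent: float            # of non-N sequence, two decimals
    kb_per_ssr: float | None  # one decimal; None ("NA") when count == 0


def summarize_ssrs(records, total_bp: int, non_n_bp: int) -> SsrSummary:
    """SSR totals; percent and spacing are computed on the non-N length."""
    if total_bp <= 0 or non_n_bp <= 0:
        raise ValueError("sequence totals must be positive")
    if isinstance(records, int):
        count, ssr_bp = records, 0
    else:
        records = list(records)
        count = len(records)
        ssr_bp = sum(r.total_bp for r in records)
    pct = round(100.0 * ssr_bp / non_n_bp, 2) if count else 0.0
    kb = round_half_up(non_n_bp / count / 1000.0, 1) if count else None
    return SsrSummary(count=count, total_bp=ssr_bp, percent=pct, kb_per_ssr=kb)


def ssr_percent(ssr_bp: int, non_n_bp: int) -> float:
    """Report view of the SSR fraction (two decimals)."""
    return round(100.0 * ssr_bp / non_n_bp, 2)


def kb_per_ssr(count: int, non_n_bp: int) -> float:
    return round_half_up(non_n_bp / count / 1000.0, 1)


# -- TE summary --------------------------------------------------------------

def te_percent(bp: int, total_bp: int) -> float:
    """Report view of a TE percent: truncated to two decimals below 1%,
    one decimal at 1% and above (the convention of the content tables)."""
    pct = 100.0 * bp / total_bp
    return trunc_pct(pct, 2) if pct < 1.0 else trunc_pct(pct, 1)


@dataclass
class TeSummary:
    total_bp: int
    families: dict    # family -> {"copies": n, "bp": bp, "percent": report view}
    dna_total: dict   # {"copies", "bp", "percent"}
    retro_total: dict

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]], total_bp: int) -> "TeSummary":
        """Build from {family: (copies, bp)} tallies."""
        import warnings

        families = {}
        for fam, (copies, bp) in counts.items():
            if fam not in TE_FAMILIES:
                warnings.warn(f"unknown TE family {fam!r}; binned as Unclassified",
                              stacklevel=2)
                prev = families.get("Unclassified", {"copies": 0, "bp": 0})
                families["Unclassified"] = {
                    "copies": prev["copies"] + copies, "bp": prev["bp"] + bp,
                }
            else:
                families[fam] = {"copies": copies, "bp": bp}
        for fam in families:
            families[fam]["percent"] = te_percent(families[fam]["bp"], total_bp)

        def class_total(members):
            copies = sum(families[f]["copies"] for f in members if f in families)
            bp = sum(families[f]["bp"] for f in members if f in families)
            return {"copies": copies, "bp": bp, "percent": te_percent(bp, total_bp)}

        return cls(
            total_bp=total_bp,
            families=families,
            dna_total=class_total(DNA_TE_FAMILIES),
            retro_total=class_total(RETRO_TE_FAMILIES),
        )


def summarize_tes(te_models, total_bp: int) -> TeSummary:
    """TE content accounting from annotated models."""
    counts: dict[str, list[int]] = {}
    for m in te_models:
        fam = m.te_family or "Unclassified"
        c = counts.setdefault(fam, [0, 0])
        c[0] += 1
        c[1] += m.end - m.start
    return TeSummary.from_counts({f: tuple(v) for f, v in counts.items()}, total_bp)
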