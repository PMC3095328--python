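"""Microsynteny: ortholog pairing, tandem collapsing, block finding and
the relative syntenic quality statistic.

Quality of a syntenic block is

    100 * (conserved_a + conserved_b) / (n_a + n_b)

where the counts exclude transposable elements and collapse tandem
arrays (a run of adjacent, mutually homologous same-side genes counts
once).  Pairing is reciprocal-best on e-value (identity breaking ties);
blocks are contiguous runs of paired genes in which consecutive pairs are
separated by at most ``max_gap`` unpaired genes on either side,
irrespective of orientation and local order, and must contain at least
two pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVALUE_CUT = 1e-46
IDENTITY_FLOOR = 0.0
MAX_GAP = 3


@dataclass
class HomologPair:
    gene_a: str
    gene_b: str
    identity: float
    evalue: float


@dataclass
class CollapsedGene:
    representative: str
    members: list[str]

    @property
    def array_size(self) -> int:
        return len(self.members)


@dataclass
class SyntenyBlock:
    region_a: tuple[int, int]
    region_b: tuple[int, int]
    genes_a: list[str]        # collapsed, TE-free gene list in block span
    genes_b: list[str]
    pairs: list[HomologPair]
    conserved_a: int
    conserved_b: int
    quality: float            # percent, one decimal

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _passing(table, evalue_cut: float, identity_floor: float):
    return [row for row in table if row[3] <= evalue_cut and row[2] >= identity_floor]


def pair_homologs(
    genes_a,
    genes_b,
    homology_table,
    evalue_cut: float = EVALUE_CUT,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[HomologPair]:
    """Reciprocal-best ortholog pairs between the two regions.

    TE-flagged genes are dropped before pairing; per gene the best partner
    is the smallest e-value (highest identity on ties), and a pair is kept
    only when the choice is mutual.
    """
    ids_a = {g.id for g in genes_a if not g.te_flag}
    ids_b = {g.id for g in genes_b if not g.te_flag}
    rows = [
        (a, b, ident, ev)
        for a, b, ident, ev in _passing(homology_table, evalue_cut, identity_floor)
        if (a in ids_a and b in ids_b) or (a in ids_b and b in ids_a)
    ]
    # orient rows as (a-side, b-side)
    oriented = [
        (a, b, ident, ev) if a in ids_a else (b, a, ident, ev)
        for a, b, ident, ev in rows
    ]
    best_a: dict[str, tuple] = {}
    best_b: dict[str, tuple] = {}
    for a, b, ident, ev in oriented:
        key = (ev, -ident)
        if a not in best_a or key < (best_a[a][3], -best_a[a][2]):
            best_a[a] = (a, b, ident, ev)
        if b not in best_b or key < (best_b[b][3], -best_b[b][2]):
            best_b[b] = (a, b, ident, ev)
    pairs = []
    for a, (ra, rb, ident, ev) in sorted(best_a.items()):
        if best_b.get(rb, (None,))[0] == a:
            pairs.append(HomologPair(a, rb, ident, ev))
    return pairs


def collapse_tandem(
    genes,
    homology_table,
    paired_ids: set[str] | None = None,
    evalue_cut: float = EVALUE_CUT,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[CollapsedGene]:
    """Collapse maximal runs of adjacent, mutually homologous genes.

    ``genes`` must be position-sorted and TE-free.  Adjacent genes belong
    to the same tandem array when every consecutive pair has a homology
    row passing the cuts.  The representative is the member with a
    cross-region pair (``paired_ids``), else the first member.
    """
    genes = list(genes)
    hom = set()
    for a, b, _, _ in _passing(homology_table, evalue_cut, identity_floor):
        hom.add((a, b))
        hom.add((b, a))
    paired_ids = paired_ids or set()
    out: list[CollapsedGene] = []
    i = 0
    while i < len(genes):
        j = i
        while j + 1 < len(genes) and (genes[j].id, genes[j + 1].id) in hom:
            j += 1
        members = [g.id for g in genes[i : j + 1]]
        rep = next((m for m in members if m in paired_ids), members[0])
        out.append(CollapsedGene(representative=rep, members=members))
        i = j + 1
    return out


def find_blocks(
    genes_a,
    genes_b,
    pairs,
    homology_table=(),
    max_gap: int = MAX_GAP,
    evalue_cut: float = EVALUE_CUT,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[SyntenyBlock]:
    """Syntenic blocks of >= 2 reciprocal pairs, with quality.

    Genes are position-sorted per region, TEs excluded and tandem arrays
    collapsed first (array members map to their representative).  Pairs
    sorted along region A chain into one block while consecutive pairs are
    separated by <= ``max_gap`` unpaired collapsed genes on both regions.
    """
    a_sorted = sorted((g for g in genes_a if not g.te_flag), key=lambda g: g.start)
    b_sorted = sorted((g for g in genes_b if not g.te_flag), key=lambda g: g.start)
    paired_a = {p.gene_a for p in pairs}
    paired_b = {p.gene_b for p in pairs}
    coll_a = collapse_tandem(a_sorted, homology_table, paired_a,
                             evalue_cut, identity_floor)
    coll_b = collapse_tandem(b_sorted, homology_table, paired_b,
                             evalue_cut, identity_floor)
    order_a = {c.representative: i for i, c in enumerate(coll_a)}
    order_b = {c.representative: i for i, c in enumerate(coll_b)}
    span_a = {c.representative: c for c in coll_a}
    span_b = {c.representative: c for c in coll_b}
    starts = {g.id: g.start for g in list(genes_a) + list(genes_b)}
    ends = {g.id: g.end for g in list(genes_a) + list(genes_b)}

    usable = [p for p in pairs if p.gene_a in order_a and p.gene_b in order_b]
    usable.sort(key=lambda p: order_a[p.gene_a])
    if not usable:
        return []

    def gap_between(i: int, j: int, paired: set[str], coll) -> int:
        lo, hi = min(i, j), max(i, j)
        return sum(
            1 for c in coll[lo + 1 : hi] if c.representative not in paired
        )

    runs: list[list[HomologPair]] = [[usable[0]]]
    for prev, cur in zip(usable, usable[1:]):
        ga = gap_between(order_a[prev.gene_a], order_a[cur.gene_a], paired_a, coll_a)
        gb = gap_between(order_b[prev.gene_b], order_b[cur.gene_b], paired_b, coll_b)
        if ga <= max_gap and gb <= max_gap:
            runs[-1].append(cur)
        else:
            runs.append([cur])

    blocks: list[SyntenyBlock] = []
    for run in runs:
        if len(run) < 2:
            continue
        ia = [order_a[p.gene_a] for p in run]
        ib = [order_b[p.gene_b] for p in run]
        in_a = coll_a[min(ia) : max(ia) + 1]
        in_b = coll_b[min(ib) : max(ib) + 1]
        gene_list_a = [c.representative for c in in_a]
        gene_list_b = [c.representative for c in in_b]
        conserved_a = sum(1 for c in in_a if c.representative in paired_a)
        conserved_b = sum(1 for c in in_b if c.representative in paired_b)
        q = 100.0 * (conserved_a + conserved_b) / (len(in_a) + len(in_b))
        members_a = [m for c in in_a for m in c.members]
        members_b = [m for c in in_b for m in c.members]
        blocks.append(
            SyntenyBlock(
                region_a=(min(starts[m] for m in members_a),
                          max(ends[m] for m in members_a)),
                region_b=(min(starts[m] for m in members_b),
                          max(ends[m] for m in members_b)),
                genes_a=gene_list_a,
                genes_b=gene_list_b,
                pairs=run,
                conserved_a=conserved_a,
                conserved_b=conserved_b,
                quality=round(q, 1),
            )
        )
    return blocks


def quality(block_or_conserved_a, conserved_b: int | None = None,
            n_a: int | None = None, n_b: int | None = None) -> float:
    """Relative syntenic quality, one decimal.

    Accepts either a :class:`SyntenyBlock` or the four counts
    ``(conserved_a, conserved_b, n_a, n_b)``.  Counts must already exclude
    TEs and collapse tandem arrays; returns 100.0 iff every countable gene
    on both sides belongs to a pair.
    """
    if isinstance(block_or_conserved_a, SyntenyBlock):
        b = block_or_conserved_a
        ca, cb = b.conserved_a, b.conserved_b
        na, nb = len(b.genes_a), len(b.genes_b)
    else:
        ca, cb, na, nb = block_or_conserved_a, conserved_b, n_a, n_b
    if na + nb == 0:
        raise ValueError("empty block")
    return round(100.0 * (ca + cb) / (na + nb), 1)


def region_quality(
    genes_a,
    genes_b,
    pairs,
    homology_table=(),
    evalue_cut: float = EVALUE_CUT,
    identity_floor: float = IDENTITY_FLOOR,
) -> float:
    """Relative syntenic quality of two whole regions.

    Unlike a block's span-local quality, every TE-free collapsed gene of
    both regions enters the denominator — the statistic reported when two
    annotated regions are compared end to end.
    """
    a_sorted = sorted((g for g in genes_a if not g.te_flag), key=lambda g: g.start)
    b_sorted = sorted((g for g in genes_b if not g.te_flag), key=lambda g: g.start)
    paired_a = {p.gene_a for p in pairs}
    paired_b = {p.gene_b for p in pairs}
    coll_a = collapse_tandem(a_sorted, homology_table, paired_a,
                             evalue_cut, identity_floor)
    coll_b = collapse_tandem(b_sorted, homology_table, paired_b,
                             evalue_cut, identity_floor)
    conserved_a = sum(1 for c in coll_a if c.representative in paired_a)
    conserved_b = sum(1 for c in coll_b if c.representative in paired_b)
    return quality(conserved_a, conserved_b, len(coll_a), len(coll_b))


@dataclass
class RatioStats:
    protein_length_ratio: float | None
    exon_count_ratio: float | None
    mean_intron_ratio: float | None
    n_pairs_used: int = 0
    n_pairs_intron: int = 0


def ratio_stats(pairs, genes_a, genes_b) -> RatioStats:
    """Mean per-pair structural ratios (region A over region B), two
    decimals; pairs missing structural data are excluded with a warning.
    The intron ratio uses only pairs where both genes have introns."""
    import warnings

    by_id = {g.id: g for g in list(genes_a) + list(genes_b)}
    prot, exon, intron = [], [], []
    used = 0
    for p in pairs:
        ga, gb = by_id.get(p.gene_a), by_id.get(p.gene_b)
        if ga is None or gb is None or ga.protein_length < 1 or gb.protein_length < 1:
            warnings.warn(f"pair {p.gene_a}/{p.gene_b} lacks structural data; skipped",
                          stacklevel=2)
            continue
        used += 1
        prot.append(ga.protein_length / gb.protein_length)
        exon.append(len(ga.exons) / len(gb.exons))
        ia, ib = ga.intron_lengths, gb.intron_lengths
        if ia and ib:
            intron.append(np.mean(ia) / np.mean(ib))
    return RatioStats(
        protein_length_ratio=round(float(np.mean(prot)), 2) if prot else None,
        exon_count_ratio=round(float(np.mean(exon)), 2) if exon else None,
        mean_intron_ratio=round(float(np.mean(intron)), 2) if intron else None,
        n_pairs_used=used,
        n_pairs_intron=len(intron),
    )
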