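"""Synthetic genomes, BAC pools, fragmented assemblies and syntenic pairs.

Every downstream stage of the pipeline is exercised against data built
here, so each generator records the ground truth it planted: the clone
truth table, the error-event list, the ortholog table.  The defaults
emulate the study conditions of a pooled-BAC pyrosequencing project on a
gene-rich plant genome fraction: ~9.9 genes/100 kb, 33% GC, 4.9 exons per
gene with 238 bp exons and 393 bp introns, 139 kb BamHI inserts with 30 bp
vector junctions, consensus errors concentrated in homopolymers of 11 nt
and longer, and syntenic region pairs whose size ratio is driven by
transposon insertions and intron-length scaling.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import base_runs, revcomp
from .seqio import GeneModel, MarkerSeq, BacClone, ScaffoldRecord

BAMHI = "GGATCC"

#: Synthetic 30 bp cloning-vector sequences flanking the BamHI site.
#: These stand in for the real vector's junction sequences (which mark a
#: BAC border when found at a scaffold extreme).
DEFAULT_JUNCTION_LEFT = "TACGCTAGTTGGCATCGACTGAACCGTTAG"
DEFAULT_JUNCTION_RIGHT = "CTAACGGATAGCTGACCATCGGTTAGCGTA"

_TE_FAMILY_WEIGHTS = {
    # copy-number proportions of a gene-rich plant genome fraction
    "CACTA": 15, "hAT": 4, "MULE": 6, "PIF": 1, "helitron": 1,
    "Copia": 15, "Gypsy": 18, "NonLTR": 3, "Unclassified": 77,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ToyGenome:
    sequence: str
    gene_models: list[GeneModel]
    te_models: list[GeneModel]
    seed: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimBacPool:
    clones: list[BacClone]
    inserts: list[str]
    junction_left: str
    junction_right: str
    truth_table: dict[str, tuple[int, int]]
    markers: list[MarkerSeq]
    genome_sequence: str  # genome after BamHI-site planting
    planted_sites: list[int] = field(default_factory=list)

    def assembled_sequence(self, clone_id: str) -> str:
        """Insert with its flanking vector junctions, as an untrimmed
        consensus would carry them."""
        idx = [c.id for c in self.clones].index(clone_id)
        return self.junction_left + self.inserts[idx] + self.junction_right


@dataclass
class ErrorProfile:
    """Consensus-level error model of homopolymer-biased sequencing.

    Defaults contract runs of >= 11 nt by 1-3 nt with probability 0.58
    (the observed fraction of long mononucleotide repeats affected) and
    perturb long dinucleotide tandem arrays; shorter runs are never
    touched.
    """

    homopolymer_contraction_prob: float = 0.58
    contraction_size_range: tuple[int, int] = (1, 3)
    run_length_threshold: int = 11
    dinucleotide_perturb_prob: float = 0.5
    dinucleotide_unit_range: tuple[int, int] = (1, 3)
    min_dinucleotide_units: int = 6
    n_gap_rate: float = 0.0  # expected N stretches per 100 kb
    n_gap_len_range: tuple[int, int] = (100, 1000)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.homopolymer_contraction_prob, self.dinucleotide_perturb_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if self.contraction_size_range[0] < 1:
            raise ValueError("contraction sizes must be >= 1")
        if self.run_length_threshold < 2:
            raise ValueError("run_length_threshold must be >= 2")


@dataclass
class PlantedEvent:
    kind: str        # homopolymer | dinucleotide_repeat | n_gap
    position: int    # start of the affected locus, input coordinates
    motif: str
    ref_len: int     # bp length of the affected locus in the input
    delta: int       # signed bp change (0 for n_gap masking)


@dataclass
class AnnotatedRegion:
    record: ScaffoldRecord
    genes: list[GeneModel]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _gene_structure(rng: np.random.Generator):
    """Exon/intron lengths: exon count geometric (mean 4.9), exon length
    log-normal (mean 238 bp), intron length log-normal (mean 393 bp)."""
    n_exons = int(min(rng.geometric(1 / 4.9), 29))
    mu_e = np.log(238) - 0.6**2 / 2
    mu_i = np.log(393) - 0.7**2 / 2
    exons = np.maximum(np.rint(rng.lognormal(mu_e, 0.6, n_exons)).astype(int), 30)
    introns = (
        np.maximum(np.rint(rng.lognormal(mu_i, 0.7, n_exons - 1)).astype(int), 50)
        if n_exons > 1
        else np.array([], dtype=int)
    )
    return exons, introns


def make_genome(
    length: int,
    gene_density: float,
    te_fraction: float,
    gc: float,
    seed: int,
) -> ToyGenome:
    """Random genome with non-overlapping gene and TE annotations.

    ``gene_density`` is genes per 100 kb; ``te_fraction`` the fraction of
    the sequence covered by transposable elements.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0,1)")
    rng = np.random.default_rng(seed)
    arr = _random_seq(rng, length, gc)

    n_genes = int(round(gene_density * length / 1e5))
    structures = [_gene_structure(rng) for _ in range(n_genes)]
    gene_lens = [int(ex.sum() + it.sum()) for ex, it in structures]

    te_lens: list[int] = []
    if te_fraction > 0:
        target = te_fraction * length
        while sum(te_lens) < target:
            te_lens.append(int(np.clip(rng.lognormal(np.log(5000), 0.7), 500, 30_000)))

    feature_bp = sum(gene_lens) + sum(te_lens)
    if feature_bp > 0.9 * length:
        raise ValueError(
            f"genome of {length} bp too small to place {n_genes} genes and "
            f"{len(te_lens)} TEs ({feature_bp} bp of features); increase "
            "length or lower densities"
        )

    # Interleave genes and TEs in a random order, spaced by random gaps.
    kinds = ["gene"] * n_genes + ["te"] * len(te_lens)
    order = rng.permutation(len(kinds))
    free = length - feature_bp
    weights = rng.random(len(kinds) + 1)
    gaps = np.floor(weights / weights.sum() * free).astype(int)

    genes: list[GeneModel] = []
    tes: list[GeneModel] = []
    families = list(_TE_FAMILY_WEIGHTS)
    fam_p = np.array(list(_TE_FAMILY_WEIGHTS.values()), dtype=float)
    fam_p /= fam_p.sum()
    pos = int(gaps[0])
    gi = ti = 0
    for slot, k in enumerate(order):
        kind = kinds[k]
        if kind == "gene":
            exons_len, introns_len = structures[gi]
            exons = []
            cursor = pos
            for i, el in enumerate(exons_len):
                exons.append((cursor, cursor + int(el)))
                cursor += int(el)
                if i < len(introns_len):
                    cursor += int(introns_len[i])
            genes.append(
                GeneModel(
                    id=f"g{gi:04d}",
                    scaffold_id="genome",
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                    est_support=bool(rng.random() < 0.732),
                    protein_length=max(int(exons_len.sum()) // 3, 34),
                )
            )
            pos = cursor
            gi += 1
        else:
            L = te_lens[ti]
            tes.append(
                GeneModel(
                    id=f"te{ti:04d}",
                    scaffold_id="genome",
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=[(pos, pos + L)],
                    te_flag=True,
                    te_family=families[int(rng.choice(len(families), p=fam_p))],
                )
            )
            pos += L
            ti += 1
        pos += int(gaps[slot + 1])
    return ToyGenome(arr.tobytes().decode(), genes, tes, seed)


def make_bac_pool(
    genome: ToyGenome,
    n_clones: int,
    insert_mean: int = 139_000,
    insert_sd: int = 10_000,
    junctions: tuple[str, str] = (DEFAULT_JUNCTION_LEFT, DEFAULT_JUNCTION_RIGHT),
    seed: int = 0,
    markers_per_clone: int = 1,
    end_length: int = 500,
    marker_length: int = 400,
    allow_overlap: bool = False,
) -> SimBacPool:
    """Draw BAC inserts from the genome, delimited by BamHI sites.

    BamHI GGATCC sites are planted at the chosen insert boundaries when the
    random genome lacks them there (the planting positions are recorded);
    every clone gets two 500 bp end sequences (the right one
    reverse-complemented, as a Sanger read off the far vector arm would
    be) and per-clone anchor markers drawn from the insert interior.
    """
    glen = len(genome)
    if insert_mean >= glen:
        raise ValueError("insert_mean must be smaller than the genome")
    jl, jr = junctions
    if len(jl) != 30 or len(jr) != 30:
        raise ValueError("junction sequences must be exactly 30 bp")
    rng = np.random.default_rng(seed)

    arr = bytearray(genome.sequence.encode())
    min_len = max(2 * end_length + marker_length + 200, 2000)
    intervals: list[tuple[int, int]] = []
    if allow_overlap:
        for _ in range(n_clones):
            L = int(np.clip(rng.normal(insert_mean, insert_sd), min_len, glen - 1))
            start = int(rng.integers(0, glen - L))
            intervals.append((start, start + L))
    else:
        # tile clones so each marker/end region is unique to its clone,
        # the situation of a marker-anchored BAC selection
        slot = glen // n_clones
        if slot < insert_mean + 3 * insert_sd + 10:
            raise ValueError(
                f"genome of {glen} bp cannot hold {n_clones} non-overlapping "
                f"~{insert_mean} bp inserts; lower insert_mean or n_clones, "
                "or pass allow_overlap=True"
            )
        for i in range(n_clones):
            L = int(np.clip(rng.normal(insert_mean, insert_sd), min_len, slot - 10))
            start = slot * i + int(rng.integers(0, slot - L))
            intervals.append((start, start + L))

    site = BAMHI.encode()
    planted: list[int] = []
    for start, end in intervals:
        for p in (start, end - len(BAMHI)):
            if arr[p : p + len(BAMHI)] != site:
                arr[p : p + len(BAMHI)] = site
                planted.append(p)
    genome_seq = arr.decode()

    clones: list[BacClone] = []
    inserts: list[str] = []
    markers: list[MarkerSeq] = []
    truth: dict[str, tuple[int, int]] = {}
    for i, (start, end) in enumerate(intervals):
        cid = f"clone{i:03d}"
        insert = genome_seq[start:end]
        marker_ids = []
        # markers spread across the insert interior, clear of both ends
        lo = start + end_length + 50
        hi = end - end_length - 50 - marker_length
        for k in range(markers_per_clone):
            mpos = lo + (hi - lo) * (k + 1) // (markers_per_clone + 1)
            mid = f"M{i:03d}_{k}"
            markers.append(MarkerSeq(mid, genome_seq[mpos : mpos + marker_length]))
            marker_ids.append(mid)
        clones.append(
            BacClone(
                id=cid,
                expected_insert=insert_mean,
                marker_ids=marker_ids,
                end_seqs={
                    "left": insert[:end_length],
                    "right": revcomp(insert[-end_length:]),
                },
            )
        )
        inserts.append(insert)
        truth[cid] = (start, end)
    return SimBacPool(
        clones=clones,
        inserts=inserts,
        junction_left=jl,
        junction_right=jr,
        truth_table=truth,
        markers=markers,
        genome_sequence=genome_seq,
        planted_sites=planted,
    )


def fragment_and_scaffold(
    insert: str,
    n_gaps: int,
    gap_len_range: tuple[int, int] = (100, 2000),
    seed: int = 0,
    end_margin: int = 600,
    scaffold_id: str = "scaffold",
) -> ScaffoldRecord:
    """Replace ``n_gaps`` disjoint internal segments of the insert with N
    runs, emulating contig scaffolding; the sequence ends are preserved so
    that border evidence survives."""
    if n_gaps < 0:
        raise ValueError("n_gaps must be >= 0")
    if n_gaps == 0:
        return ScaffoldRecord(scaffold_id, insert)
    rng = np.random.default_rng(seed)
    lo, hi = gap_len_range
    lens = rng.integers(lo, hi + 1, size=n_gaps)
    usable = len(insert) - 2 * end_margin
    needed = int(lens.sum()) + (n_gaps - 1)
    if usable < needed:
        raise ValueError(
            "gaps would touch the sequence ends: "
            f"{needed} bp of gaps+spacers do not fit in {usable} bp interior"
        )
    free = usable - int(lens.sum())
    w = rng.random(n_gaps + 1)
    spacing = np.floor(w / w.sum() * (free - (n_gaps - 1))).astype(int)
    arr = bytearray(insert.encode())
    pos = end_margin + int(spacing[0])
    for i, L in enumerate(lens):
        arr[pos : pos + int(L)] = b"N" * int(L)
        pos += int(L) + 1 + int(spacing[i + 1])
    return ScaffoldRecord(scaffold_id, arr.decode())


def _dinucleotide_arrays(seq: str, min_units: int) -> list[tuple[int, int, str]]:
    """Maximal perfect primitive dinucleotide arrays of >= min_units units,
    as (start, end, unit)."""
    out = []
    n = len(seq)
    i = 0
    while i < n - 1:
        unit = seq[i : i + 2]
        if unit[0] == unit[1] or "N" in unit:
            i += 1
            continue
        j = i + 2
        while j + 1 < n and seq[j] == unit[0] and seq[j + 1] == unit[1]:
            j += 2
        units = (j - i) // 2
        if units >= min_units:
            out.append((i, i + units * 2, unit))
            i = i + units * 2
        else:
            i += 1
    return out


def inject_errors(seq: str, profile: ErrorProfile) -> tuple[str, list[PlantedEvent]]:
    """Inject homopolymer contractions, dinucleotide-array perturbations
    and N-stretch masking per the profile; every planted event is recorded
    in input coordinates.  Runs shorter than ``run_length_threshold`` are
    never modified."""
    if not seq:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(profile.seed)
    events: list[PlantedEvent] = []

    lo, hi = profile.contraction_size_range
    for start, end, base in base_runs(seq):
        run_len = end - start
        if run_len < profile.run_length_threshold:
            continue
        if rng.random() < profile.homopolymer_contraction_prob:
            d = int(min(rng.integers(lo, hi + 1), run_len - 1))
            events.append(PlantedEvent("homopolymer", start, base, run_len, -d))

    dlo, dhi = profile.dinucleotide_unit_range
    for start, end, unit in _dinucleotide_arrays(seq, profile.min_dinucleotide_units):
        if rng.random() < profile.dinucleotide_perturb_prob:
            units = (end - start) // 2
            k = int(min(rng.integers(dlo, dhi + 1), units - profile.min_dinucleotide_units + 1))
            if k < 1:
                continue
            events.append(PlantedEvent("dinucleotide_repeat", start, unit, end - start, -2 * k))

    taken = [(e.position, e.position + e.ref_len) for e in events]
    n_expected = profile.n_gap_rate * len(seq) / 1e5
    glo, ghi = profile.n_gap_len_range
    for _ in range(int(rng.poisson(n_expected))):
        for _attempt in range(50):
            L = int(rng.integers(glo, ghi + 1))
            if len(seq) <= L + 200:
                break
            p = int(rng.integers(100, len(seq) - L - 100))
            if all(p + L + 31 <= s or p >= e + 31 for s, e in taken):
                events.append(PlantedEvent("n_gap", p, "N", L, 0))
                taken.append((p, p + L))
                break

    out = bytearray(seq.encode())
    for e in sorted(events, key=lambda e: -e.position):
        if e.kind == "n_gap":
            out[e.position : e.position + e.ref_len] = b"N" * e.ref_len
        else:
            motif = e.motif.encode()
            new_len = e.ref_len + e.delta
            reps = motif * (new_len // len(motif) + 1)
            out[e.position : e.position + e.ref_len] = reps[:new_len]
    return out.decode(), events


def make_accuracy_locus(
    length: int = 99_000,
    n_long_runs: int = 26,
    run_len_range: tuple[int, int] = (11, 28),
    n_short_runs: int = 0,
    short_run_len_range: tuple[int, int] = (4, 10),
    n_dinuc: int = 2,
    dinuc_units: tuple[int, ...] = (15, 21),
    gc: float = 0.33,
    seed: int = 0,
) -> str:
    """Reference locus with planted long mononucleotide runs and perfect
    dinucleotide arrays, emulating the repeat landscape of an AT-rich
    finished BAC sequence (a random backbone alone carries almost no run
    of 11+ nt)."""
    rng = np.random.default_rng(seed)
    arr = bytearray(_random_seq(rng, length, gc).tobytes())
    features: list[bytes] = []
    for _ in range(n_long_runs):
        base = rng.choice(np.frombuffer(b"AT", dtype=np.uint8))
        L = int(rng.integers(run_len_range[0], run_len_range[1] + 1))
        features.append(bytes([base]) * L)
    for _ in range(n_short_runs):
        base = rng.choice(_BASES)
        L = int(rng.integers(short_run_len_range[0], short_run_len_range[1] + 1))
        features.append(bytes([base]) * L)
    units = list(dinuc_units) or []
    for i in range(n_dinuc):
        unit = ["CT", "GA", "AG", "TC"][i % 4].encode()
        u = units[i % len(units)] if units else 12
        features.append(unit * u)
    # space features out so planted loci stay distinct and anchorable
    slot = length // (len(features) + 1) if features else length
    for i, feat in enumerate(rng.permutation(np.array(features, dtype=object))):
        pos = (i + 1) * slot - len(feat) // 2
        pos = int(np.clip(pos, 100, length - len(feat) - 100))
        # avoid accidentally extending the run with identical neighbours
        if arr[pos - 1] == feat[0]:
            arr[pos - 1] = next(b for b in b"ACGT" if b != feat[0])
        end = pos + len(feat)
        if arr[end] == feat[-1]:
            arr[end] = next(b for b in b"ACGT" if b != feat[-1])
        arr[pos:end] = feat
    return arr.decode()


def _mutate(arr: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``divergence``."""
    if divergence <= 0:
        return arr.copy()
    arr = arr.copy()
    hits = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr


def make_synteny_pair(
    genome: ToyGenome,
    te_insertions: int,
    intron_scale: float,
    divergence: float,
    seed: int,
    tandem_dups: int = 0,
    tandem_copies: int = 2,
    te_len_mean: int = 5300,
) -> tuple[AnnotatedRegion, AnnotatedRegion, list[tuple]]:
    """Build a diverged syntenic region pair from the genome's genes.

    Region B is the genome itself (its non-TE genes); region A is a copy
    with per-site ``divergence`` substitutions, introns scaled by
    ``intron_scale``, ``te_insertions`` transposons inserted intergenically
    and, optionally, ``tandem_dups`` genes expanded into tandem arrays of
    ``tandem_copies`` members.  Gene order and orientation are conserved.
    The returned truth table lists every homologous pair (cross-region
    ortholog rows and within-region tandem rows) as
    (gene_a, gene_b, identity%, e-value).
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    b_seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    genes_b = sorted((g for g in genome.gene_models if not g.te_flag), key=lambda g: g.start)

    dup_idx = set(
        rng.choice(len(genes_b), size=min(tandem_dups, len(genes_b)), replace=False).tolist()
    ) if tandem_dups else set()
    te_slots = sorted(
        rng.choice(len(genes_b) + 1, size=te_insertions, replace=True).tolist()
    ) if te_insertions else []

    fam_names = ("Gypsy", "Copia", "hAT", "MULE", "Unclassified")
    fam_p = np.array([0.45, 0.2, 0.1, 0.05, 0.2])

    pieces: list[np.ndarray] = []
    genes_a: list[GeneModel] = []
    tes_a: list[GeneModel] = []
    table: list[tuple] = []
    pos_a = 0
    cursor_b = 0
    te_counter = 0

    def emit(arr: np.ndarray) -> None:
        nonlocal pos_a
        pieces.append(arr)
        pos_a += len(arr)

    def insert_te() -> None:
        nonlocal te_counter
        L = int(np.clip(rng.lognormal(np.log(te_len_mean), 0.4), 800, 25_000))
        tes_a.append(
            GeneModel(
                id=f"a_te{te_counter:03d}",
                scaffold_id="regionA",
                strand="+" if rng.random() < 0.5 else "-",
                exons=[(pos_a, pos_a + L)],
                te_flag=True,
                te_family=fam_names[int(rng.choice(len(fam_names), p=fam_p))],
            )
        )
        emit(_random_seq(rng, L, 0.4))
        te_counter += 1

    def copy_gene(g: GeneModel, new_id: str, extra_div: float = 0.0) -> tuple[GeneModel, float]:
        """Emit gene g's span into region A, scaling introns; returns the
        A-side model and realized exon identity (%)."""
        exons_a = []
        matches = total = 0
        for i, (s, e) in enumerate(g.exons):
            ex = _mutate(b_seq[s:e], divergence + extra_div, rng)
            matches += int((ex == b_seq[s:e]).sum())
            total += e - s
            exons_a.append((pos_a, pos_a + len(ex)))
            emit(ex)
            if i < len(g.exons) - 1:
                istart, iend = e, g.exons[i + 1][0]
                ilen = iend - istart
                new_len = max(4, int(round(ilen * intron_scale)))
                intron = _mutate(b_seq[istart:iend], divergence + extra_div, rng)
                if new_len > ilen:
                    pad = _random_seq(rng, new_len - ilen, 0.33)
                    mid = ilen // 2
                    intron = np.concatenate([intron[:mid], pad, intron[mid:]])
                elif new_len < ilen:
                    cut = ilen - new_len
                    mid = ilen // 2
                    intron = np.concatenate([intron[: mid - cut // 2], intron[mid + (cut - cut // 2):]])
                emit(intron)
        model = GeneModel(
            id=new_id,
            scaffold_id="regionA",
            strand=g.strand,
            exons=exons_a,
            est_support=g.est_support,
            protein_length=g.protein_length,
        )
        return model, 100.0 * matches / total if total else 100.0

    for idx, g in enumerate(genes_b):
        # intergenic segment before this gene, with any scheduled TEs
        emit(_mutate(b_seq[cursor_b : g.start], divergence, rng))
        for _ in range(te_slots.count(idx)):
            insert_te()
        a_id = f"a_{g.id}"
        model, ident = copy_gene(g, a_id)
        genes_a.append(model)
        table.append((a_id, g.id, round(ident, 1), 1e-180))
        if idx in dup_idx:
            array_ids = [a_id]
            for c in range(1, tandem_copies):
                emit(_random_seq(rng, 200, 0.33))  # short spacer
                dup_id = f"a_{g.id}_dup{c}"
                dup_model, dup_ident = copy_gene(g, dup_id, extra_div=0.02)
                genes_a.append(dup_model)
                array_ids.append(dup_id)
                table.append((dup_id, g.id, round(dup_ident, 1), 1e-150))
            for x in range(len(array_ids)):
                for y in range(x + 1, len(array_ids)):
                    table.append((array_ids[x], array_ids[y], 98.0, 1e-200))
        cursor_b = g.end
    emit(_mutate(b_seq[cursor_b:], divergence, rng))
    for _ in range(te_slots.count(len(genes_b))):
        insert_te()

    a_seq = np.concatenate(pieces) if pieces else np.array([], dtype=np.uint8)
    region_a = AnnotatedRegion(
        ScaffoldRecord("regionA", a_seq.tobytes().decode()), genes_a + tes_a
    )
    region_b = AnnotatedRegion(
        ScaffoldRecord("regionB", genome.sequence),
        [GeneModel(g.id, "regionB", g.strand, g.exons,
                   est_support=g.est_support, protein_length=g.protein_length)
         for g in genes_b],
    )
    return region_a, region_b, table
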