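"""Readers/writers for the formats the pipeline touches.

FASTA goes through Biopython, GFF3 through gffutils (in-memory database),
and tabular inputs through pandas.  Internal coordinates are 0-based
half-open everywhere; GFF3 emission converts to the format's 1-based
closed convention.

Domain records
--------------
:class:`ScaffoldRecord`
    An assembled sequence over {A,C,G,T,N}, optionally labelled with the
    pool it came from.
:class:`BacClone`
    A BAC clone with an expected insert size, the genetic markers anchored
    to it, and up to two Sanger end sequences.
:class:`MarkerSeq`
    A genetic-marker sequence used to anchor scaffolds to clones.
:class:`GeneModel`
    An exon-structured annotation; transposable elements reuse the same
    record with ``te_flag`` set and a superfamily label.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import validate_dna

TE_FAMILIES = (
    "CACTA",
    "hAT",
    "MULE",
    "PIF",
    "helitron",
    "Copia",
    "Gypsy",
    "NonLTR",
    "Unclassified",
)

#: Class II (DNA transposon) vs class I (retrotransposon) membership.
DNA_TE_FAMILIES = ("CACTA", "hAT", "MULE", "PIF", "helitron")
RETRO_TE_FAMILIES = ("Copia", "Gypsy", "NonLTR", "Unclassified")


@dataclass
class ScaffoldRecord:
    id: str
    sequence: str
    pool: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.sequence = validate_dna(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BacClone:
    id: str
    expected_insert: int = 139_000
    marker_ids: list[str] = field(default_factory=list)
    end_seqs: dict[str, str] = field(default_factory=dict)  # side -> seq

    def __post_init__(self) -> None:
        if self.expected_insert <= 0:
            raise ValueError("expected_insert must be positive")
        bad = set(self.end_seqs) - {"left", "right"}
        if bad:
            raise ValueError(f"end sequence sides must be left/right, got {bad}")


@dataclass
class MarkerSeq:
    id: str
    sequence: str
    linkage_group: str | None = None
    min_length: int = 50

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence)
        if len(self.sequence) < self.min_length:
            raise ValueError(
                f"marker {self.id!r} shorter than {self.min_length} bp floor"
            )


@dataclass
class GeneModel:
    id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted
    te_flag: bool = False
    te_family: str | None = None
    est_support: bool = False
    protein_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.id}")
        if not self.exons:
            raise ValueError(f"gene {self.id!r} has zero exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"exons of {self.id!r} overlap or are degenerate")
            prev_end = e
        if self.te_flag and self.te_family is None:
            self.te_family = "Unclassified"
        if not self.te_flag and self.protein_length < 1:
            raise ValueError(f"protein-coding gene {self.id!r} needs protein_length >= 1")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def intron_lengths(self) -> list[int]:
        return [self.exons[i + 1][0] - self.exons[i][1] for i in range(len(self.exons) - 1)]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path: str | Path, pool: str | None = None) -> list[ScaffoldRecord]:
    """Read a (possibly gzipped) FASTA into :class:`ScaffoldRecord` objects.

    Order is preserved, lowercase is folded to uppercase, duplicate ids and
    empty records are rejected.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(ScaffoldRecord(rec.id, str(rec.seq), pool=pool))
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene and transposable-element models from GFF3.

    Recognises ``gene``/``mRNA``/``exon`` hierarchies and flat
    ``transposable_element`` features; 1-based closed GFF coordinates are
    converted to the package's 0-based half-open convention.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            if exon.seqid != gene.seqid:
                raise ValueError(f"exon of {gene.id} on a different scaffold")
            if exon.start - 1 < gene.start - 1 or exon.end > gene.end:
                raise ValueError(f"exon outside parent bounds for {gene.id}")
            exons.append((exon.start - 1, exon.end))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        attrs = gene.attributes
        models.append(
            GeneModel(
                id=gene.id,
                scaffold_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                est_support=attrs.get("est_support", ["false"])[0] == "true",
                protein_length=int(attrs.get("protein_length", ["1"])[0]),
            )
        )
    for te in db.features_of_type("transposable_element", order_by="start"):
        family = te.attributes.get("te_family", ["Unclassified"])[0]
        if family not in TE_FAMILIES:
            family = "Unclassified"
        models.append(
            GeneModel(
                id=te.id,
                scaffold_id=te.seqid,
                strand=te.strand if te.strand in "+-" else "+",
                exons=[(te.start - 1, te.end)],
                te_flag=True,
                te_family=family,
            )
        )
    return models


def write_gene_models(models, path: str | Path) -> None:
    """Emit models as GFF3 (gene/exon + transposable_element features)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.scaffold_id, m.start)):
            if m.te_flag:
                attrs = f"ID={m.id};te_family={m.te_family}"
                out.write(
                    f"{m.scaffold_id}\tbacpool\ttransposable_element\t"
                    f"{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
                continue
            est = "true" if m.est_support else "false"
            attrs = f"ID={m.id};est_support={est};protein_length={m.protein_length}"
            out.write(
                f"{m.scaffold_id}\tbacpool\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for k, (s, e) in enumerate(m.exons, 1):
                out.write(
                    f"{m.scaffold_id}\tbacpool\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={m.id}.exon{k};Parent={m.id}\n"
                )


def read_homology_table(path: str | Path, strict: bool = False) -> list[tuple]:
    """Read a 4-column gene-homology TSV: gene_a, gene_b, identity%, e-value.

    Malformed rows are skipped with a warning (or raise in strict mode);
    duplicate pairs collapse to the row with the smallest e-value.
    """
    import warnings

    best: dict[tuple[str, str], tuple] = {}
    order: list[tuple[str, str]] = []
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)
    except pd.errors.EmptyDataError:
        return []
    start = 0
    # Tolerate an optional header line.
    if len(df) and not _is_float(df.iloc[0, 2] if df.shape[1] > 2 else None):
        start = 1
    for i in range(start, len(df)):
        row = df.iloc[i]
        try:
            if df.shape[1] < 4:
                raise ValueError("expected 4 columns")
            a, b = str(row[0]), str(row[1])
            ident, evalue = float(row[2]), float(row[3])
            if not 0.0 <= ident <= 100.0:
                raise ValueError(f"identity {ident} outside [0,100]")
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"malformed homology row {i}: {exc}") from exc
            warnings.warn(f"skipping malformed homology row {i}: {exc}", stacklevel=2)
            continue
        key = (a, b)
        if key not in best:
            order.append(key)
            best[key] = (a, b, ident, evalue)
        elif evalue < best[key][3]:
            best[key] = (a, b, ident, evalue)
    return [best[k] for k in order]


def _is_float(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_clones(path: str | Path, ends: dict[str, str] | None = None) -> list[BacClone]:
    """Read a clone table TSV: clone_id, expected_insert, marker_ids (comma list).

    ``ends`` optionally maps ``"<clone_id>/left"`` and ``"<clone_id>/right"``
    FASTA ids to end sequences (as produced by the simulator's ends FASTA).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    clones = []
    for _, row in df.iterrows():
        cid = row["clone_id"]
        markers = [m for m in str(row.get("marker_ids", "") or "").split(",") if m]
        end_seqs = {}
        if ends:
            for side in ("left", "right"):
                key = f"{cid}/{side}"
                if key in ends:
                    end_seqs[side] = ends[key]
        clones.append(
            BacClone(
                id=cid,
                expected_insert=int(row.get("expected_insert", 139_000)),
                marker_ids=markers,
                end_seqs=end_seqs,
            )
        )
    return clones


def write_clones(clones, path: str | Path) -> None:
    rows = [
        {
            "clone_id": c.id,
            "expected_insert": c.expected_insert,
            "marker_ids": ",".join(c.marker_ids),
        }
        for c in clones
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
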