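"""Scaffold-to-BAC assignment, border detection and superscaffolding.

A scaffold is tied to a clone by its anchored genetic markers and BAC-end
sequences; whether the scaffold covers the whole insert is judged from
its *borders* — traces of the cloning vector's 30 bp junction sequences —
searched three ways: (1) the junction at a scaffold extreme, (2) raw
reads that contain the junction aligned back to a scaffold extreme, and
(3) alignment of the clone's Sanger end sequences.  Clones whose
scaffolds fall short of the insert size can be joined into a
superscaffold padded with N to the library's average insert size.

Alignment throughout is infix edit-distance (edlib) with configurable
identity (95%) and length (50 bp) floors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import edlib

from ._util import revcomp
from .seqio import ScaffoldRecord

log = logging.getLogger(__name__)

IDENTITY_FLOOR = 95.0
LENGTH_FLOOR = 50
END_WINDOW = 500   # bp from a scaffold extreme searched for junctions
MIN_GAP = 100      # minimum inserted superscaffold gap (N)

COMPLETENESS_LABELS = (
    "complete", "likely_complete", "partial", "fragmentary", "unassigned",
)


@dataclass
class MarkerHit:
    marker_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class BorderHit:
    scaffold_id: str
    side: str      # left | right
    method: str    # junction_at_extreme | read_with_junction | bac_end_blast
    position: int  # offset from the nearer scaffold end
    strand: str
    percent_identity: float
    clone_id: str | None = None


@dataclass
class Assignment:
    clone_id: str
    scaffold_ids: list[str]
    marker_hits: list[MarkerHit]
    border_hits: list[BorderHit]
    ends_found: int
    completeness: str
    total_length: int = 0


def _best_infix(query: str, target: str):
    """Best infix placement of query in target on either strand.

    Returns (start, end, strand, identity_pct) or None.
    """
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, target, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ident = 100.0 * (len(q) - res["editDistance"]) / len(q)
        loc = res["locations"][0]
        cand = (loc[0], loc[1] + 1, strand, ident)
        if best is None or ident > best[3]:
            best = cand
    return best


def find_marker_hits(
    markers,
    scaffolds,
    identity_floor: float = IDENTITY_FLOOR,
    length_floor: int = LENGTH_FLOOR,
) -> list[MarkerHit]:
    """Best scaffold hit per marker; sub-floor hits suppressed, ties on
    the identity x length score logged as ambiguous and broken by
    scaffold order."""
    hits: list[MarkerHit] = []
    for marker in markers:
        if len(marker.sequence) < length_floor:
            continue
        best: MarkerHit | None = None
        best_score = 0.0
        ambiguous = False
        for scaf in scaffolds:
            placed = _best_infix(marker.sequence, scaf.sequence)
            if placed is None:
                continue
            start, end, strand, ident = placed
            if ident < identity_floor:
                continue
            score = ident * len(marker.sequence)
            if best is None or score > best_score:
                best = MarkerHit(marker.id, scaf.id, start, end, strand, ident)
                best_score = score
                ambiguous = False
            elif score == best_score:
                ambiguous = True
        if best is not None:
            if ambiguous:
                log.warning("marker %s matches several scaffolds equally well; "
                            "keeping %s", marker.id, best.scaffold_id)
            hits.append(best)
    return hits


def _junction_in_window(window: str, junction: str, identity_floor: float):
    placed = _best_infix(junction, window)
    if placed and placed[3] >= identity_floor:
        return placed
    return None


def find_borders(
    scaffolds,
    clones=(),
    junction_left: str = "",
    junction_right: str = "",
    reads=None,
    window: int = END_WINDOW,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[BorderHit]:
    """Detect BAC borders on scaffolds by the three search modes.

    Mode 1 scans ``window`` bp at each scaffold extreme for either 30 bp
    junction on either strand.  Mode 2 runs only when raw ``reads`` are
    supplied: reads containing a junction are aligned to the extremes.
    Mode 3 aligns each clone's Sanger end sequences anywhere on the
    scaffolds (a border can sit mid-superscaffold).
    """
    for j in (junction_left, junction_right):
        if j and len(j) != 30:
            raise ValueError("junction sequences must be 30 bp")
    hits: list[BorderHit] = []
    junctions = [j for j in (junction_left, junction_right) if j]

    for scaf in scaffolds:
        seq = scaf.sequence
        w = min(window, len(seq))
        for side, sub, offset in (("left", seq[:w], 0), ("right", seq[-w:], len(seq) - w)):
            for junc in junctions:
                placed = _junction_in_window(sub, junc, identity_floor)
                if placed:
                    start, end, strand, ident = placed
                    pos = start if side == "left" else len(seq) - (offset + end)
                    hits.append(BorderHit(scaf.id, side, "junction_at_extreme",
                                          pos, strand, ident))
                    break  # one mode-1 hit per extreme is enough

    if reads:
        tagged = [r for r in reads
                  if any(j in r or revcomp(j) in r for j in junctions)]
        for read in tagged:
            core = read
            for j in junctions:
                core = core.replace(j, "").replace(revcomp(j), "")
            if len(core) < LENGTH_FLOOR:
                continue
            for scaf in scaffolds:
                placed = _best_infix(core, scaf.sequence)
                if placed is None or placed[3] < identity_floor:
                    continue
                start, end, strand, ident = placed
                if start <= window:
                    hits.append(BorderHit(scaf.id, "left", "read_with_junction",
                                          start, strand, ident))
                elif len(scaf.sequence) - end <= window:
                    hits.append(BorderHit(scaf.id, "right", "read_with_junction",
                                          len(scaf.sequence) - end, strand, ident))

    for clone in clones:
        for side, end_seq in clone.end_seqs.items():
            if len(end_seq) < LENGTH_FLOOR:
                continue
            for scaf in scaffolds:
                placed = _best_infix(end_seq, scaf.sequence)
                if placed is None or placed[3] < identity_floor:
                    continue
                start, end, strand, ident = placed
                mid = (start + end) / 2
                scaf_side = "left" if mid < len(scaf.sequence) / 2 else "right"
                pos = start if scaf_side == "left" else len(scaf.sequence) - end
                hits.append(BorderHit(scaf.id, scaf_side, "bac_end_blast",
                                      pos, strand, ident, clone_id=clone.id))
    return hits


def classify(ends_found: int, scaffold_length: int, has_marker_hit: bool) -> str:
    """Completeness label from border and marker evidence.

    complete: both borders found; likely_complete: one border and > 100 kb;
    partial: one border and 60-100 kb; fragmentary: no borders but a
    marker anchors the sequence; unassigned otherwise.
    """
    if ends_found >= 2:
        return "complete"
    if ends_found == 1 and scaffold_length > 100_000:
        return "likely_complete"
    if ends_found == 1 and 60_000 <= scaffold_length <= 100_000:
        return "partial"
    if ends_found == 0 and has_marker_hit:
        return "fragmentary"
    return "unassigned"


def assign(
    scaffolds,
    clones,
    markers,
    junction_left: str,
    junction_right: str,
    reads=None,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[Assignment]:
    """Full assignment: marker hits + border evidence -> per-clone labels."""
    marker_hits = find_marker_hits(markers, scaffolds, identity_floor=identity_floor)
    border_hits = find_borders(scaffolds, clones, junction_left, junction_right,
                               reads=reads, identity_floor=identity_floor)
    by_marker = {h.marker_id: h for h in marker_hits}
    lengths = {s.id: len(s) for s in scaffolds}
    borders_by_scaffold: dict[str, list[BorderHit]] = {}
    for h in border_hits:
        borders_by_scaffold.setdefault(h.scaffold_id, []).append(h)

    out: list[Assignment] = []
    for clone in clones:
        m_hits = [by_marker[m] for m in clone.marker_ids if m in by_marker]
        end_hits = [h for h in border_hits
                    if h.method == "bac_end_blast" and h.clone_id == clone.id]
        scaffold_ids: list[str] = []
        for h in m_hits + end_hits:
            if h.scaffold_id not in scaffold_ids:
                scaffold_ids.append(h.scaffold_id)
        evidence_borders = [h for sid in scaffold_ids
                            for h in borders_by_scaffold.get(sid, [])
                            if h.clone_id in (None, clone.id)]
        sides = {(h.scaffold_id, h.side) for h in evidence_borders}
        ends_found = min(len(sides), 2)
        total_len = sum(lengths[s] for s in scaffold_ids)
        out.append(
            Assignment(
                clone_id=clone.id,
                scaffold_ids=scaffold_ids,
                marker_hits=m_hits,
                border_hits=evidence_borders,
                ends_found=ends_found,
                completeness=classify(ends_found, total_len, bool(m_hits)),
                total_length=total_len,
            )
        )
    return out


@dataclass
class Superscaffold:
    parts: list[tuple[str, str]]      # (scaffold_id, orientation)
    inserted_gap_bp: list[int]
    final_length: int
    target_length: int
    sequence: str = ""
    at_floor: bool = False


def superscaffold(parts, target_length: int) -> Superscaffold:
    """Join oriented scaffolds with N gaps so the result reaches the
    expected insert size.

    ``parts`` is an ordered list of (ScaffoldRecord, orientation) with
    orientation "+" or "-".  The total inserted gap is
    ``max(target_length - sum(parts), 100 * n_junctions)``, split evenly
    across junctions (remainder on the last); when the floor applies a
    warning is issued.
    """
    parts = list(parts)
    if len(parts) < 2:
        raise ValueError("superscaffolding needs at least two parts")
    total_parts = sum(len(rec) for rec, _ in parts)
    n_junctions = len(parts) - 1
    total_gap = max(target_length - total_parts, MIN_GAP * n_junctions)
    at_floor = target_length - total_parts < MIN_GAP * n_junctions
    if at_floor:
        warnings.warn(
            f"parts ({total_parts} bp) already reach the target "
            f"({target_length} bp); inserting the {MIN_GAP} N minimum gap "
            "per junction",
            stacklevel=2,
        )
    base = total_gap // n_junctions
    gaps = [base] * n_junctions
    gaps[-1] += total_gap - base * n_junctions
    pieces: list[str] = []
    for i, (rec, orient) in enumerate(parts):
        if orient not in ("+", "-"):
            raise ValueError(f"orientation must be +/- (got {orient!r})")
        pieces.append(rec.sequence if orient == "+" else revcomp(rec.sequence))
        if i < n_junctions:
            pieces.append("N" * gaps[i])
    seq = "".join(pieces)
    return Superscaffold(
        parts=[(rec.id, orient) for rec, orient in parts],
        inserted_gap_bp=gaps,
        final_length=len(seq),
        target_length=target_length,
        sequence=seq,
        at_floor=at_floor,
    )
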