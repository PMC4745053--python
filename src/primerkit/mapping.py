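"""Positional outputs and primer-map graphics.

Every accepted primer becomes one positional record — a 1-based inclusive
plus-strand interval with a strand sign — written as TSV (the lossless,
round-trippable exchange format) and JSON lines (for external viewers).
Maps are rendered as SVG: one scaled ruler per sequence, an arrowed glyph
per primer pointing 3'-ward (right for +, left for -), an optional SNP
marker, and a concatenated all-sequence view that lays the inputs
end-to-end in file order with zero gap.

``primer_from_coordinates`` is the "draw a primer" operation: a
left-to-right coordinate pair returns the forward substring, a
right-to-left pair returns the reverse complement, each with its GC% and
Tm.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import thermo
from .design import BatchResult, PrimerCandidate
from .seqio import SequenceRecord, reverse_complement
from .thermo import ThermoConditions

PRIMER_COLOR = "#1f4fd8"   # blue glyphs, per the classic map styling
SNP_COLOR = "#1faa3c"      # green SNP marker

_POSITIONS_HEADER = "source_id\tname\tstart\tend\tstrand\tsequence"


@dataclass(frozen=True)
class PositionalRecord:
    """Plus-strand footprint of one primer: [start, end], 1-based inclusive."""

    source_id: str
    name: str
    start: int
    end: int
    strand: str                 # "+" | "-"
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("interval length != primer length")


@dataclass(frozen=True)
class MapLayout:
    """Rendering geometry for the maps."""

    pixels_per_base: float = 1.0
    lane_height: int = 14
    margin: int = 40

    def __post_init__(self) -> None:
        if self.pixels_per_base <= 0:
            raise ValueError("pixels_per_base must be positive")


def positional_records(result: BatchResult) -> list[PositionalRecord]:
    """One positional row per accepted primer, in input-record order."""
    return [positional_record(p) for p in result.all_primers]


def positional_record(primer: PrimerCandidate) -> PositionalRecord:
    start, end = primer.plus_span
    return PositionalRecord(
        source_id=primer.source_id,
        name=primer.name,
        start=start,
        end=end,
        strand="+" if primer.orientation == "forward" else "-",
        sequence=primer.sequence,
    )


def write_positions_tsv(rows: Iterable[PositionalRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(_POSITIONS_HEADER + "\n")
        for r in rows:
            fh.write(f"{r.source_id}\t{r.name}\t{r.start}\t{r.end}\t{r.strand}\t{r.sequence}\n")


def read_positions_tsv(path: str | Path) -> list[PositionalRecord]:
    rows: list[PositionalRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _POSITIONS_HEADER:
            raise ValueError(f"unexpected positional TSV header: {header!r}")
        for line in fh:
            source_id, name, start, end, strand, sequence = line.rstrip("\n").split("\t")
            rows.append(PositionalRecord(source_id, name, int(start), int(end), strand, sequence))
    return rows


def write_positions_json(rows: Iterable[PositionalRecord], path: str | Path) -> None:
    """JSON-lines export: one object per primer, for external viewers."""
    with open(path, "w", newline="\n") as fh:
        for r in rows:
            fh.write(json.dumps(
                {"source_id": r.source_id, "name": r.name, "start": r.start,
                 "end": r.end, "strand": r.strand},
                sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

def _assign_lanes(
    rows: Sequence[PositionalRecord],
) -> tuple[list[PositionalRecord], list[int]]:
    """Greedy first-free-lane stacking for overlapping glyphs.

    Returns the rows sorted by coordinate together with a parallel list
    of lane indices.
    """
    ordered = sorted(rows, key=lambda r: (r.start, r.end, r.strand, r.name, r.source_id))
    lanes: list[int] = []      # rightmost occupied coordinate per lane
    assignment: list[int] = []
    for r in ordered:
        for i, right in enumerate(lanes):
            if r.start > right:
                assignment.append(i)
                lanes[i] = r.end
                break
        else:
            assignment.append(len(lanes))
            lanes.append(r.end)
    return ordered, assignment


def _tick_spacing(length: int) -> int:
    spacing = 10
    while length / spacing > 20:
        spacing *= 10
    return spacing


def _svg_root(width: float, height: float) -> ET.Element:
    return ET.Element(
        "svg",
        {"xmlns": "http://www.w3.org/2000/svg", "version": "1.1",
         "width": f"{width:.0f}", "height": f"{height:.0f}",
         "viewBox": f"0 0 {width:.0f} {height:.0f}"},
    )


def _add_ruler(parent: ET.Element, x0: float, y: float, length: int, scale: float,
               label_offset: int = 0) -> None:
    g = ET.SubElement(parent, "g", {"class": "ruler"})
    ET.SubElement(g, "line", {
        "x1": f"{x0:.1f}", "y1": f"{y:.1f}",
        "x2": f"{x0 + length * scale:.1f}", "y2": f"{y:.1f}",
        "stroke": "black"})
    for pos in range(0, length + 1, _tick_spacing(length)):
        x = x0 + pos * scale
        ET.SubElement(g, "line", {
            "x1": f"{x:.1f}", "y1": f"{y:.1f}", "x2": f"{x:.1f}", "y2": f"{y + 5:.1f}",
            "stroke": "black"})
        t = ET.SubElement(g, "text", {
            "x": f"{x:.1f}", "y": f"{y + 16:.1f}", "font-size": "9",
            "text-anchor": "middle"})
        t.text = str(pos + label_offset)


def _add_primer_glyph(parent: ET.Element, row: PositionalRecord, x0: float,
                      lane_y: float, scale: float, offset: int = 0) -> None:
    xs = x0 + (row.start - 1 + offset) * scale
    xe = x0 + (row.end + offset) * scale
    head = min(6.0, (xe - xs) / 3)
    mid = lane_y + 4
    if row.strand == "+":
        pts = [(xs, lane_y), (xe - head, lane_y), (xe, mid),
               (xe - head, lane_y + 8), (xs, lane_y + 8)]
    else:
        pts = [(xe, lane_y), (xs + head, lane_y), (xs, mid),
               (xs + head, lane_y + 8), (xe, lane_y + 8)]
    g = ET.SubElement(parent, "g", {"class": "primer"})
    ET.SubElement(g, "polygon", {
        "points": " ".join(f"{x:.1f},{y:.1f}" for x, y in pts),
        "fill": PRIMER_COLOR})
    t = ET.SubElement(g, "text", {
        "x": f"{(xs + xe) / 2:.1f}", "y": f"{lane_y - 2:.1f}",
        "font-size": "8", "text-anchor": "middle"})
    t.text = row.name


def _add_snp_marker(parent: ET.Element, x: float, y: float) -> None:
    g = ET.SubElement(parent, "g", {"class": "snp-marker"})
    ET.SubElement(g, "polygon", {
        "points": f"{x:.1f},{y:.1f} {x - 5:.1f},{y - 10:.1f} {x + 5:.1f},{y - 10:.1f}",
        "fill": SNP_COLOR})


def _serialize(root: ET.Element) -> str:
    return ET.tostring(root, encoding="unicode") + "\n"


def render_sequence_map(
    record: SequenceRecord,
    rows: Sequence[PositionalRecord],
    snp_position: int | None = None,
    layout: MapLayout = MapLayout(),
) -> str:
    """Scaled per-sequence primer map as an SVG 1.1 document string."""
    for r in rows:
        if r.source_id != record.id:
            raise ValueError(f"positional record {r.name!r} belongs to {r.source_id!r}")
        if r.end > len(record):
            raise ValueError(f"positional record {r.name!r} exceeds sequence length")
    if snp_position is not None and not 1 <= snp_position <= len(record):
        raise ValueError(f"SNP position {snp_position} outside sequence")
    ordered, lanes = _assign_lanes(rows)
    n_lanes = (max(lanes) + 1) if lanes else 1
    scale = layout.pixels_per_base
    x0 = float(layout.margin)
    width = 2 * layout.margin + len(record) * scale
    top = 30.0
    ruler_y = top + n_lanes * (layout.lane_height + 10) + 20
    root = _svg_root(width, ruler_y + 40)
    title = ET.SubElement(root, "text", {
        "x": f"{x0:.1f}", "y": "18", "font-size": "12", "class": "title"})
    title.text = record.description or record.id
    for r, lane in zip(ordered, lanes):
        lane_y = top + lane * (layout.lane_height + 10) + 10
        _add_primer_glyph(root, r, x0, lane_y, scale)
    if snp_position is not None:
        _add_snp_marker(root, x0 + (snp_position - 0.5) * scale, ruler_y - 4)
    _add_ruler(root, x0, ruler_y, len(record), scale)
    return _serialize(root)


def render_concatenated_map(
    records: Sequence[SequenceRecord],
    rows_by_record: dict[str, Sequence[PositionalRecord]],
    snp_positions: dict[str, int] | None = None,
    layout: MapLayout = MapLayout(),
) -> str:
    """All-sequence view: records end-to-end, input order, zero gap.

    A primer at local start s in record i appears at global coordinate
    offset(i) + s, where offset(i) is the summed length of the preceding
    records.
    """
    offsets = global_offsets(records)
    total = sum(len(r) for r in records)
    # Lane assignment on globalized intervals.
    global_rows = [
        PositionalRecord(rec.id, row.name, row.start + offsets[rec.id],
                         row.end + offsets[rec.id], row.strand, row.sequence)
        for rec in records
        for row in rows_by_record.get(rec.id, [])
    ]
    ordered, lanes = _assign_lanes(global_rows)
    n_lanes = (max(lanes) + 1) if lanes else 1
    scale = layout.pixels_per_base
    x0 = float(layout.margin)
    width = 2 * layout.margin + total * scale
    top = 30.0
    ruler_y = top + n_lanes * (layout.lane_height + 10) + 20
    root = _svg_root(width, ruler_y + 60)
    title = ET.SubElement(root, "text", {
        "x": f"{x0:.1f}", "y": "18", "font-size": "12", "class": "title"})
    title.text = f"concatenated view: {len(records)} sequences, {total} bp"
    for grow, lane in zip(ordered, lanes):
        lane_y = top + lane * (layout.lane_height + 10) + 10
        _add_primer_glyph(root, grow, x0, lane_y, scale)
    if snp_positions:
        for rec in records:
            if rec.id in snp_positions:
                x = x0 + (offsets[rec.id] + snp_positions[rec.id] - 0.5) * scale
                _add_snp_marker(root, x, ruler_y - 4)
    _add_ruler(root, x0, ruler_y, total, scale)
    # Record boundaries: tick + label per record start.
    bounds = ET.SubElement(root, "g", {"class": "boundaries"})
    for rec in records:
        x = x0 + offsets[rec.id] * scale
        ET.SubElement(bounds, "line", {
            "x1": f"{x:.1f}", "y1": f"{ruler_y - 8:.1f}",
            "x2": f"{x:.1f}", "y2": f"{ruler_y + 8:.1f}", "stroke": "red"})
        t = ET.SubElement(bounds, "text", {
            "x": f"{x:.1f}", "y": f"{ruler_y + 34:.1f}", "font-size": "9"})
        t.text = rec.id
    return _serialize(root)


def global_offsets(records: Sequence[SequenceRecord]) -> dict[str, int]:
    """Cumulative zero-gap start offset of each record in the concatenation."""
    offsets: dict[str, int] = {}
    acc = 0
    for rec in records:
        offsets[rec.id] = acc
        acc += len(rec)
    return offsets


# ---------------------------------------------------------------------------
# Coordinate -> primer ("draw" operation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrawnPrimer:
    sequence: str
    gc: float
    tm: float
    orientation: str


def primer_from_coordinates(
    record: SequenceRecord,
    a: int,
    b: int,
    conditions: ThermoConditions = thermo.DEFAULT_CONDITIONS,
) -> DrawnPrimer:
    """Primer picked by two map coordinates.

    Left-to-right (a < b) returns the forward substring [a, b]; right-to-
    left (a > b) returns the reverse complement of [b, a].  The span must
    be at least 8 nt so a Tm is defined.
    """
    L = len(record)
    if not (1 <= a <= L and 1 <= b <= L):
        raise ValueError(f"coordinates ({a}, {b}) outside 1..{L}")
    if a == b:
        raise ValueError("coordinates must differ")
    lo, hi = min(a, b), max(a, b)
    if hi - lo + 1 < 8:
        raise ValueError(f"span {hi - lo + 1} nt too short for a primer (need >= 8)")
    seq = record.subsequence(lo, hi)
    if a > b:
        seq = reverse_complement(seq)
        orientation = "reverse"
    else:
        orientation = "forward"
    return DrawnPrimer(
        sequence=seq,
        gc=thermo.gc_percent(seq),
        tm=thermo.tm(seq, conditions),
        orientation=orientation,
    )
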