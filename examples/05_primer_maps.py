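"""Positional records, SVG primer maps, and coordinate-drawn primers.

Designs primers for two templates, writes the positional TSV, renders a
per-sequence map and the concatenated all-sequence map, and finally
"draws" a primer by picking two coordinates — right-to-left yields the
reverse-complemented primer.
"""

from pathlib import Path

from primerkit import DesignParams, design_batch, primer_from_coordinates
from primerkit.mapping import (
    positional_records,
    render_concatenated_map,
    render_sequence_map,
    write_positions_tsv,
)
from primerkit.simulate import random_dna_records

out = Path("scratch_maps")
out.mkdir(exist_ok=True)

records = random_dna_records(n_records=2, length=350, seed=21)
result = design_batch(records, DesignParams())
rows = positional_records(result)
write_positions_tsv(rows, out / "positions.tsv")
print(f"{len(rows)} positional rows -> {out / 'positions.tsv'}")

by_record = {r.id: [x for x in rows if x.source_id == r.id] for r in records}
GLYPH = 'class="primer"'
for rec in records:
    svg = render_sequence_map(rec, by_record[rec.id])
    (out / f"map_{rec.id}.svg").write_text(svg)
    print(f"map_{rec.id}.svg: {svg.count(GLYPH)} primer glyphs")
concat = render_concatenated_map(records, by_record)
(out / "map_all.svg").write_text(concat)
print(f"map_all.svg: {concat.count(GLYPH)} glyphs across both records")

drawn = primer_from_coordinates(records[0], 40, 21)  # right to left
print(f"drawn primer (40 -> 21): {drawn.sequence}  {drawn.orientation}  "
      f"GC% {drawn.gc:.1f}  Tm {drawn.tm:.1f}")
# In the SVG each primer is an arrowed glyph pointing in the direction of
# synthesis, stacked into lanes where primers overlap, above a scaled
# base-pair ruler; the concatenated view lays records end-to-end.
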