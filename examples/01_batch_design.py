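"""Design a primer pool for every record of a small FASTA-like input.

Builds two 400-nt random templates, scans the first and last 150 bp of
each for primers of 18-27 nt with GC 35-65% and Tm 52-62 °C, and prints
the accepted pool.  Each primer is named by the 1-based plus-strand
coordinate of its 5' terminus.
"""

from primerkit import DesignParams, design_batch, random_dna_records
from primerkit.tables import primers_frame

records = random_dna_records(n_records=2, length=400, seed=42)
params = DesignParams()  # defaults: 18-27 nt, Tm 52-62, GC 35-65, windows 150

result = design_batch(records, params)
for rec in records:
    primers = result.primers_by_record[rec.id]
    print(f"{rec.id}: {len(primers)} primers accepted")

frame = primers_frame(result.all_primers)
print(frame.head(8).to_string(index=False))
# Each row is one accepted primer: its source record, name (= 5' start),
# orientation, footprint, sequence, and the Tm/GC/structure scores that
# cleared the filters (selfcomp < 10, hairpin dG >= -6 kcal/mol).
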