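"""All-pairs cross-dimer screen for a multiplex primer pool.

Designs a pool, then scores every unordered primer pairing — n choose 2
combinations — for cross-complementarity.  High scores flag pairs likely
to form primer dimers in a multiplex reaction.
"""

from primerkit import DesignParams, design_batch, dimer_report
from primerkit.simulate import random_dna_records

records = random_dna_records(n_records=2, length=300, seed=3)
pool = design_batch(records, DesignParams()).all_primers[:12]

report = dimer_report(pool)
print(f"n = {report.n} primers -> {len(report.pairs)} pairings "
      f"(= {report.n}*({report.n}-1)/2)")

worst = sorted(report.pairs, key=lambda p: -p[2])[:5]
for a, b, score in worst:
    print(f"  {a}  x  {b}  score {score}")
print("flagged at >= 10:", len(report.flagged(10)))
# The score is the largest number of Watson-Crick base pairs the two
# primers can form in any ungapped antiparallel alignment; pairs at or
# above the flag level deserve a second look before pooling.
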