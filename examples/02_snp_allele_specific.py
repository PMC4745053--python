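"""SNP-flanking pools and allele-specific genotyping primers.

Simulates a canonical dbSNP-style record — 1001 nt with an IUPAC
ambiguity code at position 501 — then designs (1) a pool of primers that
bracket the SNP, and (2) allele-specific primers whose 3'-terminal base
sits exactly on the SNP so polymerase extension discriminates alleles.
"""

from primerkit import DesignParams, design_allele_specific, design_snp_flanking
from primerkit.simulate import random_snp_records

(snp,) = random_snp_records(n_records=1, length=1001, seed=7)
print(f"{snp.id}: code {snp.iupac_code} at {snp.snp_position}, alleles {snp.alleles}")

params = DesignParams()
flanking = design_snp_flanking(snp, params)
fwd = [p for p in flanking if p.orientation == "forward"]
rev = [p for p in flanking if p.orientation == "reverse"]
print(f"flanking pool: {len(fwd)} forward (3' ends <= 500), "
      f"{len(rev)} reverse (starts >= 502)")

allele_primers, problems = design_allele_specific(snp, params)
for ap in allele_primers:
    c = ap.candidate
    print(f"  {ap.label:12s} allele {ap.allele} {c.orientation:7s} "
          f"len {c.length}  3'-base {c.sequence[-1]}  Tm {c.tm:.1f}")
for combo, why in problems.items():
    print(f"  (no primer for {combo}: {why})")
# Forward primers end in the allele base itself; reverse primers end in
# its complement.  The first allele alphabetically is labelled "wildtype"
# by convention.
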