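"""Independently coded constraint verifier for accepted primers.

Re-derives every enabled design constraint from scratch — its own
complement logic, Biopython's nearest-neighbor Tm, the brute-force
structural oracles — so a primer passing here confirms the design
engine's filters, not merely replays them.
"""

import re

from Bio.SeqUtils import MeltingTemp as bio_mt

from oracles import brute_hairpin, brute_revcomp, brute_self_comp, brute_specificity

_BIO_TABLE = {"breslauer": bio_mt.DNA_NN1, "santalucia": bio_mt.DNA_NN3}
_BIO_SALTCORR = {"breslauer": 1, "santalucia": 6}


def independent_tm(seq: str, conditions) -> float:
    half_ct_nm = conditions.primer_concentration * 1e9 / 2
    return bio_mt.Tm_NN(
        seq,
        nn_table=_BIO_TABLE[conditions.engine],
        Na=conditions.monovalent_salt * 1000,
        dnac1=half_ct_nm,
        dnac2=half_ct_nm,
        saltcorr=_BIO_SALTCORR[conditions.engine],
    )


def verify_candidate(primer, record, record_set, params) -> list[str]:
    """Return a list of violated constraints (empty = fully compliant)."""
    failures = []
    seq = primer.sequence
    lo, hi = primer.plus_span
    template_window = record.residues[lo - 1 : hi]
    if primer.orientation == "forward":
        if seq != template_window:
            failures.append("sequence != template substring")
    else:
        if seq != brute_revcomp(template_window):
            failures.append("sequence != reverse complement of template substring")
    if not params.primer_len_min <= len(seq) <= params.primer_len_max:
        failures.append("length out of range")
    gc = 100.0 * sum(c in "GC" for c in seq) / len(seq)
    if not params.gc_min <= gc <= params.gc_max:
        failures.append("GC% out of range")
    tm = independent_tm(seq, params.thermo)
    if not params.tm_min - 1e-6 <= tm <= params.tm_max + 1e-6:
        failures.append(f"Tm {tm:.2f} out of range")
    if not params.allow_repeats:
        if re.search(r"(A{6,}|C{6,}|G{6,}|T{6,})", seq):
            failures.append("mononucleotide run >= 6")
        if re.search(r"([ACGT]{2})\1{4,}", seq) and any(
            m.group(1)[0] != m.group(1)[1]
            for m in re.finditer(r"([ACGT]{2})\1{4,}", seq)
        ):
            failures.append("dinucleotide tandem >= 5")
    if params.require_gc_clamp and seq[-1] not in "GC":
        failures.append("missing GC clamp")
    if brute_self_comp(seq) >= params.thresholds.selfcomp_max:
        failures.append("self-complementarity over threshold")
    if brute_hairpin(seq) < params.thresholds.hairpin_dg_min:
        failures.append("hairpin below floor")
    if params.check_specificity:
        count = brute_specificity(seq, [r.residues for r in record_set],
                                  params.max_mismatches)
        if count != 1:
            failures.append(f"specificity count {count} != 1")
    return failures
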