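"""Batch primer design: window scanning, filtering, specificity, SNP work.

The engine scans a 5' search window for forward primers and a 3' search
window for reverse primers (e.g. a 5' window of 150 means the first
150 bp of each sequence is searched), applies composition, thermodynamic
and structural filters, and optionally requires each primer to occur
exactly once — up to a mismatch allowance — across the entire input set.

For SNP records it designs flanking pools that bracket the polymorphic
site, and allele-specific genotyping primers whose 3'-terminal base sits
exactly on the SNP and matches one allele (forward) or its complement
(reverse), so that polymerase extension succeeds only on the matching
template.

Primers are named by the 1-based plus-strand coordinate of their 5'
terminus, so a reverse primer named "554" lies rightward of a forward
primer named "83".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from . import scoring, thermo
from .scoring import ScoreThresholds
from .seqio import COMPLEMENT, SequenceRecord, SnpRecord, reverse_complement
from .thermo import ThermoConditions


@dataclass(frozen=True)
class DesignParams:
    """All user-tunable design constraints."""

    primer_len_min: int = 18
    primer_len_max: int = 27
    tm_min: float = 52.0
    tm_max: float = 62.0
    gc_min: float = 35.0
    gc_max: float = 65.0
    window5: int = 150          # forward-search span from the 5' end (nt)
    window3: int = 150          # reverse-search span from the 3' end (nt)
    require_gc_clamp: bool = False
    allow_repeats: bool = False
    check_specificity: bool = False
    max_mismatches: int = 0
    max_primers_per_record: int | None = None
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    thermo: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        if not 8 <= self.primer_len_min <= self.primer_len_max:
            raise ValueError("need 8 <= primer_len_min <= primer_len_max")
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min > tm_max")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min > gc_max")
        if min(self.window5, self.window3) < self.primer_len_min:
            raise ValueError("search windows must be >= primer_len_min")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class PrimerCandidate:
    """A designed primer anchored on its source sequence.

    ``start`` is the 1-based plus-strand coordinate of the 5' terminus;
    for reverse primers the plus-strand footprint is
    [start - length + 1, start] and ``sequence`` is its reverse
    complement.  ``name`` is the decimal rendering of ``start``.
    """

    source_id: str
    orientation: str            # "forward" | "reverse"
    start: int
    length: int
    sequence: str
    tm: float = float("nan")
    gc: float = float("nan")
    selfcomp: int = -1
    hairpin: float = float("nan")

    @property
    def name(self) -> str:
        return str(self.start)

    @property
    def label(self) -> str:
        """Globally unambiguous identifier (names repeat across records and
        lengths)."""
        tag = "F" if self.orientation == "forward" else "R"
        return f"{self.source_id}|{tag}|{self.start}|{self.length}"

    @property
    def plus_span(self) -> tuple[int, int]:
        """1-based inclusive plus-strand footprint (start, end)."""
        if self.orientation == "forward":
            return self.start, self.start + self.length - 1
        return self.start - self.length + 1, self.start

    def with_scores(self, params: DesignParams) -> "PrimerCandidate":
        return replace(
            self,
            tm=thermo.tm(self.sequence, params.thermo),
            gc=thermo.gc_percent(self.sequence),
            selfcomp=scoring.self_complementarity(self.sequence),
            hairpin=scoring.hairpin_dg(self.sequence),
        )


@dataclass(frozen=True)
class AlleleSpecificPrimer:
    """An allele-discriminating genotyping primer for one SNP."""

    candidate: PrimerCandidate
    allele: str
    label: str                  # "wildtype" | "polymorphic"
    snp_id: str


@dataclass(frozen=True)
class DimerReport:
    """All-pairs cross-dimer screen: C(n, 2) unordered primer pairings."""

    n: int
    pairs: list[tuple[str, str, int]]
    k: int = 2

    def __post_init__(self) -> None:
        expected = self.n * (self.n - 1) // 2
        if len(self.pairs) != expected:
            raise ValueError(f"expected C({self.n},2) = {expected} pairs, got {len(self.pairs)}")

    def flagged(self, level: int) -> list[tuple[str, str, int]]:
        return [p for p in self.pairs if p[2] >= level]


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _forward_candidates(record, lo: int, hi: int, params) -> list[PrimerCandidate]:
    """Forward candidates fully inside the 1-based span [lo, hi]."""
    out = []
    for start in range(lo, hi + 1):
        for length in range(params.primer_len_min, params.primer_len_max + 1):
            if start + length - 1 > hi:
                break
            out.append(
                PrimerCandidate(
                    source_id=record.id,
                    orientation="forward",
                    start=start,
                    length=length,
                    sequence=record.subsequence(start, start + length - 1),
                )
            )
    return out


def _reverse_candidates(record, lo: int, hi: int, params) -> list[PrimerCandidate]:
    """Reverse candidates whose plus-strand footprint lies inside [lo, hi]."""
    out = []
    for end in range(lo, hi + 1):
        for length in range(params.primer_len_min, params.primer_len_max + 1):
            u = end - length + 1
            if u < lo:
                break
            out.append(
                PrimerCandidate(
                    source_id=record.id,
                    orientation="reverse",
                    start=end,
                    length=length,
                    sequence=reverse_complement(record.subsequence(u, end)),
                )
            )
    return out


def enumerate_candidates(record: SequenceRecord, params: DesignParams) -> list[PrimerCandidate]:
    """Every raw forward/reverse candidate inside the search windows.

    Windows larger than the sequence are clipped; no filter is applied.
    """
    L = len(record)
    if L < params.primer_len_min:
        raise ValueError(
            f"record {record.id!r}: length {L} shorter than primer_len_min "
            f"{params.primer_len_min}"
        )
    fwd = _forward_candidates(record, 1, min(params.window5, L), params)
    rev = _reverse_candidates(record, max(1, L - params.window3 + 1), L, params)
    return fwd + rev


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def specificity_count(
    primer: str,
    records: list[SequenceRecord],
    max_mismatches: int = 0,
) -> int:
    """Occurrences of a primer across all records and both strands.

    Counts every ungapped alignment position with Hamming distance
    <= ``max_mismatches``; the primer's own origin site counts, so a
    specific primer scores exactly 1.  Records shorter than the primer
    contribute 0.
    """
    p = primer.upper()
    if set(p) - set("ACGT"):
        raise ValueError("primer must be unambiguous A/C/G/T")
    queries = (_encode(p), _encode(reverse_complement(p)))
    total = 0
    for rec in records:
        t = _encode(rec.residues)
        if len(t) < len(p):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
        for q in queries:
            mismatches = (windows != q).sum(axis=1)
            total += int((mismatches <= max_mismatches).sum())
    return total


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rejection:
    candidate: PrimerCandidate
    reason: str


def apply_filters(
    candidates: list[PrimerCandidate],
    record_set: list[SequenceRecord],
    params: DesignParams,
    exempt_gc_clamp: bool = False,
    collect_rejections: bool = False,
) -> list[PrimerCandidate] | tuple[list[PrimerCandidate], list[Rejection]]:
    """Constraint gauntlet, cheap tests first.

    A candidate survives iff GC% and Tm are in range, the repeat screen
    passes (unless repeats are allowed), a GC clamp is present when
    required, self-complementarity is strictly below the threshold,
    hairpin ΔG is at or above the floor, and — when specificity checking
    is on — it occurs exactly once in the whole record set within the
    mismatch allowance.  Survivors are deduplicated by (sequence,
    orientation) keeping the smallest start, then sorted by start.
    """
    accepted: list[PrimerCandidate] = []
    rejections: list[Rejection] = []

    def reject(cand: PrimerCandidate, reason: str) -> None:
        if collect_rejections:
            rejections.append(Rejection(cand, reason))

    for cand in candidates:
        seq = cand.sequence
        gc = thermo.gc_percent(seq)
        if not params.gc_min <= gc <= params.gc_max:
            reject(cand, f"GC% {gc:.1f} outside [{params.gc_min}, {params.gc_max}]")
            continue
        if not params.allow_repeats:
            ok, why = scoring.repeat_filter(seq)
            if not ok:
                reject(cand, why)
                continue
        if params.require_gc_clamp and not exempt_gc_clamp and not scoring.has_gc_clamp(seq):
            reject(cand, "no 3' GC clamp")
            continue
        tm_val = thermo.tm(seq, params.thermo)
        if not params.tm_min <= tm_val <= params.tm_max:
            reject(cand, f"Tm {tm_val:.2f} outside [{params.tm_min}, {params.tm_max}]")
            continue
        selfcomp = scoring.self_complementarity(seq)
        if selfcomp >= params.thresholds.selfcomp_max:
            reject(cand, f"self-complementarity {selfcomp} >= {params.thresholds.selfcomp_max}")
            continue
        hairpin = scoring.hairpin_dg(seq)
        if hairpin < params.thresholds.hairpin_dg_min:
            reject(cand, f"hairpin ΔG {hairpin:.1f} below {params.thresholds.hairpin_dg_min}")
            continue
        if params.check_specificity:
            count = specificity_count(seq, record_set, params.max_mismatches)
            if count != 1:
                reject(cand, f"specificity count {count} != 1")
                continue
        accepted.append(
            replace(cand, tm=tm_val, gc=gc, selfcomp=selfcomp, hairpin=hairpin)
        )

    # Dedup by (sequence, orientation), keeping the smallest start.
    best: dict[tuple[str, str], PrimerCandidate] = {}
    for cand in accepted:
        key = (cand.sequence, cand.orientation)
        if key not in best or cand.start < best[key].start:
            best[key] = cand
    result = sorted(best.values(), key=lambda c: (c.start, c.orientation, c.length))
    if params.max_primers_per_record is not None:
        result = result[: params.max_primers_per_record]
    if collect_rejections:
        return result, rejections
    return result


# ---------------------------------------------------------------------------
# Batch design
# ---------------------------------------------------------------------------

@dataclass
class BatchResult:
    """Design output for a whole input file, in input order."""

    records: list[SequenceRecord]
    primers_by_record: dict[str, list[PrimerCandidate]]
    errors: dict[str, str]

    @property
    def all_primers(self) -> list[PrimerCandidate]:
        out: list[PrimerCandidate] = []
        for rec in self.records:
            out.extend(self.primers_by_record.get(rec.id, []))
        return out


def design_batch(records: list[SequenceRecord], params: DesignParams) -> BatchResult:
    """Enumerate-and-filter every record; per-record failures do not abort."""
    if not records:
        raise ValueError("no input records")
    primers: dict[str, list[PrimerCandidate]] = {}
    errors: dict[str, str] = {}
    for rec in records:
        try:
            raw = enumerate_candidates(rec, params)
            primers[rec.id] = apply_filters(raw, records, params)
        except ValueError as exc:
            errors[rec.id] = str(exc)
            primers[rec.id] = []
    return BatchResult(records=records, primers_by_record=primers, errors=errors)


# ---------------------------------------------------------------------------
# SNP design
# ---------------------------------------------------------------------------

def design_snp_flanking(snp: SnpRecord, params: DesignParams) -> list[PrimerCandidate]:
    """Primer pool bracketing the SNP.

    Forward primers live entirely in [snp_position - window5,
    snp_position - 1]; reverse primers in [snp_position + 1,
    snp_position + window3] (plus-strand footprints).  Any forward +
    reverse pair therefore spans the polymorphic site, and no candidate
    window contains the ambiguity code itself.
    """
    pos, L = snp.snp_position, len(snp)
    f_lo, f_hi = max(1, pos - params.window5), pos - 1
    r_lo, r_hi = pos + 1, min(L, pos + params.window3)
    if f_hi - f_lo + 1 < params.primer_len_min:
        raise ValueError(f"record {snp.id!r}: SNP too close to 5' end for any primer")
    if r_hi - r_lo + 1 < params.primer_len_min:
        raise ValueError(f"record {snp.id!r}: SNP too close to 3' end for any primer")
    raw = _forward_candidates(snp.record, f_lo, f_hi, params) + \
        _reverse_candidates(snp.record, r_lo, r_hi, params)
    return apply_filters(raw, [snp.record], params)


def design_allele_specific(
    snp: SnpRecord, params: DesignParams
) -> tuple[list[AlleleSpecificPrimer], dict[str, str]]:
    """Allele-discriminating primers whose 3' terminus sits on the SNP.

    For each allele and orientation, lengths from primer_len_min to
    primer_len_max are scanned; among those whose Tm falls inside
    [tm_min, tm_max] the one closest to the Tm midpoint wins (tie ->
    shorter).  A forward primer ends in the allele base; a reverse primer
    ends in its complement.  The GC-clamp requirement never applies here
    (the terminal base is dictated by the allele).  The alphabetically
    first allele is labelled "wildtype", the rest "polymorphic" — a
    naming convention, not an ancestral-state claim.

    Returns (primers, problems) where ``problems`` maps
    "<allele>/<orientation>" to a message for combinations with no
    admissible length.
    """
    pos, L = snp.snp_position, len(snp)
    mid = (params.tm_min + params.tm_max) / 2.0
    primers: list[AlleleSpecificPrimer] = []
    problems: dict[str, str] = {}
    for allele in snp.alleles:
        label = "wildtype" if allele == snp.alleles[0] else "polymorphic"
        for orientation in ("forward", "reverse"):
            best: PrimerCandidate | None = None
            best_dist = float("inf")
            for length in range(params.primer_len_min, params.primer_len_max + 1):
                if orientation == "forward":
                    lo = pos - length + 1
                    if lo < 1:
                        continue
                    seq = snp.record.subsequence(lo, pos - 1) + allele if length > 1 else allele
                    cand = PrimerCandidate(snp.id, "forward", lo, length, seq)
                else:
                    hi = pos + length - 1
                    if hi > L:
                        continue
                    plus = allele + snp.record.subsequence(pos + 1, hi)
                    cand = PrimerCandidate(snp.id, "reverse", hi, length, reverse_complement(plus))
                tm_val = thermo.tm(cand.sequence, params.thermo)
                if not params.tm_min <= tm_val <= params.tm_max:
                    continue
                dist = abs(tm_val - mid)
                if dist < best_dist or (dist == best_dist and best is not None and length < best.length):
                    best = cand.with_scores(params)
                    best_dist = dist
            if best is None:
                problems[f"{allele}/{orientation}"] = (
                    f"no length in [{params.primer_len_min}, {params.primer_len_max}] "
                    f"gives Tm in [{params.tm_min}, {params.tm_max}]"
                )
            else:
                primers.append(AlleleSpecificPrimer(best, allele, label, snp.id))
    return primers, problems


# ---------------------------------------------------------------------------
# Dimer report
# ---------------------------------------------------------------------------

def dimer_report(primers: list[PrimerCandidate]) -> DimerReport:
    """Cross-dimer score for every unordered pair (n choose 2).

    Rows are sorted by (first label, second label) for a stable output.
    """
    if len(primers) < 2:
        raise ValueError("need at least 2 primers for a dimer report")
    rows = []
    for a, b in itertools.combinations(primers, 2):
        la, lb = sorted((a.label, b.label))
        seq_a = a.sequence if la == a.label else b.sequence
        seq_b = b.sequence if la == a.label else a.sequence
        rows.append((la, lb, scoring.cross_dimer_score(seq_a, seq_b)))
    rows.sort(key=lambda r: (r[0], r[1]))
    return DimerReport(n=len(primers), pairs=rows)
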