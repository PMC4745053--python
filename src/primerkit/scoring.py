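"""Structural quality scores and composition filters for primer candidates.

The dimer scores use a shift-maximized Watson-Crick pairing count: the
primer (or primer pair) is slid along the reverse complement of its
partner at every relative offset, and the score is the largest number of
aligned identical bases — i.e. the most base pairs the two strands can
form in an ungapped antiparallel annealing.  The hairpin score is an
additive stem-loop ΔG over ungapped stems of >= 3 pairs with loops of
3-12 nt (A·T = -1.0, G·C = -1.5 kcal/mol per pair, flat +3.5 kcal/mol
loop penalty); a primer with no admissible negative-ΔG fold scores 0.

Default thresholds: self-complementarity accepted strictly below 10;
hairpin ΔG accepted at or above a floor of -6.0 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import reverse_complement

_PAIR_ENERGY = {"A": -1.0, "T": -1.0, "G": -1.5, "C": -1.5}  # keyed by stem base
_LOOP_PENALTY = 3.5
_MIN_STEM = 3
_LOOP_RANGE = (3, 12)
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ScoreThresholds:
    """Accept/reject levels for structural scores.

    selfcomp_max : exclusive upper bound on the self-complementarity score.
    hairpin_dg_min : ΔG floor (kcal/mol); candidates folding below it reject.
    dimer_flag_level : cross-dimer score at/above which a pair is flagged.
    """

    selfcomp_max: int = 10
    hairpin_dg_min: float = -6.0
    dimer_flag_level: int = 10

    def __post_init__(self) -> None:
        if self.selfcomp_max <= 0:
            raise ValueError("selfcomp_max must be positive")
        if self.hairpin_dg_min > 0:
            raise ValueError("hairpin_dg_min must be <= 0")


def _check(seq: str) -> str:
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if set(s) - set("ACGT"):
        raise ValueError("sequence must be unambiguous A/C/G/T")
    return s


def cross_dimer_score(a: str, b: str) -> int:
    """Maximal Watson-Crick pairing count between two primers.

    Symmetric in its arguments; ``cross_dimer_score(s, s)`` is the
    self-complementarity score of ``s``.
    """
    sa = _check(a)
    sc = reverse_complement(_check(b))
    best = 0
    # Slide sc across sa through every overlapping offset.
    for shift in range(-(len(sc) - 1), len(sa)):
        count = 0
        for i in range(max(0, shift), min(len(sa), shift + len(sc))):
            if sa[i] == sc[i - shift]:
                count += 1
        if count > best:
            best = count
    return best


def self_complementarity(seq: str) -> int:
    """Self-dimer score: the diagonal of the cross-dimer score."""
    return cross_dimer_score(seq, seq)


def hairpin_dg(seq: str) -> float:
    """Most stable (most negative) stem-loop ΔG in kcal/mol, or 0.0.

    Enumerates every ungapped stem of >= 3 Watson-Crick pairs closing a
    loop of 3-12 unpaired bases.
    """
    s = _check(seq)
    n = len(s)
    best = 0.0
    for stem in range(_MIN_STEM, (n - _LOOP_RANGE[0]) // 2 + 1):
        for loop in range(_LOOP_RANGE[0], _LOOP_RANGE[1] + 1):
            span = 2 * stem + loop
            if span > n:
                break
            for i in range(n - span + 1):
                # 5' arm s[i : i+stem] pairs antiparallel with
                # 3' arm s[i+stem+loop : i+span].
                dg = _LOOP_PENALTY
                for t in range(stem):
                    left = s[i + stem - 1 - t]
                    if _COMP[left] != s[i + stem + loop + t]:
                        dg = None
                        break
                    dg += _PAIR_ENERGY[left]
                if dg is not None and dg < best:
                    best = dg
    return best


def repeat_filter(seq: str) -> tuple[bool, str]:
    """Low-complexity screen: (passed, reason).

    Fails on a run of >= 6 identical bases ("more than 5 mononucleotide
    repeats") or >= 5 tandem copies of a two-base motif with distinct
    bases ("more than 4 dinucleotide repeats").
    """
    s = _check(seq)
    run_base, run_len = s[0], 1
    for c in s[1:]:
        if c == run_base:
            run_len += 1
            if run_len >= 6:
                return False, f"mononucleotide run: {run_base}x{run_len}+"
        else:
            run_base, run_len = c, 1
    for i in range(len(s) - 1):
        motif = s[i : i + 2]
        if motif[0] == motif[1]:
            continue
        copies = 1
        j = i + 2
        while s[j : j + 2] == motif:
            copies += 1
            j += 2
        if copies >= 5:
            return False, f"dinucleotide run: {motif}x{copies}"
    return True, ""


def has_gc_clamp(seq: str) -> bool:
    """True iff the 3'-terminal base of the 5'->3' primer is G or C."""
    return _check(seq)[-1] in "GC"
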