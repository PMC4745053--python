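"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the definition of the quantity, with its own
complement table and loop structure, so it shares no code path with the
shipped implementations it checks.
"""

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def brute_cross_dimer(a: str, b: str) -> int:
    """Max Watson-Crick pairings when a and b anneal antiparallel.

    Slides the reversed copy of b along a and counts positions where
    a[i] is complementary to b[j], for every overlap.
    """
    rb = b[::-1]
    best = 0
    for offset in range(-(len(rb) - 1), len(a)):
        count = 0
        for i, c in enumerate(a):
            j = i - offset
            if 0 <= j < len(rb) and _COMP[c] == rb[j]:
                count += 1
        best = max(best, count)
    return best


def brute_self_comp(seq: str) -> int:
    return brute_cross_dimer(seq, seq)


def brute_hairpin(seq: str, stem_min: int = 3, loop_min: int = 3, loop_max: int = 12,
                  loop_penalty: float = 3.5) -> float:
    """Min additive stem-loop ΔG by direct enumeration of (i, j, stem)."""
    energy = {"A": -1.0, "T": -1.0, "G": -1.5, "C": -1.5}
    n = len(seq)
    best = 0.0
    # i = index of last 5'-arm base; j = index of first 3'-arm base.
    for i in range(n):
        for j in range(i + 1 + loop_min, min(n, i + 1 + loop_max + 1)):
            # Grow the stem outward from the loop-closing pair.
            dg = loop_penalty
            stem = 0
            while i - stem >= 0 and j + stem < n and \
                    _COMP[seq[i - stem]] == seq[j + stem]:
                dg += energy[seq[i - stem]]
                stem += 1
                if stem >= stem_min:
                    best = min(best, dg)
    return best


def brute_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_specificity(primer: str, sequences: list[str], max_mismatches: int) -> int:
    """Both-strand ungapped window scan, counting Hamming-close sites."""
    total = 0
    for query in (primer, brute_revcomp(primer)):
        for seq in sequences:
            for start in range(len(seq) - len(query) + 1):
                mismatches = sum(
                    1 for x, y in zip(query, seq[start : start + len(query)]) if x != y
                )
                if mismatches <= max_mismatches:
                    total += 1
    return total
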