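"""Seeded synthetic sequence fixtures.

Generates the two input kinds the toolkit consumes without touching any
remote database: plain random DNA FASTA records, and SNP flanking
records of the canonical dbSNP shape — an odd-length sequence with an
IUPAC ambiguity code at the exact center and a header carrying
``pos = <center>|len<length>``.  Per-record GC targets are drawn
uniformly from a realistic genomic band so downstream Tm/GC filters see
a natural spread.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .seqio import SequenceRecord, SnpRecord, write_fasta

#: Biallelic-and-up codes used at simulated SNP sites (two-allele codes
#: dominate real dbSNP; B/D/H/V are rare and omitted by default).
SNP_CODES = ("R", "Y", "M", "K", "W", "S")

_GC_BAND = (0.35, 0.65)


def _random_sequence(rng: np.random.Generator, length: int, gc_target: float) -> str:
    n_gc = int(round(gc_target * length))
    bases = np.where(rng.random(length) < 0.5, "A", "T").astype(object)
    gc_positions = rng.choice(length, size=n_gc, replace=False)
    strong = np.where(rng.random(n_gc) < 0.5, "G", "C")
    for pos, b in zip(gc_positions, strong):
        bases[pos] = b
    return "".join(bases)


def random_dna_records(n_records: int, length: int, seed: int | None = None) -> list[SequenceRecord]:
    """Random DNA records with per-record GC uniform on [0.35, 0.65]."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_records):
        gc = float(rng.uniform(*_GC_BAND))
        out.append(
            SequenceRecord(
                id=f"seq{i + 1:03d}",
                residues=_random_sequence(rng, length, gc),
                description=f"seq{i + 1:03d} simulated length={length}",
            )
        )
    return out


def random_snp_records(n_records: int, length: int, seed: int | None = None) -> list[SnpRecord]:
    """SNP flanking records with a centered ambiguity code.

    ``length`` must be odd and >= 101 so the SNP sits at the exact center
    with ample flank on both sides (the canonical shape is 1001 nt with
    the site at 501).
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if length < 101 or length % 2 == 0:
        raise ValueError("length must be odd and >= 101")
    rng = np.random.default_rng(seed)
    center = (length + 1) // 2
    out = []
    for i in range(n_records):
        gc = float(rng.uniform(*_GC_BAND))
        seq = list(_random_sequence(rng, length, gc))
        seq[center - 1] = str(rng.choice(SNP_CODES))
        rec = SequenceRecord(
            id=f"rs{i + 1:07d}",
            residues="".join(seq),
            description=f"rs{i + 1:07d} pos = {center}|len{length}",
        )
        out.append(SnpRecord(record=rec, snp_position=center, declared_length=length))
    return out


def simulate_fixtures(
    kind: str,
    n_records: int,
    length: int,
    seed: int,
    out_path: str | Path,
) -> Path:
    """Write a FASTA (kind="dna") or rs_fastA (kind="snp") fixture file."""
    out_path = Path(out_path)
    if kind == "dna":
        write_fasta(random_dna_records(n_records, length, seed), out_path)
    elif kind == "snp":
        write_fasta([s.record for s in random_snp_records(n_records, length, seed)], out_path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r} (expected 'dna' or 'snp')")
    return out_path
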