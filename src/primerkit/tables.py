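"""Tabular (TSV) writers for design output.

All writers use fixed column orders, tab separators, Unix newlines and
fixed-precision floats, so identical designs serialize byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .design import AlleleSpecificPrimer, DimerReport, PrimerCandidate

PRIMER_COLUMNS = [
    "source_id", "name", "orientation", "start", "length",
    "sequence", "tm", "gc_percent", "selfcomp", "hairpin_dg",
]

ALLELE_COLUMNS = PRIMER_COLUMNS + ["snp_id", "allele", "label"]


def primers_frame(primers: Iterable[PrimerCandidate]) -> pd.DataFrame:
    rows = [
        {
            "source_id": p.source_id,
            "name": p.name,
            "orientation": p.orientation,
            "start": p.start,
            "length": p.length,
            "sequence": p.sequence,
            "tm": round(p.tm, 2),
            "gc_percent": round(p.gc, 2),
            "selfcomp": p.selfcomp,
            "hairpin_dg": round(p.hairpin, 2),
        }
        for p in primers
    ]
    return pd.DataFrame(rows, columns=PRIMER_COLUMNS)


def allele_frame(primers: Iterable[AlleleSpecificPrimer]) -> pd.DataFrame:
    base = primers_frame([a.candidate for a in primers])
    extras = pd.DataFrame(
        [{"snp_id": a.snp_id, "allele": a.allele, "label": a.label} for a in primers],
        columns=["snp_id", "allele", "label"],
    )
    return pd.concat([base, extras], axis=1)


def dimer_frame(report: DimerReport) -> pd.DataFrame:
    return pd.DataFrame(report.pairs, columns=["name_a", "name_b", "cross_dimer_score"])


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.2f")


def read_primers_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"name": str})
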