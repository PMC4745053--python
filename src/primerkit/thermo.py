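"""Melting-temperature engines and base-composition calculations.

Three Tm engines are provided:

``basic``
    The classic length/GC formulas: the Wallace rule ``2(A+T) + 4(G+C)``
    for oligos shorter than 14 nt, and ``64.9 + 41(G+C - 16.4)/L``
    otherwise.  No salt dependence.

``breslauer``
    Nearest-neighbor thermodynamics with the Breslauer et al. (1986)
    dinucleotide ΔH/ΔS table, salt-corrected with the Schildkraut-Lifson
    additive term ``16.6·log10([Na+])``.  This is the package default: in
    cross-calculator comparisons its predictions track the widely deployed
    Breslauer-based calculators most tightly.

``santalucia``
    The SantaLucia (1998) unified nearest-neighbor table, salt-corrected
    with the Owczarzy et al. (2004) GC-dependent reciprocal-temperature
    form.

The duplex Tm in Kelvin is ``ΔH_total / (ΔS_total + R·ln(C_T/4))`` for a
non-self-complementary oligo at total strand concentration ``C_T``
(R = 1.987 cal/(mol·K)); self-complementary sequences use ``C_T/1`` plus
the symmetry entropy term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .seqio import reverse_complement

R_GAS = 1.987  # cal / (mol K)
_ZERO_C = 273.15

# ---------------------------------------------------------------------------
# Published nearest-neighbor parameter tables, keyed by the plus-strand
# dinucleotide (16 steps; complementary steps share published values).
# ΔH in kcal/mol, ΔS in cal/(mol K).
# ---------------------------------------------------------------------------

# Breslauer, Frank, Bloecker & Marky (1986) PNAS 83:3746-3750.
_BRESLAUER_CORE = {
    "AA": (-9.1, -24.0), "AT": (-8.6, -23.9), "TA": (-6.0, -16.9),
    "CA": (-5.8, -12.9), "GT": (-6.5, -17.3), "CT": (-7.8, -20.8),
    "GA": (-5.6, -13.5), "CG": (-11.9, -27.8), "GC": (-11.1, -26.7),
    "GG": (-11.0, -26.6),
}

# SantaLucia (1998) PNAS 95:1460-1465, unified parameters.
_SANTALUCIA_CORE = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

_STEP_COMPLEMENT = {"TT": "AA", "TG": "CA", "AC": "GT", "AG": "CT", "TC": "GA", "CC": "GG"}


def _full_table(core: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    full = dict(core)
    for step, canonical in _STEP_COMPLEMENT.items():
        full[step] = core[canonical]
    return full


@dataclass(frozen=True)
class NNParameterSet:
    """A published dinucleotide-stack ΔH/ΔS table plus initiation terms."""

    name: str
    delta_h: dict[str, float]   # kcal/mol per stack
    delta_s: dict[str, float]   # cal/(mol K) per stack
    # Breslauer-style initiation: one entropy penalty chosen by composition.
    init_one_gc: tuple[float, float] = (0.0, 0.0)
    init_all_at: tuple[float, float] = (0.0, 0.0)
    # SantaLucia-style initiation: per-terminal-base terms.
    init_terminal_at: tuple[float, float] = (0.0, 0.0)
    init_terminal_gc: tuple[float, float] = (0.0, 0.0)
    symmetry: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if set(self.delta_h) != set(self.delta_s) or len(self.delta_h) != 16:
            raise ValueError(f"{self.name}: parameter table must cover all 16 dinucleotide steps")
        if any(h > 0 for h in self.delta_h.values()):
            raise ValueError(f"{self.name}: Watson-Crick stack enthalpies must be <= 0")


def _make_parameter_set(name, core, **kw) -> NNParameterSet:
    table = _full_table(core)
    return NNParameterSet(
        name=name,
        delta_h={k: v[0] for k, v in table.items()},
        delta_s={k: v[1] for k, v in table.items()},
        **kw,
    )


BRESLAUER_1986 = _make_parameter_set(
    "breslauer1986",
    _BRESLAUER_CORE,
    init_one_gc=(0.0, -16.8),
    init_all_at=(0.0, -20.1),
    symmetry=(0.0, -1.3),
)

SANTALUCIA_1998 = _make_parameter_set(
    "santalucia1998",
    _SANTALUCIA_CORE,
    init_terminal_at=(2.3, 4.1),
    init_terminal_gc=(0.1, -2.8),
    symmetry=(0.0, -1.4),
)

PARAMETER_SETS = {"breslauer": BRESLAUER_1986, "santalucia": SANTALUCIA_1998}

ENGINES = ("basic", "breslauer", "santalucia")

# Representative monovalent-salt settings (M) for vendor buffer systems whose
# exact compositions are proprietary; used by the cross-engine comparison
# presets.  Under the Schildkraut correction the choice shifts every Tm by the
# same constant, so correlations are unaffected.
PHUSION_MONOVALENT = 0.2
Q5_MONOVALENT = 0.1


@dataclass(frozen=True)
class ThermoConditions:
    """Buffer/engine settings under which a Tm is computed.

    monovalent_salt : total monovalent cation concentration, molar.
    primer_concentration : total oligo strand concentration C_T, molar.
    engine : one of {"basic", "breslauer", "santalucia"}.
    """

    monovalent_salt: float = 0.05
    primer_concentration: float = 5e-8
    engine: str = "breslauer"

    def __post_init__(self) -> None:
        if not 0 < self.monovalent_salt <= 1.0:
            raise ValueError("monovalent_salt must lie in (0, 1] M")
        if self.primer_concentration <= 0:
            raise ValueError("primer_concentration must be positive")
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; choose from {ENGINES}")


DEFAULT_CONDITIONS = ThermoConditions()


def _check_plain(seq: str, min_len: int = 1) -> str:
    s = seq.upper()
    if len(s) < min_len:
        raise ValueError(f"sequence too short ({len(s)} < {min_len} nt)")
    if set(s) - set("ACGT"):
        raise ValueError("sequence must be unambiguous A/C/G/T")
    return s


def gc_percent(seq: str) -> float:
    """GC content as a percentage of sequence length."""
    s = _check_plain(seq)
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def tm_basic(seq: str, conditions: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Length/GC rule-of-thumb Tm (°C): Wallace rule below 14 nt."""
    s = _check_plain(seq, min_len=8)
    gc = s.count("G") + s.count("C")
    if len(s) < 14:
        return 2.0 * (len(s) - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(s)


def _nn_sums(s: str, params: NNParameterSet) -> tuple[float, float]:
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol K)
    for i in range(len(s) - 1):
        step = s[i : i + 2]
        dh += params.delta_h[step]
        ds += params.delta_s[step]
    # Initiation terms.
    if params.init_terminal_at != (0.0, 0.0) or params.init_terminal_gc != (0.0, 0.0):
        for terminal in (s[0], s[-1]):
            term = params.init_terminal_gc if terminal in "GC" else params.init_terminal_at
            dh += term[0]
            ds += term[1]
    else:
        term = params.init_all_at if set(s) <= {"A", "T"} else params.init_one_gc
        dh += term[0]
        ds += term[1]
    if s == reverse_complement(s):
        dh += params.symmetry[0]
        ds += params.symmetry[1]
    return dh, ds


def tm_nearest_neighbor(
    seq: str,
    conditions: ThermoConditions = DEFAULT_CONDITIONS,
    parameter_set: NNParameterSet | None = None,
) -> float:
    """Nearest-neighbor duplex Tm (°C), salt-corrected.

    The parameter set defaults to the table matching ``conditions.engine``
    (Breslauer for the default engine).  The salt correction is chosen by
    table: Schildkraut additive for Breslauer, Owczarzy reciprocal form
    for SantaLucia.
    """
    s = _check_plain(seq, min_len=8)
    if parameter_set is None:
        engine = conditions.engine if conditions.engine != "basic" else "breslauer"
        parameter_set = PARAMETER_SETS[engine]
    dh, ds = _nn_sums(s, parameter_set)
    ct = conditions.primer_concentration
    factor = 1.0 if s == reverse_complement(s) else 4.0
    tm_kelvin = (dh * 1000.0) / (ds + R_GAS * math.log(ct / factor))
    na = conditions.monovalent_salt
    if parameter_set.name.startswith("santalucia"):
        # Owczarzy et al. (2004): 1/Tm correction with the GC-fraction term.
        fgc = (s.count("G") + s.count("C")) / len(s)
        inv = 1.0 / tm_kelvin + (4.29 * fgc - 3.95) * 1e-5 * math.log(na) \
            + 9.40e-6 * math.log(na) ** 2
        tm_kelvin = 1.0 / inv
        return tm_kelvin - _ZERO_C
    # Schildkraut & Lifson (1965) additive correction, 1 M reference.
    return tm_kelvin - _ZERO_C + 16.6 * math.log10(na)


def tm(seq: str, conditions: ThermoConditions = DEFAULT_CONDITIONS) -> float:
    """Tm under the engine selected in ``conditions``."""
    if conditions.engine == "basic":
        return tm_basic(seq, conditions)
    return tm_nearest_neighbor(seq, conditions, PARAMETER_SETS[conditions.engine])


def random_primers(
    n: int,
    length_min: int = 18,
    length_max: int = 30,
    gc_low: float = 0.2,
    gc_high: float = 0.8,
    seed: int | None = None,
) -> list[str]:
    """Seeded random primer set with controlled GC spread.

    Each primer draws a uniform length on [length_min, length_max] and a
    per-primer GC target uniform on [gc_low, gc_high]; exactly
    ``round(target * length)`` positions (chosen uniformly) receive G or C,
    the rest A or T.  The per-primer GC target (rather than i.i.d. uniform
    bases) gives the wide Tm spread a cross-engine correlation study needs.
    """
    if not 8 <= length_min <= length_max:
        raise ValueError("need 8 <= length_min <= length_max")
    if not 0 <= gc_low <= gc_high <= 1:
        raise ValueError("need 0 <= gc_low <= gc_high <= 1")
    rng = np.random.default_rng(seed)
    primers: list[str] = []
    for _ in range(n):
        length = int(rng.integers(length_min, length_max + 1))
        target = float(rng.uniform(gc_low, gc_high))
        n_gc = int(round(target * length))
        bases = [rng.choice(("A", "T")) for _ in range(length)]
        for pos in rng.choice(length, size=n_gc, replace=False):
            bases[pos] = rng.choice(("G", "C"))
        primers.append("".join(bases))
    return primers


def compare_tm_engines(
    primers: Sequence[str],
    conditions_a: ThermoConditions,
    conditions_b: ThermoConditions,
) -> tuple[float, np.ndarray]:
    """Squared Pearson correlation between two engines over a primer set.

    Returns ``(r_squared, pairs)`` where ``pairs`` is an (n, 2) array of
    (Tm_a, Tm_b) values for plotting or reporting.  Degenerate inputs
    (fewer than 3 primers, or zero variance on either axis) are errors.
    """
    if len(primers) < 3:
        raise ValueError("need at least 3 primers to correlate")
    a = np.array([tm(p, conditions_a) for p in primers])
    b = np.array([tm(p, conditions_b) for p in primers])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate Tm variance: all values identical on one axis")
    r, _ = stats.pearsonr(a, b)
    return float(r * r), np.column_stack([a, b])


def comparison_presets() -> dict[str, ThermoConditions]:
    """Named comparator conditions for the cross-calculator Tm study."""
    return {
        "phusion_breslauer_schildkraut": ThermoConditions(
            monovalent_salt=PHUSION_MONOVALENT, engine="breslauer"
        ),
        "q5_santalucia_owczarzy": ThermoConditions(
            monovalent_salt=Q5_MONOVALENT, engine="santalucia"
        ),
        "calculator_default_breslauer": ThermoConditions(
            monovalent_salt=0.05, primer_concentration=5e-8, engine="breslauer"
        ),
    }


def with_engine(conditions: ThermoConditions, engine: str) -> ThermoConditions:
    """Copy of ``conditions`` with a different engine."""
    return replace(conditions, engine=engine)
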