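# primerkit

Batch PCR primer design for molecular biologists who need many
coordinated primers at once — primer walking, nested PCR, multiplex
pools, and SNP genotyping panels — rather than one optimal pair.
primerkit scans a user-defined 5′ window and 3′ window of every sequence
in a multi-record FASTA file, applies length, GC%, melting-temperature,
low-complexity and structural filters, optionally requires each primer
to be unique across the whole input (up to an allowed number of
mismatches), and renders the accepted pool as positional tables and SVG
primer maps. From dbSNP-style flanking records it additionally designs
SNP-bracketing pools and allele-specific genotyping primers.

## The models at the core

**Melting temperature.** The default engine is nearest-neighbor
thermodynamics with the Breslauer et al. (1986) dinucleotide ΔH/ΔS
table:

    Tm(K) = ΔH° / (ΔS° + R ln(C_T / 4))

summed over adjacent dinucleotide stacks plus initiation terms, with the
Schildkraut–Lifson monovalent-salt correction `+16.6 log₁₀[Na⁺]`.
Two alternates are provided: the SantaLucia (1998) unified table with
the Owczarzy (2004) GC-dependent reciprocal-temperature salt correction,
and the classic length/GC formulas (Wallace rule below 14 nt,
`64.9 + 41(G+C − 16.4)/L` otherwise). Defaults: 50 mM Na⁺, 50 nM total
primer.

**Structure scores.** Self- and cross-dimer scores are the maximum
number of Watson–Crick base pairs two strands can form in any ungapped
antiparallel alignment (a primer is accepted when its self score is
strictly below 10). Hairpins are scored by an additive stem–loop ΔG
(stems ≥ 3 pairs, loops 3–12 nt, A·T −1.0 and G·C −1.5 kcal/mol per
pair, +3.5 kcal/mol loop penalty) with a −6.0 kcal/mol acceptance floor.

**Allele-specific primers.** For each SNP allele, the primer whose
3′-terminal base sits exactly on the polymorphic site (the allele itself
for forward primers, its complement for reverse) is chosen at the length
whose Tm is closest to the middle of the allowed Tm range — extension by
the polymerase then succeeds only on the matching allele.

**Multiplex screening.** All n accepted primers are paired without
replacement — C(n, 2) = n(n−1)/2 combinations — and each pairing gets a
cross-dimer score.

## Worked example

```sh
python examples/04_tm_engines.py
```

```text
TCCCCGAAAATCTTCAGTG  GC% 47.37
  basic       Tm  48.93 C
  breslauer   Tm  53.57 C
  santalucia  Tm  48.56 C
default vs phusion_breslauer_schildkraut    r^2 = 1.0000
default vs q5_santalucia_owczarzy           r^2 = 0.9707
default vs calculator_default_breslauer     r^2 = 1.0000
```

The primer (a PCR-validated 19-mer, 9 G/C over 19 bases → GC% 47.37)
melts at 48.9 °C under the plain length/GC formula, 53.6 °C under the
default Breslauer nearest-neighbor engine and 48.6 °C under
SantaLucia/Owczarzy — typical spread between Tm conventions. The r²
lines are the cross-engine study over 100 seeded random 18–30-mers:
Breslauer-based comparators correlate perfectly with the default engine
(a Schildkraut salt change only shifts every Tm by a constant), while
the SantaLucia/Owczarzy comparator, built from different stack
parameters, correlates at 0.97.

```sh
python examples/02_snp_allele_specific.py
```

```text
rs0000001: code R at 501, alleles ('A', 'G')
flanking pool: 207 forward (3' ends <= 500), 334 reverse (starts >= 502)
  wildtype     allele A forward len 20  3'-base A  Tm 57.1
  wildtype     allele A reverse len 19  3'-base T  Tm 57.3
  polymorphic  allele G forward len 20  3'-base G  Tm 56.7
  polymorphic  allele G reverse len 18  3'-base C  Tm 55.0
```

Every flanking primer stops short of the SNP at position 501, so any
forward+reverse pair brackets it; the four allele-specific primers place
an A/G (forward) or T/C (reverse) exactly at their 3′ terminus.

The remaining examples cover batch design (`01`), the multiplex dimer
screen (`03`) and positional tables, SVG maps and coordinate-drawn
primers (`05`). The same operations are available from the shell via the
`primerkit` command (`design`, `snp`, `dimers`, `tm`, `tm-compare`,
`score`, `map`, `draw`, `simulate`; run `primerkit --help`).

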