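# Methods

## Scope of the design procedure

primerkit designs primer *pools*, not ranked pairs: every candidate that
clears the enabled constraints is returned, because the intended uses
(primer walking, nested PCR, multiplex panels, SNP genotyping) want a
dense menu of interchangeable primers with a map to choose from. An
optional per-record cap (`max_primers_per_record`) exists for very large
windows. Pair selection with product-size constraints is deliberately
out of scope.

Coordinates are 1-based and inclusive everywhere. A primer's name is the
1-based plus-strand coordinate of its 5′ terminus; a reverse primer's
plus-strand footprint is therefore `[start − length + 1, start]` and its
sequence is the reverse complement of that window.

## Candidate enumeration and filters

Forward candidates are every substring of length `len_min..len_max`
lying fully inside the first `window5` bases; reverse candidates mirror
this over the last `window3` bases (window coordinates counted from the
3′ end, symmetric with the 5′ description). Windows larger than the
sequence are clipped.

Filters run cheap-to-expensive: GC% → repeats → GC clamp → Tm →
self-complementarity → hairpin → specificity. The order affects only
which rejection reason is reported, never the accepted set. Survivors
are deduplicated by (sequence, orientation), keeping the smallest start,
and sorted by start. Defaults: length 18–27 nt, Tm 52–62 °C, GC 35–65 %,
windows 150 nt.

The repeat rule fails a candidate containing a run of ≥ 6 identical
bases (more than 5 mononucleotide repeats) or ≥ 5 tandem copies of a
two-base motif with distinct bases (more than 4 dinucleotide repeats);
homopolymer "dinucleotides" are governed by the first rule. The GC clamp
check looks at exactly one 3′-terminal base, evaluated on the primer's
own 5′→3′ sequence for both orientations.

Specificity counts every ungapped alignment position across all input
records and both strands with Hamming distance ≤ `max_mismatches`
(implemented as a vectorized sliding-window comparison). The count
includes the primer's own origin site, so "specific" means a count of
exactly 1 — the only self-consistent reading when the template set is
the universe searched.

## Melting temperature

Engines:

* `basic` — Wallace rule `2(A+T) + 4(G+C)` below 14 nt, otherwise
  `64.9 + 41(G+C − 16.4)/L`. No salt term.
* `breslauer` (default) — nearest-neighbor sum over the Breslauer 1986
  ΔH/ΔS table with the composition-dependent initiation entropy (−16.8
  cal/(mol·K) with any G/C, −20.1 all-A/T) and the symmetry term for
  self-complementary oligos; duplex Tm `ΔH/(ΔS + R ln(C_T/4))`;
  Schildkraut additive salt correction `16.6·log₁₀[Na⁺]` (1 M
  reference).
* `santalucia` — SantaLucia 1998 unified table with per-terminal-base
  initiation terms; Owczarzy 2004 correction in reciprocal-temperature
  form, `1/Tm' = 1/Tm + (4.29 f_GC − 3.95)·10⁻⁵ ln[Na⁺] +
  9.40·10⁻⁶ ln²[Na⁺]`.

Breslauer with Schildkraut was made the default because, in
cross-calculator comparisons, its predictions track the widely deployed
Breslauer-based calculators (Phusion-style and Primer3-style) most
tightly. Both parameter tables are embedded as frozen constants covering
all 16 dinucleotide steps (complementary steps share the published
values) and are cross-checked in the test suite against Biopython's
independent implementation to ≤ 10⁻⁶ °C.

Conditions default to 50 mM monovalent salt and 50 nM total primer —
common calculator defaults. The vendor-buffer comparison presets use
representative monovalent settings (Phusion-style 0.2 M, Q5-style
0.1 M); the exact buffer compositions are proprietary, and under the
Schildkraut correction the choice shifts every Tm by the same constant,
leaving correlations untouched, while under Owczarzy the dependence on
the choice is weak. Divalent (Mg²⁺) and dNTP corrections are out of
scope. Monovalent salt is validated to (0, 1 M], the range on which both
corrections are monotone increasing.

## Structure scores

The published tools this package descends from never define their
complementarity or hairpin algorithms (thresholds there were set by PCR
validation). primerkit therefore uses precise, testable stand-ins:

* **Dimer scores** — the maximum number of Watson–Crick pairings over
  all ungapped antiparallel offsets of one primer against another (self
  score = the diagonal case). Total pairings were chosen over
  longest-contiguous-run; the alternative is noted as a variant a future
  version could expose.
* **Hairpin ΔG** — minimum over all stem–loop foldings with stems ≥ 3
  pairs and loops 3–12 nt of `+3.5 + Σ pair energies` with A·T = −1.0
  and G·C = −1.5 kcal/mol; 0 if no negative folding exists. This is an
  additive toy energy model, not a partition-function fold; it ranks
  candidates consistently and cheaply but does not predict real folding
  free energies. Sequences shorter than 9 nt cannot fold (3+3+3).

Acceptance thresholds: self score < 10 (the one threshold the
descendant tools do print), hairpin floor −6.0 kcal/mol (documented
default), dimer pairs flagged at ≥ 10. Both scores are verified against
independent brute-force enumerations on hundreds of random sequences in
the test suite.

## SNP and allele-specific design

rs_fastA input: a FASTA whose header embeds `pos = <int>|len<int>`
(whitespace around `=` tolerated) and whose body carries an IUPAC
ambiguity code at the declared position. The id is the first
whitespace-delimited header token; the full header is preserved as the
description. Declared-length mismatches and a non-ambiguous base at the
SNP site are hard errors, as are residues outside the 15-letter IUPAC
alphabet anywhere (no silent stripping).

Flanking design restricts forward candidates to
`[pos − window5, pos − 1]` and reverse candidates to
`[pos + 1, pos + window3]`, so no candidate covers the ambiguity code
and every forward+reverse pair brackets the SNP.

Allele-specific design fixes the 3′ terminus on the SNP (allele base
forward, complement reverse), copies the rest of the primer from the
template, scans lengths `len_min..len_max`, and keeps the length whose
Tm is inside the allowed range and closest to the range midpoint
(ties → shorter). Only the Tm gate applies: structural scores and GC%
are computed and reported but do not reject, and the GC-clamp
requirement is never applied (the terminal base is dictated by the
allele). Labels: the alphabetically first allele is "wildtype", the
rest "polymorphic" — a naming convention only, since dbSNP flanking
records do not mark the ancestral allele.

## Maps and positional output

Positional records (source, name, start, end, strand, sequence) are the
lossless exchange format; the TSV writer/reader round-trips
byte-identically, and a JSON-lines export serves external viewers. SVG
is the canonical graphic: it scales losslessly and its elements can be
asserted in tests. Each map has one scaled base-pair ruler, one arrowed
glyph per primer pointing in the direction of synthesis (blue by
default), an optional green SNP marker, and the FASTA header as title.
Overlapping glyphs stack into lanes greedily (first free lane) — a
presentation choice, not a semantic one. The concatenated view lays
records end-to-end in input order with zero gap; record boundaries are
drawn as ticks, not coordinate offsets, so a primer at local start s in
record i sits at global coordinate `Σ len(records < i) + s`. Rendering
is a pure function of its inputs: identical inputs give byte-identical
SVG.

`primer_from_coordinates` reproduces the draw-a-primer interaction:
left-to-right returns the forward substring, right-to-left its reverse
complement, with GC% and Tm of the returned strand; spans under 8 nt
are rejected because no Tm is defined there.

## Synthetic data

The fixture generator stands in for remote GenBank/dbSNP retrieval so
every test and example is download-free. DNA records draw a per-record
GC target uniform on [0.35, 0.65] — a realistic genomic band — with
bases otherwise placed uniformly; SNP records are odd-length (default
1001 nt) with a two-allele ambiguity code (R/Y/M/K/W/S) at the exact
center and a conformant `pos = <center>|len<length>` header. The random
primer generator used by the Tm study draws a per-primer GC target
uniform on [0.2, 0.8] rather than i.i.d. bases, giving the wide Tm
spread a correlation study needs. Everything is reproducible from a
single integer seed.

What the generator does **not** emulate: repeat-rich and biased genomic
composition, homologous record sets (so default specificity tests see
mostly unique primers), heterozygous indels, and real dbSNP header
variants beyond the canonical pattern. Passing tests therefore
demonstrate correctness of the algorithms under controlled conditions,
not performance on any particular genome.

## Numerical and testing choices

Problem sizes in the test suite (10 records × 1 kb for the closed-loop
and specificity studies, 100 primers for the Tm study, pools up to
n = 100 for the dimer combinatorics) were chosen to exercise every code
path at realistic scale while keeping the full suite fast. Floating
output is serialized at fixed precision (2 decimals) so repeated runs
are byte-identical. Structural scores, the specificity count and every
accepted primer's constraints are verified against independently coded
brute-force oracles; Tm engines are verified against Biopython's
nearest-neighbor implementation with matched concentration conventions
(its `dnac1 − dnac2/2` duplex term equals `C_T/4` when
`dnac1 = dnac2 = C_T/2`).

## Known limitations

* The hairpin and dimer models are alignment-counting heuristics, not
  thermodynamic folding.
* No Mg²⁺/dNTP salt corrections; no mismatch or dangling-end
  nearest-neighbor terms.
* Specificity search is ungapped (no indel tolerance) and in-memory;
  whole-genome background screening should use a dedicated aligner or
  BLAST (the `blast` subcommand exports query FASTA for exactly that).
* Remote database retrieval is intentionally absent; all input is local.
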