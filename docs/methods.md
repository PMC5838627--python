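# Methods

## Thermodynamic model

Probe–target duplex formation is scored with the nearest-neighbor (NN)
model: ΔH° and ΔS° are sums of dinucleotide stack contributions plus two
per-terminus initiation terms. Watson–Crick stacks use the unified
parameter set (SantaLucia 1998); single internal mismatches use the
published mismatch stack tables (Allawi & SantaLucia 1997–1998 for G·T,
A·C, C·T and G·A; Peyret et al. 1999 for A·A, C·C, G·G and T·T). The
values ship as plain-text TSV package data
(`src/fretprobe/data/nn_*.tsv`, schema: stack, dH kcal/mol, dS
cal/(mol·K)); the loader resolves a stack either directly or through its
reverse-complement-equivalent key, and raises a typed coverage error
naming any missing stack. Sums use `math.fsum`, which makes ΔH/ΔS
independent of stack order and hence exactly symmetric under swapping the
probe and target roles.

Supported regime: perfect duplexes and duplexes with exactly one internal
mismatch. Terminal mismatches and multiple mismatches are rejected with a
typed error rather than mis-scored — the published mismatch parameters are
calibrated for internal contexts, and a terminal mismatch would need
separate terminal-mismatch tables.

### Melting temperature

Two-state Tm at the 1 M Na⁺ reference:

    Tm(1M) = ΔH°·1000 / (ΔS° + R ln(C_T/f)) − 273.15,  R = 1.987 cal/(mol·K)

with f = 4 for non-self-complementary duplexes (f = 1 self-complementary).
Probe–amplicon hybridization is treated as non-self-complementary equimolar
strands at the assay's total strand concentration C_T = 20 µM, i.e. an
effective concentration C_T/4 = 5 µM.

Salt correction uses the Owczarzy et al. (2004) reciprocal-temperature
monovalent formula,

    1/Tm[Na] = 1/Tm[1M] + (4.29·f_GC − 3.95)·10⁻⁵ ln[Na] + 9.40·10⁻⁶ ln²[Na],

which returns the input unchanged at 1 M and is monotone in [Na⁺] over the
assay-relevant range. Divalent cations are folded in through the von Ahsen
(2001) sodium-equivalent transform Na_eq = [mono] + 120·√[Mg²⁺] (mM); the
assay buffer (50 mM Na⁺, 2 mM Mg²⁺) is therefore treated as ≈220 mM
monovalent equivalent. The duplex GC fraction entering the correction is
the probe-strand GC fraction. A full empirical Mg²⁺ correction (Owczarzy
2008) would differ by well under a degree at this ratio of
√[Mg²⁺]/[mono] and was not worth the extra parameterization here.

Dye steric effects on Tm are representable as an optional constant offset
(`steric_tm_offset_c`, default 0): no reliable magnitude is available, so
the default model ignores them.

## Melting curves and the heterozygote readout

The fluorescence readout is modeled as proportional to sensor-probe site
occupancy on the target. With the probe in excess the occupancy isotherm is

    θ(T) = K(T)·c / (1 + K(T)·c),  c = C_T/4,

where K is the van't Hoff association constant. Using c = C_T/4 makes this
curve exactly consistent with the Tm convention above: θ passes through 1/2
at Tm and the derivative peak −dθ/dT sits on Tm to machine precision. The
entropy is re-anchored so the transition is centered on the salt-corrected
Tm while keeping ΔH° from the NN sum — ΔH° alone sets the transition
width (FWHM ≈ 3.5·R·Tm²/|ΔH°|, about 6–8 °C for 16-mer probes).

The alternative curve shape — both strands dilute and equimolar, solved
from the binding quadratic — was evaluated and rejected for the readout: its
derivative maximum sits systematically above the two-state Tm (≈0.9 °C, or
nine grid steps, for the fixture probe), breaking the peak-position
diagnostic, and its long low-temperature tail merges heterozygote peaks
even at 9 °C separation. The occupancy isotherm has neither defect and
corresponds to the actual assay situation where amplicon and probe
concentrations are not matched.

Heterozygotes are modeled as a 50:50 pointwise mixture of the matched and
mismatched duplex curves (diploid assumption; weights configurable).
Peaks are local maxima of −dθ/dT with a minimum prominence of 10 % of the
curve's global derivative maximum (scipy `find_peaks`); the default grid is
50–100 °C at 0.1 °C.

Whether two transitions resolve into two peaks depends on their enthalpies,
not only their separation: the package exposes
`melt.peak_resolution_limit()`, which bisects for the model's own merge
threshold for a given (ΔH_ref, ΔH_alt, Tm) triple. For the fixture's sensor
(ΔH ≈ −121 / −93 kcal/mol) the limit is ≈8.1 °C, safely below the
fixture's 9.5 °C allele separation; genotype round-trip properties in the
test suite condition on this limit plus two grid steps. Sharp transitions
(|ΔH| ≳ 200 kcal/mol, amplicon-scale) resolve separations down to ≈4 °C.

Genotype calls match peak positions to the expected per-allele Tms within a
tolerance of 1.5 °C by default — covering the ~0.5 °C
theoretical-versus-measured Tm deviation reported for this probe chemistry
plus grid and composite-shift effects. One peak near exactly one expected
Tm gives the homozygous call, two peaks (one near each) the heterozygous
call; everything else is an explicit `no_call` with a reason.

## Probe-pair design

The acceptor (sensor) length scan fixes one footprint edge and extends the
probe away from it, computing matched and mismatched Tm per length; every
candidate must cover the SNP strictly in its interior. Selection takes the
row with maximal ΔTm subject to ΔTm ≥ 5 °C (the discrimination floor) and a
working matched-Tm window of 45–70 °C, breaking ties toward shorter length
and lower Tm. The end-to-end designer tries both probe orientations and
both anchored sides, placing the fixed end so the SNP is central at the
minimum scanned length; among surviving candidates it prefers
hairpin-unflagged designs, then maximal ΔTm. ΔTm generally *decreases* with
sensor length (the single mismatch is diluted in a longer duplex), so the
floor and window, not the scan maximum, determine the practical optimum.

The donor (anchor) probe is placed on the side where its 3' dye faces the
acceptor's 5' dye, with the smallest workable gap in 1–5 nt and the
shortest length whose Tm exceeds the acceptor's matched Tm by ≥2 °C — the
sensor must melt first so its transition dominates the observed peak. The
SNP may not fall under the donor footprint.

The hairpin screen enumerates all stem-loop candidates with stems of ≥3
Watson–Crick pairs closing loops of 3–8 nt, scoring stems by NN stacks plus
a fixed +3.5 kcal/mol loop penalty, and flags the region when the best
candidate's ΔG37 falls below −3 kcal/mol. This is a deliberate
simplification of a full secondary-structure fold (no bulges, internal
loops, multiloops, or loop-size-dependent penalties): it is a screen for
obviously competing structure, not a structure predictor.

## Nested primers

Inner primers flank the probe footprint by ≥3 nt, outer primers sit
strictly outside the inner footprints. Each of the four slots takes the
best-scoring candidate among 3'-end positions within a 40 nt outward window
and lengths 18–24 nt. The score is |Tm − 60| + 25·|GC − 0.5| plus
2 kcal⁻¹-weighted penalties for self-dimers stronger than −6 kcal/mol and
hairpins stronger than −3 kcal/mol; deviations are penalties rather than
hard filters, so a best-scoring set exists whenever the geometry fits, and
ties resolve deterministically to the innermost, shortest candidate.
Self-dimers are scored by sliding the oligo against itself antiparallel and
stack-scoring the best contiguous complementary run; 3' stability is the
summed ΔG37 of the five terminal stacks. An independent validator re-checks
footprint identity on the correct strand, strict nesting, probe-footprint
coverage and binding-site uniqueness from the sequence alone.

A published-set convention worth stating prominently: a primer's recorded
position is the 5'-most reference-strand footprint coordinate for forward
oligos and the *rightmost* footprint base for reverse oligos. Under this
reading the published quartet yields well-nested 140 bp and 85 bp
amplicons on the fixture.

## The synthetic locus

`fixtures.build_fixture(allele, seed)` reconstructs a 480 bp fragment with
the six published oligos pinned at their published coordinates
(offset = genomic position − 270120). Filler bases are drawn uniformly
(realized fragment GC is constrained to 40–60 %) from a seeded generator
and redrawn until no oligo has a second exact binding site on either allele
variant, keeping uniqueness validation meaningful. The same seed gives the
same filler for both alleles, so the G and A fragments differ at exactly
one position.

Two modeling choices here are assumptions, not published facts:

- **Probe orientation.** Both probes are taken as plus-strand-matching
  (hybridizing to the complementary strand). This is the only orientation
  that brings the printed dye ends (donor 3', acceptor 5') within gap+1 nt
  of each other at the published coordinates; the opposite orientation
  would separate them by >30 nt. Consequently the G/A alleles read C/T on
  the fixture reference strand, and the alleles are named on the probe
  target strand.
- **SNP placement.** The variant is placed under acceptor probe index 10
  (fragment offset 231) — the most central acceptor base capable of
  Watson–Crick-pairing a G — so the G allele is the perfect match and the A
  allele produces an internal C·A mismatch. The true offset within the
  probe is not published; other C positions (index 15/16) would put the
  mismatch at or next to the terminus, outside the supported NN regime.

What the fixture does *not* emulate: real genomic flanking sequence (filler
is random), amplification kinetics, fluorescence baselines/crosstalk, and
salt-condition drift. Passing tests therefore demonstrate the design and
readout logic under the stated thermodynamic model, not concordance with a
particular instrument's raw fluorescence.

## Numerical choices

- Temperatures are °C at every API boundary, Kelvin internally;
  R = 1.987 cal/(mol·K); ΔG37 uses T = 310.15 K.
- Default grid 50–100 °C at 0.1 °C (501 points); peak positions are
  reported on the grid, so Tm agreement diagnostics are bounded by one
  grid step.
- Composite-curve grids must agree within 10⁻¹²; weights must be
  non-negative and sum to 1 within 10⁻⁹.
- Tie-breaks: acceptor selection (ΔTm, then shorter, then cooler), donor
  placement (smaller gap, then shorter), primer slots (innermost 3' end,
  then shorter) — all deterministic.
- Degenerate inputs are typed errors (empty ranges, terminal mismatches,
  non-ACGT characters, no-transition thermodynamics) except where the spec
  of the operation is an explicit outcome: acceptor selection returns an
  explicit no-candidate, the designers return outcome objects carrying
  per-stage diagnostics, and genotype calling returns `no_call` with a
  reason.

## Known limitations

- The two-state NN engine is not an ensemble partition-function model;
  predicted Tms can differ from ensemble web servers by a few degrees, and
  the fixture's allele ΔTm (≈9.5 °C) should be read as "well above the
  5 °C discrimination floor", not as an instrument-calibrated value.
- Only single internal mismatches are supported; indels, adjacent SNPs and
  terminal variants are out of regime.
- The hairpin screen and self-dimer scorer are contiguous-run
  approximations; no bulged or interior-loop structures.
- Primer design optimizes slots independently (no pair Tm-balance term) and
  checks specificity only within the supplied locus, not genome-wide.
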