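# Methods

## Scope and shape

`citrosat` implements a complete microsatellite marker-development workflow —
mining, classification, primer design, electronic PCR (ePCR) screening, marker
statistics, distance-based diversity analysis and physical mapping — organized
as a library (`src/citrosat/`) driven by numbered analysis scripts and a thin
CLI. Because the real inputs of such studies are multi-hundred-Mb genome
assemblies, the package ships a first-class synthetic-genome simulator whose
planted tracts give every downstream stage an exact expected answer; all
quantitative claims in the test suite and the acceptance script are measured
against that ground truth or against closed-form arithmetic.

## SSR mining

**Perfect tracts.** For each motif length k = 1..6 the scanner finds maximal
period-k runs (`seq[j] == seq[j-k]`), reports a run under its length-k motif
only when that motif is primitive (not an integer power of a shorter unit, so
ATATAT is a dinucleotide, never a hexanucleotide), and truncates the tract to
whole motif copies — a partial trailing copy is excluded, making
`tract_length = len(motif) * repeats` exact and the class boundaries
unambiguous. Minimum repeat counts default to mono 12, di 7, tri 5,
tetra/penta/hexa 4. Any non-ACGT base other than N is an error; N never
matches anything, so tracts cannot span ambiguity runs. Coordinates are
1-based inclusive at every interface (GFF3 convention); BED export converts to
0-based half-open. Equivalence with an exhaustive per-start-position scanner
is asserted on seeded random sequences.

**Classes.** Di- to hexanucleotide tracts: class III for t < 20 nt, class II
for 20 <= t <= 30, class I for t > 30 (hypervariable), extremely variable for
t >= 40. The t < 20 reading of the class III boundary makes the three classes
tile the length axis without overlap. Mononucleotide runs are deliberately
left unclassified, matching the practice of excluding them from marker
classification.

**Compound SSRs.** Maximal chains of >= 2 perfect tracts on one chromosome
with inter-tract gaps <= 100 bp (configurable) merge into a compound record
that retains its members; perfect and compound totals are counted
independently, and compound spans are not themselves classed.

**Imperfect SSRs.** There is no community-standard definition; this package
uses a documented seed-and-extend approximation: perfect seeds of >= 3 motif
copies are extended in motif phase in both directions, accepting a mismatching
position while the cumulative mismatch fraction over the extended tract stays
<= 0.1; tracts are trimmed to end on matching positions, filtered at
>= 12 nt, and overlapping same-canonical-motif calls are merged (longest
representative). Perfect tracts are recovered with zero mismatches. Counts
from this scanner are *not* comparable to any particular external tool's
imperfect totals; its guarantees are the property-based ones in the tests.

**Summaries.** Relative abundance = loci per Mb of examined sequence;
relative density = summed tract bp per Mb; percentages and average lengths are
plain ratios. These definitions reproduce the internally consistent entries of
published survey tables (the definitions-from-counts route), not any value
that conflicts with its own printed numerator and denominator.

## Synthetic genomes

Background sequence is i.i.d. with a configurable GC fraction (default 0.42,
a plant-genome-like value). Planted tracts are specified by motif, repeat
count, chromosome and 1-based position, with optional within-tract
substitutions (imperfect plants). Two guarantees make the truth table exact
rather than probabilistic:

1. **Boundary phase-breaking** — the base on each side of a planted tract is
   forced to differ from the phase-continuation base, so the planted tract is
   maximal and is recovered at its exact coordinates.
2. **Rejection filtering** — the generated genome is scanned with the miner
   and the background under any unplanned detectable tract is resampled until
   the miner's catalogue equals the planted perfect set (chance perfect runs
   fully inside a planted imperfect tract are tolerated, since they are part
   of the planted signal).

Related genomes insert or delete whole motif copies at the 3' end of selected
tracts (so the expected amplicon size changes by `len(motif) * delta` exactly)
and apply background substitutions at a configurable rate only outside the
tracts and their 400-bp protective flanks — 400 bp covers the maximum designed
product, so primer landing sites survive mutation by construction. A single
integer seed drives all randomness through deterministically derived
sub-seeds; identical seeds give byte-identical FASTA.

What the simulator does *not* emulate: realistic repeat landscapes,
transposable elements, indel background variation, assembly gaps and
sequencing error. Passing tests therefore demonstrate algorithmic correctness
against the stated definitions, not robustness to the full messiness of real
assemblies.

## Primer design

Candidates are enumerated exhaustively over all flank windows of length
18-20 nt within 400 bp of the tract, filtered by GC 40-70%, Tm 52-60 °C and
product size 100-400 bp (5' end of the forward primer to 5' end of the
reverse primer, inclusive; the amplicon always contains the whole tract), and
ranked by

    penalty = |Tm_f − 55| + |Tm_r − 55| + |len_f − 19| + |len_r − 19|
              + |product − 250| / 100

with ties broken by leftmost forward start, then lexicographic forward
sequence — deterministic output. The 250-bp optimum is the midpoint of the
product window. Two secondary screens reject fragile pairs: a primer
containing a >= 8 bp perfect self-complementary stretch, and a primer whose
sequence (either strand) occurs more than once within its own amplicon
region. Infeasible loci return an empty list, not an error.

Tm defaults to the unified nearest-neighbor thermodynamic estimate
(Biopython's `Tm_NN`, 50 mM monovalent salt, 250 nM primer); the Wallace rule
(2·(A+T) + 4·(G+C)) is available where exact integer arithmetic is convenient.
The accepted 52-60 °C range is a design constraint; the computation method
behind it is this package's choice, since marker studies typically delegate it
to a primer-design program.

## Electronic PCR

Primer sites are located through a contiguous-word index (word size 12,
forward strand; reverse-strand queries via reverse complement) and verified
by full-length exact comparison — no mismatches, no gaps. Both template
orientations are searched. Amplicon coordinates run 5' end to 5' end,
1-based inclusive, and this span is the allele size used everywhere
downstream. Amplicons outside 100-1000 bp are discarded; when a pair carries
its designed product size, a deviation cap of 3000 bp (`margin`) also
applies — with the 100-1000 window it is normally inert, which is the
documented reading of that screening parameter.

Cross-genome screening scores, per primer pair: amplicon-count class
(0 / 1 / 2 / >= 3) per genome; *single-locus* = exactly one amplicon in the
reference; *transferable* = amplified in at least one non-reference genome
(`transferable_genomes` counts all amplified genomes); *polymorphic* = at
least two distinct sizes among at least two amplified genomes — requiring two
genomes keeps the flag a cross-genome size polymorphism rather than a
within-genome duplication artifact. For statistics, each genome contributes
one diploid observation per locus: homozygous for the single amplicon size,
heterozygous for exactly two products, missing otherwise. This
homozygous-haploid-as-diploid convention follows how genome panels are
typically fed to population-genetics software and implies Ho = 0 at
single-copy loci.

## Marker statistics

With pᵢ the allele frequencies over the 2N observations of N scored diploids:
Na (allele count), MAF (max pᵢ), Ne = 1/Σpᵢ², I = −Σpᵢ ln pᵢ (natural log),
Ho = heterozygotes/N, He = 1 − Σpᵢ², uHe = (2N/(2N−1))·He, and
PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (the Botstein formula — stated prominently
because published PIC columns are often not reproducible from their own
frequency summaries). Missing genotypes are dropped per locus (pairwise
deletion), so N varies by locus; a monomorphic locus scores Na = 1, MAF = 1,
Ne = 1, I = Ho = He = PIC = 0. Grouped summaries are arithmetic means over
loci, with TP (loci) and TPP (loci with Na >= 2). Binary (dominant,
band-presence) data are scored per band as a biallelic locus with the null
frequency q = sqrt(absence-phenotype frequency); Ho is undefined (NaN) in
binary mode.

## Diversity

The default codominant metric is shared-allele dissimilarity
(1 − mean shared-allele proportion over comparable loci; a locus contributes
`Σ min(count_x, count_y)/2`); binary data use simple matching (default) or
Jaccard. A pair of samples with no comparable loci is an error naming the
pair. NJ follows Saitou–Nei with the standard Q criterion; a negative branch
length is clamped to zero with the deficit transferred to its sister branch,
and the final three nodes are resolved by the three-point formulas (so
additive matrices are recovered exactly, asserted to 1e-9 on path lengths).
UPGMA is arithmetic-average linkage; its output is ultrametric by
construction. All agglomeration ties break on the lexicographically smallest
leaf label, making tree output invariant to input sample order. PCoA is
classical scaling (double-center −D²/2, symmetric eigendecomposition,
coordinates scaled by sqrt of positive eigenvalues); negative eigenvalues are
reported but excluded from the percent-variance denominator. scikit-bio's NJ
and PCoA serve as independent cross-checks in the test suite, never as the
implementation.

## Physical maps

Markers are ordered by position per chromosome; the map reports markers/Mb,
inter-marker gaps (max and mean) and tract-length bins with inclusive lower
edges: 40-49, 50-59, 60-69 and >= 70 nt (the >= 70 reading makes the bins
tile above the 60-69 bin), plus a leading < 40 bin so counts always sum to
the marker count. Exports: MapChart-style TSV, GFF3/BED, Circos-format
karyotype and tile-track text, and an optional matplotlib strip plot. Summary
floats are fixed at 2 decimals with fixed column order, so identical inputs
re-export byte-identically.

## Problem sizes and numerical choices

The bundled study runs on two 56-kb chromosomes with 20 planted tracts and a
seven-genome panel (reference + six relatives), chosen so the whole chain —
including the exhaustive brute-force cross-checks — completes in seconds while
exercising every class boundary, both strands and all seven pipeline stages.
Closed-form identities are asserted to 1e-12, tree path lengths to 1e-9
(newick branch lengths are emitted at 17 significant digits for this reason),
and estimator-recovery checks use n = 5000 diploids with a 0.02 absolute
tolerance, the scale at which binomial sampling error comfortably clears that
bound. Frequency-vector validation uses a 1e-9 sum tolerance.

## Known limitations

- Imperfect-SSR counts are approximation-specific and not comparable across
  tools.
- ePCR is exact-match only; a mismatch-tolerant mode is intentionally out of
  scope of the validated surface.
- Primer screening uses a longest-self-complement heuristic, not
  thermodynamic dimer/hairpin free energies; multiplex compatibility is not
  evaluated.
- Population-structure modeling (Bayesian admixture), bootstrap support
  values, F-statistics and Hardy–Weinberg testing are out of scope.
- The simulator's background model is i.i.d.; conclusions about real-genome
  repeat landscapes require real assemblies.
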