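# citrosat

Genome-wide microsatellite (SSR) marker development as a tested, reusable
pipeline: mine perfect / compound / imperfect simple sequence repeats from
genome FASTA, classify tracts by length, design flanking primers for the
hypervariable subset, validate the primers by exact-match electronic PCR
(ePCR) across a panel of related genomes, score transferability and size
polymorphism, compute allele-frequency diversity statistics, and build
distance-based clusterings and chromosome physical maps.

The workflow mirrors marker-development studies in perennial crops (the
motivating case is citrus, where chromosome-specific highly variable SSRs —
HvSSRs, tract length >= 40 nt — are screened across species panels), but every
stage runs end-to-end on synthetic genomes with planted ground truth, so each
output has an exact expected value.

## The model

An SSR is a tandem repetition of a 1-6 nt DNA motif. A *perfect* tract is a
maximal uninterrupted run meeting per-motif-size minimum repeat counts
(mono 12, di 7, tri 5, tetra/penta/hexa 4); two tracts separated by <= 100 bp
form a *compound* SSR; *imperfect* tracts are found by seed-and-extend with a
bounded mismatch fraction. Motifs are reported under their canonical family
(lexicographic minimum over cyclic rotations and the reverse complement, so
TA, AT -> AT). Di- to hexanucleotide tracts are classed by length *t*:
class III (*t* < 20 nt), class II (20 <= *t* <= 30), class I (*t* > 30,
hypervariable), with *t* >= 40 flagged extremely variable.

Primer pairs (18-20 nt, GC 40-70%, Tm 52-60 °C, product 100-400 bp spanning
the full tract) are enumerated exhaustively over the flanks and ranked by a
penalty against the optima (19 nt, 55 °C, 250 bp). ePCR reports an amplicon
wherever both primers match exactly (no mismatches, no gaps, both
orientations), with the 5'-to-5' span in 100-1000 bp defining the allele size.

Per locus, with pᵢ the frequency of the i-th allele over N diploid
individuals: Ne = 1/Σpᵢ², I = −Σpᵢ ln pᵢ, Ho = hets/N, He = 1 − Σpᵢ²,
uHe = (2N/(2N−1))·He, and PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ² (Botstein).
Relatedness uses shared-allele dissimilarity with Saitou–Nei neighbor joining,
UPGMA, and classical-scaling PCoA.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
genomes (two 56-kb chromosomes, 20 planted tracts, six related genomes with
known repeat-count changes at the 16 extremely variable loci):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_mine.py
python analysis/03_design_primers.py
python analysis/04_epcr.py
```

which prints

```
planted 20 tracts (16 extremely variable) on 2 chromosomes; wrote reference + 6 related genomes ...
found 20 perfect (16 class I, 16 extremely variable), 0 compound, 27 imperfect SSRs
planted perfect loci recovered: 20/20 (unplanned: 0)
designed 16 primer pairs for 16 extremely variable loci (100.0% success)
screened 16 primer pairs across 7 genomes:
  single amplicon in reference: 16/16 (100.00%)
  size-polymorphic across panel: 16/16 (100.00%)
```

— the miner returns exactly the planted catalogue (the simulator
rejection-filters chance repeats, so the truth table is exhaustive), every
extremely variable locus gets a conforming primer pair, and the ePCR screen
recovers each planted repeat-count change as a distinct amplicon size.
`05_marker_stats.py`, `06_diversity.py` and `07_physical_map.py` continue with
the diversity statistics (e.g. mean Na 4.81, mean He 0.75, mean PIC 0.71 over
the panel), NJ/UPGMA trees plus PCoA, and the chromosome physical map with
tract-length bins.

The same stages are scriptable via the `citrosat` CLI
(`simulate`, `mine`, `design`, `epcr`, `stats`, `diversity`, `map`).

## Layout

- `src/citrosat/` — the library: `simulate` (planted-truth genomes), `mining`,
  `primers`, `epcr`, `stats`, `diversity`, `physmap`, `io`, `cli`
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — pytest suite with independent brute-force oracles
- `docs/methods.md` — models, conventions, parameter choices and limitations
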