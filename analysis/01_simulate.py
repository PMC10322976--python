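#!/usr/bin/env python
"""Simulate the study genomes: a reference with planted SSR tracts plus six
related genomes carrying known repeat-count changes at the extremely variable
loci. Writes FASTA files and the ground-truth table under results/genomes/."""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import GC_BACKGROUND, CHROM_LENGTHS, N_RELATED, RESULTS, SNP_RATE, plant_specs

from citrosat.simulate import generate_genome, mutate_related_genomes, write_truth_table


def main(seed: int) -> None:
    outdir = RESULTS / "genomes"
    outdir.mkdir(parents=True, exist_ok=True)

    genome, truth = generate_genome(
        CHROM_LENGTHS, plant_specs(seed), gc_background=GC_BACKGROUND,
        seed=seed % 2**31, genome_id="ref",
    )
    rng = np.random.default_rng((seed + 1) % 2**31)
    hv = [t for t in truth if t.tract_length >= 40 and len(t.motif) > 1]
    deltas = {t.locus_id: [int(d) for d in rng.integers(-4, 5, size=N_RELATED)]
              for t in hv}
    related, truth = mutate_related_genomes(
        genome, truth, deltas, snp_rate_outside_flanks=SNP_RATE, seed=seed % 2**31
    )

    genome.to_fasta(outdir / "ref.fasta")
    for g in related:
        g.to_fasta(outdir / f"{g.genome_id}.fasta")
    write_truth_table(truth, outdir / "truth.tsv")
    print(f"planted {len(truth)} tracts ({len(hv)} extremely variable) on "
          f"{len(CHROM_LENGTHS)} chromosomes; wrote reference + {len(related)} "
          f"related genomes to {outdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
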