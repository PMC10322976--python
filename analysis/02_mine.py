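#!/usr/bin/env python
"""Mine the reference genome for perfect, compound and imperfect SSRs,
classify tracts, and check the catalogue against the planted truth table.
Writes GFF3/BED/summary tables under results/mining/."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS

from citrosat import Genome
from citrosat.io import export_reports
from citrosat.mining import find_compound_ssrs, find_imperfect_ssrs, find_perfect_ssrs, summarize


def main() -> None:
    genomes = RESULTS / "genomes"
    outdir = RESULTS / "mining"
    genome = Genome.from_fasta(genomes / "ref.fasta", genome_id="ref")
    truth = pd.read_csv(genomes / "truth.tsv", sep="\t")

    perfect = find_perfect_ssrs(genome)
    compounds = find_compound_ssrs(perfect)
    imperfect = find_imperfect_ssrs(genome)
    summary = summarize(perfect, genome)
    export_reports(outdir, loci=perfect, genome=genome, summary=summary)

    planted = {(r.chrom, r.start, r.end, r.motif)
               for r in truth[truth.ssr_type == "perfect"].itertuples()}
    found = {(l.chrom, l.start, l.end, l.motif) for l in perfect}
    n_class1 = sum(l.ssr_class == "I" for l in perfect)
    n_hv = sum(l.extremely_variable for l in perfect)
    print(f"found {len(perfect)} perfect ({n_class1} class I, {n_hv} extremely "
          f"variable), {len(compounds)} compound, {len(imperfect)} imperfect SSRs")
    print(f"abundance {summary.relative_abundance:.2f} loci/Mb, density "
          f"{summary.relative_density:.2f} bp/Mb")
    print(f"planted perfect loci recovered: {len(found & planted)}/{len(planted)}"
          f" (unplanned: {len(found - planted)})")


if __name__ == "__main__":
    main()
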