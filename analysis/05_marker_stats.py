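#!/usr/bin/env python
"""Per-locus diversity statistics (Na, MAF, Ne, I, Ho, He, uHe, PIC) and
chromosome-wise means (TP/TPP) from the ePCR allele-size matrix.
Writes results/stats/."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS

from citrosat.io import read_primer_tsv
from citrosat.stats import AlleleMatrix, group_stats, stats_table


def main() -> None:
    matrix = AlleleMatrix.from_tsv(RESULTS / "epcr" / "allele_matrix.tsv")
    per_locus = stats_table(matrix)
    chrom_of = {p.id: p.chrom for p in read_primer_tsv(RESULTS / "primers.tsv")}
    per_chrom = group_stats(matrix, {l: chrom_of[l] for l in matrix.loci})

    outdir = RESULTS / "stats"
    outdir.mkdir(parents=True, exist_ok=True)
    per_locus.round(4).to_csv(outdir / "locus_stats.tsv", sep="\t")
    per_chrom.round(4).to_csv(outdir / "chromosome_stats.tsv", sep="\t")

    print(f"{len(per_locus)} loci: mean Na {per_locus['Na'].mean():.2f}, "
          f"mean MAF {per_locus['MAF'].mean():.2f}, mean He "
          f"{per_locus['He'].mean():.2f}, mean PIC {per_locus['PIC'].mean():.2f}")
    print("chromosome-wise means:")
    print(per_chrom.round(3).to_string())


if __name__ == "__main__":
    main()
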