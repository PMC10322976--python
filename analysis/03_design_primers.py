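#!/usr/bin/env python
"""Design flanking primers for the extremely variable (tract >= 40 nt) class I
SSRs of the reference genome. Writes results/primers.tsv."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS

from citrosat import Genome, design_primers
from citrosat.io import read_gff3, write_primer_tsv


def main() -> None:
    genome = Genome.from_fasta(RESULTS / "genomes" / "ref.fasta", genome_id="ref")
    loci = [l for l in read_gff3(RESULTS / "mining" / "ssr_loci.gff3")
            if l.ssr_class == "I" and l.tract_length >= 40]
    pairs = []
    for locus in loci:
        pairs.extend(design_primers(locus, genome, k=1, id_prefix="HvSSR"))
    write_primer_tsv(pairs, RESULTS / "primers.tsv")
    tms = [t for p in pairs for t in (p.forward_tm, p.reverse_tm)]
    print(f"designed {len(pairs)} primer pairs for {len(loci)} extremely variable "
          f"loci ({100 * len(pairs) / len(loci):.1f}% success)")
    print(f"Tm range {min(tms):.1f}-{max(tms):.1f} degC, products "
          f"{min(p.expected_product_bp for p in pairs)}-"
          f"{max(p.expected_product_bp for p in pairs)} bp")


if __name__ == "__main__":
    main()
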