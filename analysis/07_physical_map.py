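#!/usr/bin/env python
"""Chromosome physical map of the extremely variable SSR markers: ordered
positions, densities, inter-marker gaps and tract-length bins.
Writes results/map/."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS

from citrosat import Genome
from citrosat.io import read_gff3, write_map_tsv
from citrosat.physmap import build_physical_map


def main() -> None:
    genome = Genome.from_fasta(RESULTS / "genomes" / "ref.fasta", genome_id="ref")
    markers = [l for l in read_gff3(RESULTS / "mining" / "ssr_loci.gff3")
               if l.ssr_class == "I" and l.tract_length >= 40]
    pm = build_physical_map(markers, genome)

    outdir = RESULTS / "map"
    outdir.mkdir(parents=True, exist_ok=True)
    write_map_tsv(pm, outdir / "physical_map.tsv")

    print(f"{pm.n_markers} markers mapped:")
    print(pm.chromosomes.round(2).to_string())
    print("tract-length bins:")
    print(pm.tract_bins.to_string())


if __name__ == "__main__":
    main()
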