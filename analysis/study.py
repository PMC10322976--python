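"""Shared configuration for the numbered analysis scripts.

Defines the synthetic study: a reference genome with planted SSR tracts on two
chromosomes, and six related genomes whose extremely variable tracts differ by
known repeat counts — a desk-scale analogue of surveying a genome for
microsatellites, designing markers for the hypervariable subset and screening
them across a seven-genome panel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from citrosat.simulate import PlantSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"

CHROM_LENGTHS = {"chr1": 56_000, "chr2": 56_000}
GC_BACKGROUND = 0.42
N_RELATED = 6
SNP_RATE = 0.001

HV_MOTIFS = ["AT", "AAG", "AC", "ATC", "AAT", "AG", "ACC", "AAC"]


def plant_specs(seed: int) -> list[PlantSpec]:
    rng = np.random.default_rng(seed % 2**31)
    specs = []
    for c, chrom in enumerate(CHROM_LENGTHS):
        for i in range(8):
            motif = HV_MOTIFS[(i + 4 * c) % len(HV_MOTIFS)]
            reps = int(rng.integers(20, 31)) if len(motif) == 2 else int(rng.integers(14, 21))
            specs.append(PlantSpec(motif, reps, chrom, 3001 + 6000 * i))
        specs.append(PlantSpec("A", 13, chrom, 1201))
        specs.append(PlantSpec("AGAT", 6, chrom, 52_001))
    return specs
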