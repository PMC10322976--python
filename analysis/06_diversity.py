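#!/usr/bin/env python
"""Genetic relatedness of the panel from the marker matrix: shared-allele
distances, NJ and UPGMA trees, and principal coordinate analysis.
Writes results/diversity/."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS

from citrosat.diversity import distance_matrix, nj_tree, pcoa, upgma_tree
from citrosat.stats import AlleleMatrix


def main() -> None:
    matrix = AlleleMatrix.from_tsv(RESULTS / "epcr" / "allele_matrix.tsv")
    D = distance_matrix(matrix, metric="shared_allele")

    outdir = RESULTS / "diversity"
    outdir.mkdir(parents=True, exist_ok=True)
    D.to_dataframe().round(6).to_csv(outdir / "distances.tsv", sep="\t")
    (outdir / "nj.nwk").write_text(nj_tree(D).newick + "\n")
    (outdir / "upgma.nwk").write_text(upgma_tree(D).newick + "\n")
    res = pcoa(D, n_axes=3)
    with open(outdir / "pcoa.tsv", "w") as fh:
        fh.write("# percent_variance\t"
                 + "\t".join(f"{v:.2f}" for v in res.percent_variance) + "\n")
        res.coordinates.round(6).to_csv(fh, sep="\t")

    print(f"distances over {len(D.ids)} genomes "
          f"(range {D.data[D.data > 0].min():.3f}-{D.data.max():.3f})")
    axes = ", ".join(f"PCo{i + 1} {v:.2f}%" for i, v in enumerate(res.percent_variance))
    print(f"PCoA: {axes}")
    print(f"NJ + UPGMA trees written to {outdir}")


if __name__ == "__main__":
    main()
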