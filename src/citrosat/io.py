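"""Tabular and annotation-format exports (GFF3, BED, TSV, newick, Circos tracks).

Coordinate conventions: GFF3 is 1-based inclusive, BED is 0-based half-open;
both exports of the same locus describe the identical genomic interval. Float
columns in summary tables are fixed at 2 decimals and column order is fixed,
so re-running on identical inputs is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from citrosat.genome import Genome
from citrosat.mining import SSRLocus, SSRSummary, classify_ssr
from citrosat.physmap import PhysicalMap
from citrosat.primers import PrimerPair

GFF3_HEADER = "##gff-version 3"


def write_gff3(loci: list[SSRLocus], path: str | Path, source: str = "citrosat") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for locus in loci:
            attrs = [
                f"ID={locus.id}",
                f"motif={locus.motif}",
                f"canonical_motif={locus.canonical}",
                f"repeats={locus.repeats}",
                f"ssr_type={locus.ssr_type}",
            ]
            if locus.ssr_class is not None:
                attrs.append(f"ssr_class={locus.ssr_class}")
            if locus.ssr_type == "imperfect":
                attrs.append(f"mismatches={locus.mismatches}")
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        source,
                        "microsatellite",
                        str(locus.start),
                        str(locus.end),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    return path


def read_gff3(path: str | Path) -> list[SSRLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, _source, _type, start, end, _score, _strand, _phase, attr = (
                line.split("\t")
            )
            fields = dict(kv.split("=", 1) for kv in attr.split(";") if kv)
            locus = SSRLocus(
                chrom=chrom,
                start=int(start),
                end=int(end),
                motif=fields["motif"],
                canonical=fields["canonical_motif"],
                repeats=int(fields["repeats"]),
                ssr_type=fields.get("ssr_type", "perfect"),
                mismatches=int(fields.get("mismatches", 0)),
            )
            loci.append(classify_ssr(locus))
    return loci


def write_bed(loci: list[SSRLocus], path: str | Path) -> Path:
    """BED export: 0-based half-open intervals, name = motif x repeats."""
    path = Path(path)
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.motif}x{locus.repeats}\n"
            )
    return path


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED intervals as (chrom, start0, end0, name) tuples (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]),
                        parts[3] if len(parts) > 3 else ""))
    return out


PRIMER_COLUMNS = [
    "id", "locus_ref", "chrom", "forward_seq", "reverse_seq", "forward_tm",
    "reverse_tm", "forward_gc", "reverse_gc", "expected_product_bp",
    "forward_start", "reverse_end", "penalty",
]


def write_primer_tsv(pairs: list[PrimerPair], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for p in pairs:
        row = {c: getattr(p, c) for c in PRIMER_COLUMNS}
        for c in ("forward_tm", "reverse_tm", "forward_gc", "reverse_gc", "penalty"):
            row[c] = f"{row[c]:.2f}"
        rows.append(row)
    pd.DataFrame(rows, columns=PRIMER_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_primer_tsv(path: str | Path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for _, r in df.iterrows():
        pairs.append(
            PrimerPair(
                id=r["id"], locus_ref=r["locus_ref"], chrom=r["chrom"],
                forward_seq=r["forward_seq"], reverse_seq=r["reverse_seq"],
                forward_tm=float(r["forward_tm"]), reverse_tm=float(r["reverse_tm"]),
                forward_gc=float(r["forward_gc"]), reverse_gc=float(r["reverse_gc"]),
                expected_product_bp=int(r["expected_product_bp"]),
                forward_start=int(r["forward_start"]),
                reverse_end=int(r["reverse_end"]),
                penalty=float(r["penalty"]),
            )
        )
    return pairs


def write_summary_tsv(summary: SSRSummary, path: str | Path) -> Path:
    """Mining summary in the layout of the genome-characterization tables."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"examined_sequence_bp\t{summary.genome_bp}\n")
        fh.write(f"total_ssr_count\t{summary.total_count}\n")
        fh.write(f"total_ssr_length_bp\t{summary.total_length_bp}\n")
        fh.write(f"relative_abundance_loci_per_mb\t{summary.relative_abundance:.2f}\n")
        fh.write(f"relative_density_bp_per_mb\t{summary.relative_density:.2f}\n")
        fh.write(f"average_length_bp\t{summary.average_length:.2f}\n")
    by_class = summary.by_size_class.copy()
    for col in ("percent", "average_length", "abundance", "density"):
        by_class[col] = by_class[col].map(lambda v: f"{v:.2f}")
    by_class.to_csv(path.with_suffix(".by_class.tsv"), sep="\t")
    by_chrom = summary.by_chromosome.copy()
    for col in ("abundance", "density"):
        by_chrom[col] = by_chrom[col].map(lambda v: f"{v:.2f}")
    by_chrom.to_csv(path.with_suffix(".by_chromosome.tsv"), sep="\t")
    return path


def write_map_tsv(pmap: PhysicalMap, path: str | Path) -> Path:
    """MapChart-style marker map: chromosome, position, marker id."""
    path = Path(path)
    pmap.markers[["chromosome", "position", "marker_id", "tract_length", "tract_bin"]
                 ].to_csv(path, sep="\t", index=False)
    pmap.chromosomes.assign(
        markers_per_mb=pmap.chromosomes["markers_per_mb"].map(lambda v: f"{v:.2f}"),
        mean_gap=pmap.chromosomes["mean_gap"].map(lambda v: f"{v:.2f}"),
    ).to_csv(path.with_suffix(".chromosomes.tsv"), sep="\t")
    pmap.tract_bins.to_csv(path.with_suffix(".tract_bins.tsv"), sep="\t")
    return path


def write_circos_tracks(genome: Genome, loci: list[SSRLocus], outdir: str | Path,
                        prefix: str = "circos") -> tuple[Path, Path]:
    """Circos-compatible karyotype and tile-track text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    karyotype = outdir / f"{prefix}.karyotype.txt"
    with open(karyotype, "w") as fh:
        for i, chrom in enumerate(genome, 1):
            fh.write(f"chr - {chrom} {chrom} 0 {len(genome[chrom])} chr{i}\n")
    track = outdir / f"{prefix}.ssr_track.txt"
    with open(track, "w") as fh:
        for locus in loci:
            fh.write(f"{locus.chrom} {locus.start - 1} {locus.end} "
                     f"motif={locus.motif}\n")
    return karyotype, track


def plot_marker_density(pmap: PhysicalMap, path: str | Path,
                        bin_size: int = 1_000_000) -> Path:
    """Simple per-chromosome marker-position strip plot (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    chroms = list(pmap.chromosomes.index)
    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.4 * len(chroms)))
    for y, chrom in enumerate(chroms):
        length = pmap.chromosomes.loc[chrom, "length_bp"]
        ax.hlines(y, 0, length / 1e6, color="lightgrey", lw=6)
        sub = pmap.markers[pmap.markers["chromosome"] == chrom]
        ax.vlines(sub["position"] / 1e6, y - 0.2, y + 0.2, color="darkred", lw=0.8)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (Mb)")
    ax.set_title("SSR marker physical map")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def export_reports(
    outdir: str | Path,
    loci: list[SSRLocus] | None = None,
    genome: Genome | None = None,
    summary: SSRSummary | None = None,
    primers: list[PrimerPair] | None = None,
    pmap: PhysicalMap | None = None,
    trees: dict | None = None,
    stats_tables: dict | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write every available result to ``outdir``; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if loci is not None:
        written["gff3"] = write_gff3(loci, outdir / "ssr_loci.gff3")
        written["bed"] = write_bed(loci, outdir / "ssr_loci.bed")
        if genome is not None:
            k, t = write_circos_tracks(genome, loci, outdir)
            written["circos_karyotype"], written["circos_track"] = k, t
    if summary is not None:
        written["summary"] = write_summary_tsv(summary, outdir / "ssr_summary.tsv")
    if primers is not None:
        written["primers"] = write_primer_tsv(primers, outdir / "primers.tsv")
    if pmap is not None:
        written["map"] = write_map_tsv(pmap, outdir / "physical_map.tsv")
        if plots:
            written["map_plot"] = plot_marker_density(pmap, outdir / "physical_map.png")
    if trees:
        for name, tree in trees.items():
            p = outdir / f"{name}.nwk"
            p.write_text(tree.newick + "\n")
            written[f"tree_{name}"] = p
    if stats_tables:
        for name, df in stats_tables.items():
            p = outdir / f"{name}.tsv"
            df.round(4).to_csv(p, sep="\t")
            written[name] = p
    return written
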