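"""Chromosome physical maps of SSR markers.

A physical map orders markers by base-pair position along each chromosome and
summarizes marker density (markers/Mb), inter-marker gaps, and the tract-length
spectrum binned at 40-49, 50-59, 60-69 and >= 70 nt (inclusive lower edges;
markers under 40 nt, if any, fall in a leading '<40' bin so bin counts always
sum to the marker count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from citrosat.genome import Genome
from citrosat.mining import SSRLocus

TRACT_BINS = ["<40", "40-49", "50-59", "60-69", ">=70"]


def tract_bin(tract_length: int) -> str:
    if tract_length < 40:
        return "<40"
    if tract_length <= 49:
        return "40-49"
    if tract_length <= 59:
        return "50-59"
    if tract_length <= 69:
        return "60-69"
    return ">=70"


@dataclass
class PhysicalMap:
    markers: pd.DataFrame  # marker_id, chromosome, position, tract_length (sorted)
    chromosomes: pd.DataFrame  # length_bp, n_markers, markers_per_mb, max_gap, mean_gap
    tract_bins: pd.DataFrame  # chromosomes x bins, counts

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def gaps(self, chrom: str) -> list[int]:
        pos = self.markers.loc[self.markers["chromosome"] == chrom, "position"]
        return list(np.diff(np.sort(pos.to_numpy())))


def build_physical_map(markers, genome: Genome) -> PhysicalMap:
    """Build a physical map from SSR loci (or (id, chrom, position, tract) tuples)."""
    rows = []
    for m in markers:
        if isinstance(m, SSRLocus):
            rows.append(
                {"marker_id": m.id, "chromosome": m.chrom, "position": m.start,
                 "tract_length": m.tract_length}
            )
        else:
            mid, chrom, pos, tract = m
            rows.append(
                {"marker_id": mid, "chromosome": chrom, "position": int(pos),
                 "tract_length": int(tract)}
            )
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position", "tract_length"])
    for _, r in df.iterrows():
        if r["chromosome"] not in genome:
            raise ValueError(f"marker {r['marker_id']} on unknown chromosome "
                             f"{r['chromosome']!r}")
        if not 1 <= r["position"] <= len(genome[r["chromosome"]]):
            raise ValueError(f"marker {r['marker_id']} beyond end of {r['chromosome']}")
    df = df.sort_values(["chromosome", "position"], kind="stable").reset_index(drop=True)
    df["tract_bin"] = [tract_bin(t) for t in df["tract_length"]]

    chrom_rows = []
    bin_rows = []
    for chrom in genome:
        sub = df[df["chromosome"] == chrom]
        length = len(genome[chrom])
        gaps = np.diff(sub["position"].to_numpy()) if len(sub) > 1 else np.array([])
        chrom_rows.append(
            {
                "chromosome": chrom,
                "length_bp": length,
                "n_markers": len(sub),
                "markers_per_mb": len(sub) / (length / 1e6) if length else 0.0,
                "max_gap": int(gaps.max()) if gaps.size else 0,
                "mean_gap": float(gaps.mean()) if gaps.size else 0.0,
            }
        )
        counts = sub["tract_bin"].value_counts()
        bin_rows.append(
            {"chromosome": chrom, **{b: int(counts.get(b, 0)) for b in TRACT_BINS}}
        )
    return PhysicalMap(
        markers=df,
        chromosomes=pd.DataFrame(chrom_rows).set_index("chromosome"),
        tract_bins=pd.DataFrame(bin_rows).set_index("chromosome")[TRACT_BINS],
    )
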