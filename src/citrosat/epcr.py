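"""Exact-match electronic PCR (e-PCR) across genome panels.

A primer pair amplifies wherever a full-length exact match of the forward
primer on one strand is paired with a full-length exact match of the reverse
primer (as reverse complement) downstream on the same template orientation;
both orientations are searched. No mismatches and no gaps are allowed by
default (a mismatch-tolerant mode is not part of the validated surface).
Amplicon coordinates run 5' end of one primer to 5' end of the other,
1-based inclusive on the forward strand, and this span defines the amplicon
size used for polymorphism calls.

Amplicons outside the size window (default 100-1000 bp) are discarded; when a
pair carries a designed product size, amplicons deviating from it by more than
``margin`` (default 3000 bp, usually inert under the size cap) are discarded
too. Primer sites are located through a contiguous-word index (default word
size 12) and verified by full-length comparison.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from citrosat.genome import Genome, revcomp
from citrosat.primers import PrimerPair
from citrosat.stats import AlleleMatrix

DEFAULT_EPCR_PARAMS = {
    "amplicon_min": 100,
    "amplicon_max": 1000,
    "margin": 3000,
    "allow_mismatch": False,
    "allow_gap": False,
}


@dataclass(frozen=True)
class Amplicon:
    genome_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    @property
    def size(self) -> int:
        return self.end - self.start + 1


class SeedIndex:
    """Contiguous-word index of a genome's forward strand."""

    def __init__(self, genome: Genome, word_size: int = 12):
        if word_size < 8:
            raise ValueError("word_size must be >= 8")
        self.genome = genome
        self.word_size = word_size
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            w = word_size
            for i in range(len(seq) - w + 1):
                word = seq[i : i + w]
                if "N" not in word:
                    self._index[word].append((chrom, i))

    def word_positions(self, word: str) -> list[tuple[str, int]]:
        """0-based forward-strand positions of an exact word."""
        if len(word) != self.word_size:
            raise ValueError(f"query must be exactly {self.word_size} nt")
        return list(self._index.get(word, []))

    def find_exact(self, query: str) -> list[tuple[str, int]]:
        """0-based positions of full-length exact matches on the forward strand."""
        if len(query) < self.word_size:
            raise ValueError(
                f"query of {len(query)} nt is shorter than word size {self.word_size}"
            )
        hits = []
        w = self.word_size
        for chrom, i in self._index.get(query[:w], []):
            if self.genome[chrom][i : i + len(query)] == query:
                hits.append((chrom, i))
        return hits


def index_genome(genome: Genome, word_size: int = 12) -> SeedIndex:
    """Build a word index supporting both-strand lookups via revcomp queries."""
    return SeedIndex(genome, word_size=word_size)


def run_epcr(
    pair: PrimerPair,
    genome: Genome,
    params: dict | None = None,
    index: SeedIndex | None = None,
) -> list[Amplicon]:
    """All amplicons a primer pair yields on one genome, deduplicated and
    sorted by (chromosome, start)."""
    p = dict(DEFAULT_EPCR_PARAMS)
    if params:
        p.update(params)
    if p["allow_mismatch"] or p["allow_gap"]:
        raise NotImplementedError("only exact-match ePCR is supported")
    idx = index if index is not None else index_genome(genome)
    if idx.genome is not genome:
        raise ValueError("index was built for a different genome")

    f, r = pair.forward_seq.upper(), pair.reverse_seq.upper()
    found: set[Amplicon] = set()

    def pair_sites(left_sites, right_sites, left_len, right_len):
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for chrom, i in right_sites:
            by_chrom[chrom].append(i)
        for chrom, i in left_sites:
            start = i  # 5' end of left primer, 0-based
            for j in sorted(by_chrom.get(chrom, [])):
                end = j + right_len - 1  # 5' end of right primer, 0-based
                if end <= start:
                    continue
                size = end - start + 1
                if not p["amplicon_min"] <= size <= p["amplicon_max"]:
                    continue
                if (
                    pair.expected_product_bp
                    and abs(size - pair.expected_product_bp) > p["margin"]
                ):
                    continue
                found.add(
                    Amplicon(genome.genome_id, chrom, start + 1, end + 1)
                )

    # orientation 1: forward primer on + strand, reverse primer downstream
    pair_sites(idx.find_exact(f), idx.find_exact(revcomp(r)), len(f), len(r))
    # orientation 2: reverse primer binds + strand, forward primer downstream
    pair_sites(idx.find_exact(r), idx.find_exact(revcomp(f)), len(r), len(f))

    order = {c: i for i, c in enumerate(genome)}
    return sorted(found, key=lambda a: (order[a.chrom], a.start, a.end))


def classify_amplification(amplicons: list[Amplicon]) -> int:
    """Bin a locus by amplicon count: 0, 1, 2 or 3 (meaning >= 3)."""
    return min(len(amplicons), 3)


@dataclass
class EPCRResult:
    """Cross-genome screen outcome for one primer pair."""

    primer_id: str
    amplicons: dict[str, list[Amplicon]]  # genome_id -> amplicons
    locus_count_class: dict[str, int] = field(default_factory=dict)
    reference_id: str = ""
    single_locus: bool = False  # exactly one amplicon in the reference genome
    transferable: bool = False  # amplified in >= 1 non-reference genome
    transferable_genomes: int = 0  # genomes (incl. reference) with >= 1 amplicon
    polymorphic: bool = False  # >= 2 distinct sizes among >= 2 amplified genomes

    def sizes(self) -> dict[str, list[int]]:
        return {g: [a.size for a in amps] for g, amps in self.amplicons.items()}


def cross_genome_screen(
    pairs: list[PrimerPair],
    genomes: list[Genome],
    reference_id: str,
    params: dict | None = None,
) -> list[EPCRResult]:
    """Run every primer pair against every genome of a panel.

    Single-locus status is judged on the reference genome; a pair is
    transferable when it amplifies in at least one non-reference genome, and
    polymorphic when at least two distinct amplicon sizes occur among the
    (>= 2) genomes it amplifies in.
    """
    ids = [p.id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate primer ids")
    genome_ids = [g.genome_id for g in genomes]
    if reference_id not in genome_ids:
        raise ValueError(f"reference genome {reference_id!r} not in panel")
    indexes = {g.genome_id: index_genome(g) for g in genomes}

    results = []
    for pair in pairs:
        amps = {
            g.genome_id: run_epcr(pair, g, params=params, index=indexes[g.genome_id])
            for g in genomes
        }
        amplified = [gid for gid in genome_ids if amps[gid]]
        all_sizes = {a.size for gid in amplified for a in amps[gid]}
        results.append(
            EPCRResult(
                primer_id=pair.id,
                amplicons=amps,
                locus_count_class={g: classify_amplification(a) for g, a in amps.items()},
                reference_id=reference_id,
                single_locus=len(amps[reference_id]) == 1,
                transferable=any(gid != reference_id for gid in amplified),
                transferable_genomes=len(amplified),
                polymorphic=len(amplified) >= 2 and len(all_sizes) >= 2,
            )
        )
    return results


def build_allele_matrix(results: list[EPCRResult], genomes: list[Genome]) -> AlleleMatrix:
    """Primer x genome allele-size matrix from a cross-genome screen.

    Each genome contributes one observation per primer: a homozygous diploid
    genotype of the amplicon size where it yields a single amplicon, a
    heterozygote of the two sizes where it yields exactly two, and a missing
    cell otherwise (no amplification, or > 2 products).
    """
    genome_ids = [g.genome_id for g in genomes]
    loci = [r.primer_id for r in results]
    genotypes: dict = {}
    for r in results:
        for gid in genome_ids:
            amps = r.amplicons.get(gid, [])
            if len(amps) == 1:
                genotypes[(r.primer_id, gid)] = (amps[0].size, amps[0].size)
            elif len(amps) == 2:
                a, b = sorted(x.size for x in amps)
                genotypes[(r.primer_id, gid)] = (a, b)
            else:
                genotypes[(r.primer_id, gid)] = None
    return AlleleMatrix(loci, genome_ids, genotypes, mode="codominant")
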