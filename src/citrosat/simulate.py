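"""Synthetic genomes with planted SSR tracts and exact ground truth.

The simulator emulates the structures the mining / primer / e-PCR stages are
built to recover: chromosome-scale FASTA sequences with known perfect,
imperfect and compound-candidate repeat tracts planted at known coordinates,
"related" genomes whose tracts differ by known repeat-count changes (the
cross-species size polymorphisms an e-PCR screen scores), and diploid allele
matrices drawn from known allele frequencies.

Background sequence is i.i.d. with a configurable GC fraction and is
rejection-filtered: any chance repeat tract that would meet the miner's
detection thresholds is resampled, so the truth table is exhaustive rather
than probabilistic. Planted tract boundaries are forced to break motif phase
so every planted tract is maximal.

All randomness flows from one integer seed; per-operation sub-seeds are
derived deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from citrosat.genome import Genome
from citrosat.mining import find_perfect_ssrs
from citrosat.stats import AlleleMatrix

_BASES = np.array(list("ACGT"))
_ACGT = frozenset("ACGT")


@dataclass
class PlantSpec:
    """One repeat tract to plant.

    ``insert_position`` is the 1-based start of the tract on the chromosome.
    ``imperfection_positions`` are 0-based offsets within the tract that are
    substituted (making the tract imperfect).
    """

    motif: str
    repeats: int
    chromosome_id: str
    insert_position: int
    imperfection_positions: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.motif = self.motif.upper()
        if not self.motif or not set(self.motif) <= _ACGT:
            raise ValueError(f"motif must be non-empty ACGT, got {self.motif!r}")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError("motif length must be 1-6 nt")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.insert_position < 1:
            raise ValueError("insert_position is 1-based and must be >= 1")
        t = len(self.motif) * self.repeats
        for p in self.imperfection_positions:
            if not 0 <= p < t:
                raise ValueError(f"imperfection offset {p} outside tract of {t} nt")

    @property
    def tract_length(self) -> int:
        return len(self.motif) * self.repeats

    @property
    def start(self) -> int:
        return self.insert_position

    @property
    def end(self) -> int:
        return self.insert_position + self.tract_length - 1


@dataclass
class TruthRecord:
    """Ground truth for one planted tract."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    repeats: int
    ssr_type: str  # perfect | imperfect
    mismatches: int = 0
    compound_group: int | None = None  # shared id for tracts within d_max of each other
    per_genome_repeats: dict = field(default_factory=dict)

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, salt]))


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _substituted(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_genome(
    chrom_lengths: dict[str, int],
    plant_specs: list[PlantSpec],
    gc_background: float = 0.38,
    seed: int = 0,
    min_repeats: dict | None = None,
    compound_d_max: int = 100,
    genome_id: str = "synthetic",
    max_rejection_rounds: int = 60,
) -> tuple[Genome, list[TruthRecord]]:
    """Generate one genome with planted tracts and an exhaustive truth table.

    Background is resampled wherever an unplanned tract would meet the miner's
    detection thresholds, so ``find_perfect_ssrs`` returns exactly the planted
    perfect loci. Deterministic for a fixed seed.
    """
    by_chrom: dict[str, list[PlantSpec]] = {c: [] for c in chrom_lengths}
    for spec in plant_specs:
        if spec.chromosome_id not in chrom_lengths:
            raise ValueError(f"unknown chromosome {spec.chromosome_id!r}")
        if spec.end > chrom_lengths[spec.chromosome_id]:
            raise ValueError(f"planted tract {spec.motif}x{spec.repeats} exceeds "
                             f"{spec.chromosome_id} length")
        by_chrom[spec.chromosome_id].append(spec)
    for chrom, specs in by_chrom.items():
        specs.sort(key=lambda s: s.start)
        for a, b in zip(specs, specs[1:]):
            if b.start <= a.end:
                raise ValueError(f"planted tracts overlap on {chrom}: "
                                 f"{a.start}-{a.end} and {b.start}-{b.end}")

    rng = _rng(seed, 1)
    seqs: dict[str, np.ndarray] = {}
    truth: list[TruthRecord] = []
    for chrom, length in chrom_lengths.items():
        arr = _background(rng, length, gc_background)
        for spec in by_chrom[chrom]:
            tract = list(spec.motif * spec.repeats)
            for off in spec.imperfection_positions:
                tract[off] = _substituted(tract[off], rng)
            a = spec.start - 1
            arr[a : a + len(tract)] = tract
            # break motif phase at both boundaries so the tract is maximal
            k = len(spec.motif)
            if a - 1 >= 0:
                expected = spec.motif[(-1) % k]
                if arr[a - 1] == expected:
                    arr[a - 1] = _substituted(expected, rng)
            b = a + len(tract)
            if b < length:
                expected = spec.motif[(b - a) % k]
                if arr[b] == expected:
                    arr[b] = _substituted(expected, rng)
            truth.append(
                TruthRecord(
                    chrom=chrom,
                    start=spec.start,
                    end=spec.end,
                    motif=spec.motif,
                    repeats=spec.repeats,
                    ssr_type="imperfect" if spec.imperfection_positions else "perfect",
                    mismatches=len(spec.imperfection_positions),
                    per_genome_repeats={genome_id: spec.repeats},
                )
            )
        seqs[chrom] = arr

    # annotate compound-candidate groups (inter-tract gap <= d_max)
    group_id = 0
    for chrom in chrom_lengths:
        recs = sorted((t for t in truth if t.chrom == chrom), key=lambda t: t.start)
        current: list[TruthRecord] = []
        for rec in recs:
            if current and rec.start - current[-1].end - 1 <= compound_d_max:
                current.append(rec)
            else:
                if len(current) >= 2:
                    for r in current:
                        r.compound_group = group_id
                    group_id += 1
                current = [rec]
        if len(current) >= 2:
            for r in current:
                r.compound_group = group_id
            group_id += 1

    planted_mask = {
        chrom: np.zeros(chrom_lengths[chrom], dtype=bool) for chrom in chrom_lengths
    }
    planted_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for rec in truth:
        planted_mask[rec.chrom][rec.start - 1 : rec.end] = True
        planted_spans[rec.chrom].append((rec.start, rec.end))
    expected_perfect = {
        (t.chrom, t.start, t.end, t.motif) for t in truth if t.ssr_type == "perfect"
    }

    # rejection filtering: resample background under any unplanned detected tract
    for _ in range(max_rejection_rounds):
        genome = Genome({c: "".join(seqs[c]) for c in chrom_lengths}, genome_id=genome_id)
        offending = []
        for locus in find_perfect_ssrs(genome, min_repeats=min_repeats):
            key = (locus.chrom, locus.start, locus.end, locus.motif)
            if key in expected_perfect:
                continue
            if any(locus.start >= s and locus.end <= e
                   for s, e in planted_spans[locus.chrom]):
                continue  # chance-perfect run inside a planted (imperfect) tract
            offending.append(locus)
        if not offending:
            return genome, truth
        for locus in offending:
            sl = slice(locus.start - 1, locus.end)
            mask = planted_mask[locus.chrom][sl]
            fresh = _background(rng, locus.end - locus.start + 1, gc_background)
            seqs[locus.chrom][sl] = np.where(mask, seqs[locus.chrom][sl], fresh)
    raise RuntimeError("could not clear unplanned SSRs; lower gc bias or lengths")


def mutate_related_genomes(
    genome: Genome,
    truth: list[TruthRecord],
    repeat_deltas: dict,
    n_genomes: int | None = None,
    snp_rate_outside_flanks: float = 0.0,
    flank_width: int = 400,
    seed: int = 0,
) -> tuple[list[Genome], list[TruthRecord]]:
    """Derive related genomes differing by known repeat-count changes.

    ``repeat_deltas`` maps a truth locus id (``chrom:start-end``) to a list of
    per-genome integer deltas; every list must have the same length (the number
    of related genomes, or pass ``n_genomes`` when all deltas default to 0).
    Whole motif copies are inserted/removed at the 3' end of each tract, so the
    expected amplicon at a locus changes by ``len(motif) * delta`` bp.
    Background substitutions at ``snp_rate_outside_flanks`` never touch planted
    tracts nor their primer-landing flanks (``flank_width`` bp each side).
    """
    lengths = [len(v) for v in repeat_deltas.values()]
    if lengths:
        if len(set(lengths)) != 1:
            raise ValueError("all delta lists must have the same length")
        n = lengths[0]
    elif n_genomes is not None:
        n = n_genomes
    else:
        raise ValueError("pass repeat_deltas or n_genomes")
    by_id = {t.locus_id: t for t in truth}
    for locus_id, deltas in repeat_deltas.items():
        rec = by_id.get(locus_id)
        if rec is None:
            raise ValueError(f"unknown truth locus {locus_id!r}")
        for d in deltas:
            if rec.repeats + d < 0:
                raise ValueError(
                    f"delta {d} makes {locus_id} repeat count negative"
                )

    out_truth = [
        TruthRecord(
            chrom=t.chrom, start=t.start, end=t.end, motif=t.motif, repeats=t.repeats,
            ssr_type=t.ssr_type, mismatches=t.mismatches, compound_group=t.compound_group,
            per_genome_repeats=dict(t.per_genome_repeats),
        )
        for t in truth
    ]
    by_id_out = {t.locus_id: t for t in out_truth}

    genomes: list[Genome] = []
    for g in range(n):
        rng = _rng(seed, 1000 + g)
        gid = f"{genome.genome_id}_rel{g + 1}"
        seqs: dict[str, str] = {}
        for chrom, seq in genome.items():
            recs = sorted((t for t in truth if t.chrom == chrom), key=lambda t: t.start)
            protected = np.zeros(len(seq), dtype=bool)
            for t in recs:
                lo = max(0, t.start - 1 - flank_width)
                hi = min(len(seq), t.end + flank_width)
                protected[lo:hi] = True
            chars = np.array(list(seq))
            if snp_rate_outside_flanks > 0:
                hits = np.where(
                    (~protected) & (rng.random(len(seq)) < snp_rate_outside_flanks)
                )[0]
                for i in hits:
                    chars[i] = _substituted(chars[i], rng)
            pieces: list[str] = []
            prev = 0
            for t in recs:
                deltas = repeat_deltas.get(t.locus_id)
                d = deltas[g] if deltas is not None else 0
                by_id_out[t.locus_id].per_genome_repeats[gid] = t.repeats + d
                a, b = t.start - 1, t.end
                pieces.append("".join(chars[prev:a]))
                tract = "".join(chars[a:b])
                k = len(t.motif)
                if d > 0:
                    tract = tract + t.motif * d
                elif d < 0:
                    tract = tract[: len(tract) + k * d]
                pieces.append(tract)
                prev = b
            pieces.append("".join(chars[prev:]))
            seqs[chrom] = "".join(pieces)
        genomes.append(Genome(seqs, genome_id=gid))
    return genomes, out_truth


def generate_allele_matrix(
    n_loci: int,
    n_individuals: int,
    allele_freqs,
    missing_rate: float = 0.0,
    seed: int = 0,
    allele_size_base: int = 200,
    allele_size_step: int = 2,
) -> AlleleMatrix:
    """Diploid genotypes drawn i.i.d. from per-locus allele frequencies.

    ``allele_freqs`` is one frequency vector (recycled over loci) or a list of
    ``n_loci`` vectors; each must sum to 1 within 1e-9. Allele labels are
    fragment sizes ``allele_size_base + allele_size_step * index`` bp. Whole
    genotypes go missing independently at ``missing_rate``.
    """
    freq_list = list(allele_freqs)
    if freq_list and np.isscalar(freq_list[0]):
        freq_list = [freq_list] * n_loci
    if len(freq_list) != n_loci:
        raise ValueError(f"need {n_loci} frequency vectors, got {len(freq_list)}")
    for i, f in enumerate(freq_list):
        s = float(np.sum(f))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"frequency vector {i} sums to {s}, not 1")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0, 1]")

    rng = _rng(seed, 7)
    loci = [f"L{i + 1}" for i in range(n_loci)]
    individuals = [f"ind{j + 1}" for j in range(n_individuals)]
    genotypes: dict = {}
    for locus, freqs in zip(loci, freq_list):
        f = np.asarray(freqs, dtype=float)
        labels = [allele_size_base + allele_size_step * a for a in range(len(f))]
        draws = rng.choice(len(f), size=(n_individuals, 2), p=f / f.sum())
        miss = rng.random(n_individuals) < missing_rate
        for j, ind in enumerate(individuals):
            if miss[j]:
                genotypes[(locus, ind)] = None
            else:
                a, b = sorted(draws[j])
                genotypes[(locus, ind)] = (labels[a], labels[b])
    return AlleleMatrix(loci, individuals, genotypes, mode="codominant")


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> Path:
    """Truth table as TSV with 1-based inclusive coordinates."""
    path = Path(path)
    genome_ids: list[str] = []
    for t in truth:
        for gid in t.per_genome_repeats:
            if gid not in genome_ids:
                genome_ids.append(gid)
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "motif", "repeats", "tract_length",
                "ssr_type", "mismatches", "compound_group"]
        cols += [f"repeats:{g}" for g in genome_ids]
        fh.write("\t".join(cols) + "\n")
        for t in sorted(truth, key=lambda t: (t.chrom, t.start)):
            row = [t.chrom, t.start, t.end, t.motif, t.repeats, t.tract_length,
                   t.ssr_type, t.mismatches,
                   "" if t.compound_group is None else t.compound_group]
            row += [t.per_genome_repeats.get(g, "") for g in genome_ids]
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
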