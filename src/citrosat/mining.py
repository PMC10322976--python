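"""Microsatellite (SSR) detection, motif normalization and tract-length classification.

Perfect SSRs are maximal uninterrupted runs of a 1-6 nt motif meeting a
per-motif-size minimum repeat count (defaults: mono 12, di 7, tri 5, tetra /
penta / hexa 4). Compound SSRs are chains of >= 2 perfect tracts separated by
at most ``d_max`` bases (default 100). Imperfect SSRs are found by a
seed-and-extend scan with a bounded cumulative mismatch fraction.

Tract-length classes for di- to hexanucleotide repeats:

* class III: tract < 20 nt (variable)
* class II:  20 <= tract <= 30 nt (possibly variable)
* class I:   tract > 30 nt (hypervariable); tracts >= 40 nt are additionally
  flagged *extremely variable* (the HvSSR set used for marker development)

Mononucleotide runs are left unclassified.

Conventions: coordinates are 1-based inclusive on the forward strand; a tract
covers whole motif copies only (a partial trailing copy is excluded, so
``tract_length == len(motif) * repeats`` for perfect loci); a tract whose motif
is itself a repetition of a shorter motif is reported once under the shortest
motif; N (or any non-ACGT base) terminates a tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from citrosat.genome import Genome, revcomp

SIZE_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

DEFAULT_MIN_REPEATS = {"mono": 12, "di": 7, "tri": 5, "tetra": 4, "penta": 4, "hexa": 4}

_ACGT = frozenset("ACGT")


@dataclass
class SSRLocus:
    """One detected repeat tract (perfect, imperfect or compound)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str
    canonical: str
    repeats: int
    ssr_type: str = "perfect"  # perfect | imperfect | compound
    ssr_class: str | None = None  # I | II | III | unclassified
    hypervariable: bool = False
    extremely_variable: bool = False
    members: list["SSRLocus"] = field(default_factory=list)
    mismatches: int = 0

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    @property
    def motif_size_class(self) -> str:
        return SIZE_CLASS_NAMES[len(self.motif)] if 1 <= len(self.motif) <= 6 else "compound"

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.motif)


def canonical_motif(motif: str) -> str:
    """Strand- and rotation-normalized representative of a motif family.

    The lexicographically smallest string among all cyclic rotations of the
    motif and of its reverse complement, so e.g. TA, AT -> AT and T -> A.
    Idempotent.
    """
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    if not set(motif) <= _ACGT:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    candidates = []
    for m in (motif, revcomp(motif)):
        candidates.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(candidates)


def _is_primitive(motif: str) -> bool:
    """True unless the motif is an integer power of a shorter unit."""
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def _normalize_min_repeats(min_repeats: dict | None) -> dict[int, int]:
    table = dict(DEFAULT_MIN_REPEATS)
    if min_repeats:
        for key, val in min_repeats.items():
            name = SIZE_CLASS_NAMES[key] if isinstance(key, int) else str(key)
            if name not in table:
                raise ValueError(f"unknown motif size class {key!r}")
            table[name] = int(val)
    return {k: table[name] for k, name in SIZE_CLASS_NAMES.items()}


def _validate_sequence(chrom: str, seq: str) -> None:
    bad = set(seq) - _ACGT - {"N"}
    if bad:
        raise ValueError(f"{chrom}: non-ACGTN characters {sorted(bad)}")


def find_perfect_ssrs(
    genome: Genome, min_repeats: dict | None = None
) -> list[SSRLocus]:
    """Detect maximal perfect SSR tracts in every chromosome.

    For each motif length k = 1..6 the scanner finds maximal stretches where
    ``seq[j] == seq[j - k]`` (period-k runs), reports the run under its length-k
    motif when that motif is primitive, and truncates the tract to whole motif
    copies. Runs below the per-size minimum repeat count are dropped.
    """
    if len(genome) == 0 or genome.total_length == 0:
        raise ValueError("empty genome")
    minrep = _normalize_min_repeats(min_repeats)
    loci: list[SSRLocus] = []
    for chrom, seq in genome.items():
        _validate_sequence(chrom, seq)
        n = len(seq)
        for k in range(1, 7):
            j = k
            while j < n:
                if seq[j] == seq[j - k] and seq[j] in _ACGT:
                    j0 = j
                    while j < n and seq[j] == seq[j - k] and seq[j] in _ACGT:
                        j += 1
                    a = j0 - k  # run interval [a, j-1], 0-based
                    run_len = j - a
                    reps = run_len // k
                    motif = seq[a : a + k]
                    if reps >= minrep[k] and _is_primitive(motif):
                        end = a + k * reps  # exclusive
                        loci.append(
                            SSRLocus(
                                chrom=chrom,
                                start=a + 1,
                                end=end,
                                motif=motif,
                                canonical=canonical_motif(motif),
                                repeats=reps,
                                ssr_type="perfect",
                            )
                        )
                else:
                    j += 1
    order = {c: i for i, c in enumerate(genome)}
    loci.sort(key=lambda l: (order[l.chrom], l.start, l.end, l.motif))
    return [classify_ssr(l) for l in loci]


def classify_ssr(locus: SSRLocus) -> SSRLocus:
    """Assign tract-length class and variability flags (in place; returns locus).

    Only di- to hexanucleotide simple repeats are classed; mononucleotides are
    'unclassified' and compound loci keep their members' classes.
    """
    t = locus.tract_length
    locus.hypervariable = t > 30
    locus.extremely_variable = t >= 40
    if locus.ssr_type == "compound":
        locus.ssr_class = None
        return locus
    if len(locus.motif) == 1:
        locus.ssr_class = "unclassified"
    elif t < 20:
        locus.ssr_class = "III"
    elif t <= 30:
        locus.ssr_class = "II"
    else:
        locus.ssr_class = "I"
    return locus


def find_compound_ssrs(loci: list[SSRLocus], d_max: int = 100) -> list[SSRLocus]:
    """Merge chains of >= 2 perfect loci separated by <= ``d_max`` bases.

    Input must be sorted by (chromosome, start); member loci are retained on
    the compound record. Perfect and compound totals are reported
    independently downstream (a member still counts as a perfect locus).
    """
    for prev, cur in zip(loci, loci[1:]):
        if prev.chrom == cur.chrom and prev.start > cur.start:
            raise ValueError("loci must be sorted by (chromosome, start)")
    compounds: list[SSRLocus] = []
    chain: list[SSRLocus] = []

    def flush(chain: list[SSRLocus]) -> None:
        if len(chain) >= 2:
            members = [replace(m, members=[]) for m in chain]
            comp = SSRLocus(
                chrom=chain[0].chrom,
                start=chain[0].start,
                end=max(m.end for m in chain),
                motif="-".join(m.motif for m in chain),
                canonical="-".join(m.canonical for m in chain),
                repeats=sum(m.repeats for m in chain),
                ssr_type="compound",
                members=members,
            )
            compounds.append(classify_ssr(comp))

    for locus in loci:
        if locus.ssr_type != "perfect":
            continue
        if chain and locus.chrom == chain[-1].chrom and (
            locus.start - max(m.end for m in chain) - 1 <= d_max
        ):
            chain.append(locus)
        else:
            flush(chain)
            chain = [locus]
    flush(chain)
    return compounds


DEFAULT_IMPERFECT_PARAMS = {
    "min_seed_repeats": 3,
    "max_mismatch_fraction": 0.1,
    "min_tract_nt": 12,
}


def find_imperfect_ssrs(genome: Genome, params: dict | None = None) -> list[SSRLocus]:
    """Seed-and-extend detection of imperfect SSR tracts.

    Seeds are perfect runs of >= ``min_seed_repeats`` motif copies. Each seed is
    extended greedily in both directions in motif phase; a mismatching position
    is accepted while the cumulative mismatch fraction over the extended tract
    stays <= ``max_mismatch_fraction``. Tracts are trimmed to end on matching
    positions, filtered at ``min_tract_nt``, and overlapping calls for the same
    canonical motif are merged (longest-tract representative). Perfect tracts
    are recovered with ``mismatches == 0``.
    """
    p = dict(DEFAULT_IMPERFECT_PARAMS)
    if params:
        p.update(params)
    f = float(p["max_mismatch_fraction"])
    if not (0 <= f < 0.5):
        raise ValueError("max_mismatch_fraction must lie in [0, 0.5)")
    min_seed = int(p["min_seed_repeats"])
    min_nt = int(p["min_tract_nt"])

    raw: list[SSRLocus] = []
    for chrom, seq in genome.items():
        _validate_sequence(chrom, seq)
        n = len(seq)
        for k in range(1, 7):
            j = k
            while j < n:
                if seq[j] == seq[j - k] and seq[j] in _ACGT:
                    j0 = j
                    while j < n and seq[j] == seq[j - k] and seq[j] in _ACGT:
                        j += 1
                    a = j0 - k
                    reps = (j - a) // k
                    motif = seq[a : a + k]
                    if reps >= min_seed and _is_primitive(motif):
                        raw.append(_extend_seed(chrom, seq, a, a + k * reps, motif, f))
                else:
                    j += 1

    calls = [
        c
        for c in raw
        if c is not None and c.tract_length >= min_nt
    ]
    # merge overlapping same-canonical calls: keep the longest representative
    calls.sort(key=lambda l: (l.chrom, l.canonical, l.start, -l.tract_length))
    merged: list[SSRLocus] = []
    for c in calls:
        last = merged[-1] if merged else None
        if (
            last is not None
            and last.chrom == c.chrom
            and last.canonical == c.canonical
            and c.start <= last.end
        ):
            if c.tract_length > last.tract_length:
                merged[-1] = c
        else:
            merged.append(c)
    order = {c: i for i, c in enumerate(genome)}
    merged.sort(key=lambda l: (order[l.chrom], l.start, l.end, l.motif))
    return [classify_ssr(l) for l in merged]


def _extend_seed(
    chrom: str, seq: str, a: int, b: int, motif: str, max_frac: float
) -> SSRLocus | None:
    """Greedy bidirectional phase extension of a perfect seed [a, b) (0-based)."""
    k = len(motif)
    n = len(seq)
    mism: set[int] = set()
    left, right = a, b  # current tract [left, right)

    j = b
    while j < n and seq[j] in _ACGT:
        expected = motif[(j - a) % k]
        if seq[j] == expected:
            right = j + 1
        else:
            if (len(mism) + 1) / (j - left + 1) <= max_frac:
                mism.add(j)
                right = j + 1
            else:
                break
        j += 1
    j = a - 1
    while j >= 0 and seq[j] in _ACGT:
        expected = motif[(j - a) % k]
        if seq[j] == expected:
            left = j
        else:
            if (len(mism) + 1) / (right - j) <= max_frac:
                mism.add(j)
                left = j
            else:
                break
        j -= 1
    # trim to matching ends
    while left in mism:
        mism.discard(left)
        left += 1
    while (right - 1) in mism:
        mism.discard(right - 1)
        right -= 1
    if right <= left:
        return None
    return SSRLocus(
        chrom=chrom,
        start=left + 1,
        end=right,
        motif=motif,
        canonical=canonical_motif(motif),
        repeats=round((right - left) / k),
        ssr_type="imperfect",
        mismatches=len(mism),
    )


@dataclass
class SSRSummary:
    """Abundance / density summary of a locus set over a genome."""

    total_count: int
    total_length_bp: int
    genome_bp: int
    relative_abundance: float  # loci / Mb
    relative_density: float  # bp / Mb
    average_length: float
    by_size_class: pd.DataFrame  # count, length_bp, percent, average_length, abundance, density
    by_chromosome: pd.DataFrame


def relative_abundance(count: int, genome_bp: int) -> float:
    """Loci per Mb of examined sequence."""
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    return count / (genome_bp / 1e6)


def relative_density(total_length_bp: int, genome_bp: int) -> float:
    """Summed tract bp per Mb of examined sequence."""
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    return total_length_bp / (genome_bp / 1e6)


def summarize(loci: list[SSRLocus], genome: Genome) -> SSRSummary:
    """Count / length / abundance / density totals, by motif size class and chromosome."""
    genome_bp = genome.total_length
    if genome_bp == 0:
        raise ValueError("empty genome")
    total = len(loci)
    total_len = sum(l.tract_length for l in loci)

    class_rows = []
    for k in range(1, 7):
        name = SIZE_CLASS_NAMES[k]
        sub = [l for l in loci if len(l.motif) == k and l.ssr_type != "compound"]
        cnt = len(sub)
        ln = sum(l.tract_length for l in sub)
        class_rows.append(
            {
                "size_class": name,
                "count": cnt,
                "length_bp": ln,
                "percent": (100.0 * cnt / total) if total else 0.0,
                "average_length": (ln / cnt) if cnt else 0.0,
                "abundance": relative_abundance(cnt, genome_bp),
                "density": relative_density(ln, genome_bp),
            }
        )
    by_class = pd.DataFrame(class_rows).set_index("size_class")

    chrom_rows = []
    for chrom in genome:
        sub = [l for l in loci if l.chrom == chrom]
        cnt = len(sub)
        ln = sum(l.tract_length for l in sub)
        cbp = len(genome[chrom])
        chrom_rows.append(
            {
                "chromosome": chrom,
                "length_bp": cbp,
                "count": cnt,
                "ssr_length_bp": ln,
                "abundance": relative_abundance(cnt, cbp) if cbp else 0.0,
                "density": relative_density(ln, cbp) if cbp else 0.0,
            }
        )
    by_chrom = pd.DataFrame(chrom_rows).set_index("chromosome")

    return SSRSummary(
        total_count=total,
        total_length_bp=total_len,
        genome_bp=genome_bp,
        relative_abundance=relative_abundance(total, genome_bp),
        relative_density=relative_density(total_len, genome_bp),
        average_length=(total_len / total) if total else 0.0,
        by_size_class=by_class,
        by_chromosome=by_chrom,
    )
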