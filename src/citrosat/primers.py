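"""Flanking-primer design for SSR loci.

Candidate primers are enumerated exhaustively over all windows in the two
flanks of a locus, filtered by hard constraints (length 18-20 nt, GC 40-70%,
Tm 52-60 degC, product 100-400 bp containing the full tract, no >= 8 bp perfect
self-complement, primer unique within the amplicon region) and ranked by a
penalty reflecting the declared optima (19 nt, 55 degC, product mid-window
250 bp):

    penalty = |Tm_f - 55| + |Tm_r - 55| + |len_f - 19| + |len_r - 19|
              + |product - 250| / 100

Ties break by leftmost forward start, then lexicographic forward sequence.

Tm is computed either by the Wallace rule (2*(A+T) + 4*(G+C); exact integer
arithmetic, handy for tests) or by the unified nearest-neighbor thermodynamic
model (default; Biopython's Tm_NN with 50 mM monovalent salt and 250 nM
primer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from citrosat.genome import Genome, revcomp
from citrosat.mining import SSRLocus

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 18
    max_length: int = 20
    opt_length: int = 19
    min_gc: float = 40.0
    max_gc: float = 70.0
    min_tm: float = 52.0
    max_tm: float = 60.0
    opt_tm: float = 55.0
    min_product: int = 100
    max_product: int = 400
    opt_product: int = 250
    flank_width: int = 400  # how far from the tract to search
    tm_method: str = "nearest_neighbor"
    self_dimer_len: int = 8  # reject >= this many bp of perfect self-complement


@dataclass
class PrimerPair:
    """A designed forward/reverse primer pair for one SSR locus."""

    id: str
    locus_ref: str
    chrom: str
    forward_seq: str
    reverse_seq: str  # 5'->3' on the reverse strand
    forward_tm: float
    reverse_tm: float
    forward_gc: float
    reverse_gc: float
    expected_product_bp: int
    forward_start: int  # 1-based, 5' end of forward primer
    reverse_end: int  # 1-based, 5' end of reverse primer on the forward strand
    penalty: float = 0.0


def gc_content(seq: str) -> float:
    """GC percentage of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if not set(seq) <= _ACGT:
        raise ValueError("sequence contains non-ACGT characters")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def tm(
    seq: str,
    method: str = "nearest_neighbor",
    conditions: dict | None = None,
) -> float:
    """Melting temperature in degC.

    ``wallace`` is the rule of thumb 2*(A+T) + 4*(G+C); ``nearest_neighbor``
    is the unified NN thermodynamic estimate with salt correction
    (conditions: Na_mM, default 50; primer_nM, default 250).
    """
    seq = seq.upper()
    if not set(seq) <= _ACGT:
        raise ValueError("sequence contains non-ACGT characters")
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    cond = {"Na_mM": 50.0, "primer_nM": 250.0}
    if conditions:
        cond.update(conditions)
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gcn = seq.count("G") + seq.count("C")
        return 2.0 * at + 4.0 * gcn
    if method == "nearest_neighbor":
        return float(
            _mt.Tm_NN(seq, Na=cond["Na_mM"], dnac1=cond["primer_nM"], dnac2=0)
        )
    raise ValueError(f"unknown Tm method {method!r}")


def has_self_dimer(seq: str, min_len: int = 8) -> bool:
    """True if the primer contains a perfect self-complementary stretch.

    Checked as: some ``min_len``-mer of the primer whose reverse complement
    also occurs in the primer (enables self-annealing / hairpins).
    """
    if len(seq) < min_len:
        return False
    kmers = {seq[i : i + min_len] for i in range(len(seq) - min_len + 1)}
    return any(revcomp(w) in kmers for w in kmers)


def _count_occurrences(hay: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = hay.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def _unique_in_region(region: str, primer: str) -> bool:
    """Primer binds exactly one site (either strand) within the region."""
    return _count_occurrences(region, primer) + _count_occurrences(
        region, revcomp(primer)
    ) == 1


def design_primers(
    locus: SSRLocus,
    genome: Genome,
    constraints: PrimerConstraints | None = None,
    k: int = 1,
    id_prefix: str = "SSR",
) -> list[PrimerPair]:
    """Design up to ``k`` best primer pairs flanking an SSR locus.

    Returns an empty list (not an error) when no window combination satisfies
    the constraints. The amplicon always contains the full repeat tract; the
    product size is measured 5' end of the forward primer to 5' end of the
    reverse primer, inclusive.
    """
    c = constraints or PrimerConstraints()
    if locus.chrom not in genome:
        raise ValueError(f"locus chromosome {locus.chrom!r} not in genome")
    seq = genome[locus.chrom]
    if locus.end > len(seq) or locus.start < 1:
        raise ValueError("locus coordinates outside chromosome")

    ts0, te0 = locus.start - 1, locus.end - 1  # 0-based tract bounds

    def window_ok(w: str) -> tuple[float, float] | None:
        if not set(w) <= _ACGT:
            return None
        g = gc_content(w)
        if not c.min_gc <= g <= c.max_gc:
            return None
        t = tm(w, method=c.tm_method)
        if not c.min_tm <= t <= c.max_tm:
            return None
        return g, t

    # forward candidates: windows ending before the tract start
    forwards = []  # (start0, length, seq, gc, tm)
    lo = max(0, ts0 - c.flank_width)
    for f0 in range(lo, ts0):
        for L in range(c.min_length, c.max_length + 1):
            if f0 + L > ts0:
                break
            w = seq[f0 : f0 + L]
            ok = window_ok(w)
            if ok:
                forwards.append((f0, L, w, *ok))

    # reverse candidates: windows starting after the tract end
    reverses = []  # (start0, length, seq(revcomp), gc, tm)
    hi = min(len(seq), te0 + 1 + c.flank_width)
    for r0 in range(te0 + 1, hi):
        for L in range(c.min_length, c.max_length + 1):
            if r0 + L > hi:
                break
            w = revcomp(seq[r0 : r0 + L])
            ok = window_ok(w)
            if ok:
                reverses.append((r0, L, w, *ok))

    candidates = []
    for f0, Lf, fseq, fgc, ftm in forwards:
        for r0, Lr, rseq, rgc, rtm in reverses:
            r_end0 = r0 + Lr - 1  # 0-based 5' end of reverse primer
            product = r_end0 - f0 + 1
            if not c.min_product <= product <= c.max_product:
                continue
            penalty = (
                abs(ftm - c.opt_tm)
                + abs(rtm - c.opt_tm)
                + abs(Lf - c.opt_length)
                + abs(Lr - c.opt_length)
                + abs(product - c.opt_product) / 100.0
            )
            candidates.append(
                (penalty, f0, fseq, Lf, fgc, ftm, r0, Lr, rseq, rgc, rtm,
                 r_end0, product)
            )
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    chosen: list[PrimerPair] = []
    for (penalty, f0, fseq, Lf, fgc, ftm, r0, Lr, rseq, rgc, rtm,
         r_end0, product) in candidates:
        if len(chosen) >= k:
            break
        if has_self_dimer(fseq, c.self_dimer_len) or has_self_dimer(rseq, c.self_dimer_len):
            continue
        region = seq[f0 : r_end0 + 1]
        if not (_unique_in_region(region, fseq) and _unique_in_region(region, rseq)):
            continue
        chosen.append(
            PrimerPair(
                id=f"{id_prefix}_{locus.chrom}_{locus.start}_{len(chosen) + 1}",
                locus_ref=locus.id,
                chrom=locus.chrom,
                forward_seq=fseq,
                reverse_seq=rseq,
                forward_tm=ftm,
                reverse_tm=rtm,
                forward_gc=fgc,
                reverse_gc=rgc,
                expected_product_bp=product,
                forward_start=f0 + 1,
                reverse_end=r_end0 + 1,
                penalty=penalty,
            )
        )
    return chosen
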