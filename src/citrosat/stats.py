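"""Per-locus marker diversity statistics from allele matrices.

Statistics follow the GenAlEx conventions for codominant SSR data. With pi the
frequency of the i-th allele at a locus (counted over the 2N allele
observations of the N genotyped diploid individuals):

* Na  — number of different alleles
* MAF — major (most frequent) allele frequency
* Ne  — effective number of alleles, 1 / sum(pi^2)
* I   — Shannon's information index, -sum(pi * ln pi)
* Ho  — observed heterozygosity, (number of heterozygotes) / N
* He  — expected heterozygosity, 1 - sum(pi^2)
* uHe — unbiased expected heterozygosity, (2N / (2N - 1)) * He
* PIC — polymorphic information content (Botstein et al. 1980):
  1 - sum(pi^2) - sum_{i<j} 2 pi^2 pj^2

Binary (dominant, band presence/absence) data are scored per band as a
biallelic locus with the null-allele frequency estimated as
q = sqrt(frequency of the absence phenotype); Ho is undefined (NaN) in binary
mode. Missing genotypes are dropped locus-wise (pairwise deletion), so N
varies by locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "NA"


class AlleleMatrix:
    """Loci x individuals genotype table.

    In codominant mode a genotype is an unordered pair of allele labels
    (typically fragment sizes in bp) or None for missing. In binary mode a
    genotype is 0/1 band presence or None.
    """

    def __init__(
        self,
        loci: list[str],
        individuals: list[str],
        genotypes: dict,
        mode: str = "codominant",
    ):
        if mode not in ("codominant", "binary"):
            raise ValueError(f"unknown mode {mode!r}")
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.mode = mode
        self.genotypes = {}
        for (locus, ind), g in genotypes.items():
            if g is None:
                self.genotypes[(locus, ind)] = None
            elif mode == "codominant":
                a, b = g
                self.genotypes[(locus, ind)] = (a, b)
            else:
                if g not in (0, 1):
                    raise ValueError(f"binary genotype must be 0/1, got {g!r}")
                self.genotypes[(locus, ind)] = int(g)

    def genotype(self, locus: str, individual: str):
        return self.genotypes.get((locus, individual))

    def non_missing(self, locus: str) -> list:
        out = []
        for ind in self.individuals:
            g = self.genotypes.get((locus, ind))
            if g is not None:
                out.append(g)
        return out

    def allele_frequencies(self, locus: str) -> dict:
        """Allele label -> frequency pi at one locus (codominant mode)."""
        if self.mode != "codominant":
            raise ValueError("allele_frequencies is defined for codominant matrices")
        counts: dict = {}
        for a, b in self.non_missing(locus):
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {locus!r} has no scored genotypes")
        return {k: v / total for k, v in counts.items()}

    # ---- I/O: rows = loci; codominant = two columns per individual ----

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if self.mode == "codominant":
                header = ["locus"]
                for ind in self.individuals:
                    header += [f"{ind}.1", f"{ind}.2"]
                fh.write("\t".join(header) + "\n")
                for locus in self.loci:
                    row = [locus]
                    for ind in self.individuals:
                        g = self.genotypes.get((locus, ind))
                        row += [MISSING, MISSING] if g is None else [str(g[0]), str(g[1])]
                    fh.write("\t".join(row) + "\n")
            else:
                fh.write("\t".join(["locus"] + self.individuals) + "\n")
                for locus in self.loci:
                    row = [locus]
                    for ind in self.individuals:
                        g = self.genotypes.get((locus, ind))
                        row.append(MISSING if g is None else str(g))
                    fh.write("\t".join(row) + "\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "codominant") -> "AlleleMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).set_index("locus")
        loci = list(df.index)
        genotypes: dict = {}
        if mode == "codominant":
            individuals = list(dict.fromkeys(c.rsplit(".", 1)[0] for c in df.columns))
            for locus in loci:
                for ind in individuals:
                    a, b = df.loc[locus, f"{ind}.1"], df.loc[locus, f"{ind}.2"]
                    if a == MISSING or b == MISSING:
                        genotypes[(locus, ind)] = None
                    else:
                        genotypes[(locus, ind)] = (_maybe_num(a), _maybe_num(b))
        else:
            individuals = list(df.columns)
            for locus in loci:
                for ind in individuals:
                    v = df.loc[locus, ind]
                    genotypes[(locus, ind)] = None if v == MISSING else int(v)
        return cls(loci, individuals, genotypes, mode=mode)


def _maybe_num(s: str):
    try:
        f = float(s)
        return int(f) if f == int(f) else f
    except ValueError:
        return s


@dataclass
class LocusStats:
    locus: str
    N: int
    Na: int
    MAF: float
    Ne: float
    I: float
    Ho: float
    He: float
    uHe: float
    PIC: float


def pic_botstein(freqs) -> float:
    """Botstein et al. polymorphic information content for a frequency vector."""
    p = np.asarray(list(freqs), dtype=float)
    sum_p2 = float(np.sum(p**2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - sum_p2 - cross


def _stats_from_freqs(locus: str, freqs: dict, n: int, ho: float) -> LocusStats:
    p = np.array(list(freqs.values()), dtype=float)
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    ne = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p))))
    uhe = (2 * n / (2 * n - 1)) * he if n > 0 and 2 * n > 1 else he
    return LocusStats(
        locus=locus,
        N=n,
        Na=len(p),
        MAF=float(np.max(p)),
        Ne=ne,
        I=shannon,
        Ho=ho,
        He=he,
        uHe=uhe,
        PIC=pic_botstein(p),
    )


def locus_stats(matrix: AlleleMatrix, locus: str) -> LocusStats:
    """All diversity statistics for one locus (pairwise deletion of missing)."""
    obs = matrix.non_missing(locus)
    if not obs:
        raise ValueError(f"locus {locus!r} has no scored genotypes")
    n = len(obs)
    if matrix.mode == "codominant":
        freqs = matrix.allele_frequencies(locus)
        hets = sum(1 for a, b in obs if a != b)
        return _stats_from_freqs(locus, freqs, n, hets / n)
    # binary (dominant) mode: q = sqrt(absence phenotype frequency)
    absent = sum(1 for g in obs if g == 0)
    q = math.sqrt(absent / n)
    p = 1.0 - q
    if p == 0.0 or q == 0.0:
        freqs = {"band": 1.0}
    else:
        freqs = {"present": p, "absent": q}
    return _stats_from_freqs(locus, freqs, n, float("nan"))


def stats_table(matrix: AlleleMatrix) -> pd.DataFrame:
    """Per-locus statistics for every locus, as a DataFrame."""
    rows = [vars(locus_stats(matrix, locus)) for locus in matrix.loci]
    return pd.DataFrame(rows).set_index("locus")


def group_stats(matrix: AlleleMatrix, grouping: dict) -> pd.DataFrame:
    """Arithmetic means of all per-locus statistics within groups.

    ``grouping`` maps locus id -> group label (e.g. chromosome). Adds TP
    (total primers/loci in the group) and TPP (polymorphic, Na >= 2). Empty
    groups are omitted with a warning.
    """
    missing = [l for l in matrix.loci if l not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover loci: {missing[:5]}")
    per_locus = stats_table(matrix)
    per_locus["group"] = [grouping[l] for l in per_locus.index]
    rows = []
    for group, sub in per_locus.groupby("group", sort=True):
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"group {group!r} is empty; omitted")
            continue
        row = {"group": group, "TP": len(sub), "TPP": int((sub["Na"] >= 2).sum())}
        for col in ["N", "Na", "MAF", "Ne", "I", "Ho", "He", "uHe", "PIC"]:
            row[col] = float(sub[col].mean())
        rows.append(row)
    empty = set(grouping.values()) - {r["group"] for r in rows}
    for g in sorted(empty):
        warnings.warn(f"group {g!r} is empty; omitted")
    return pd.DataFrame(rows).set_index("group")


def binary_score(band_table: pd.DataFrame) -> AlleleMatrix:
    """Convert a band presence/absence table (rows = bands, cols = samples)
    into a binary-mode AlleleMatrix. Entries must be 0, 1 or missing (NaN/"NA").
    """
    loci = [str(i) for i in band_table.index]
    individuals = [str(c) for c in band_table.columns]
    genotypes: dict = {}
    for locus, (_, row) in zip(loci, band_table.iterrows()):
        for ind, v in zip(individuals, row):
            if pd.isna(v) or v == MISSING:
                genotypes[(locus, ind)] = None
                continue
            iv = float(v)
            if iv not in (0.0, 1.0):
                raise ValueError(f"non-binary band entry {v!r} at ({locus}, {ind})")
            genotypes[(locus, ind)] = int(iv)
    return AlleleMatrix(loci, individuals, genotypes, mode="binary")
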