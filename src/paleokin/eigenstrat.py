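"""EIGENSTRAT genotype I/O and pseudo-haploid conversion.

Supports the ASCII EIGENSTRAT dialect only: one geno row per SNP, one digit
per individual, 9 = missing. Genotypes are stored as alt-allele dosages
(0/1/2 diploid; 0/1 pseudo-haploid) in an individuals x SNPs int8 array with
``MISSING`` (-1) for no-calls. The .snp file's genetic-position column is
interpreted as Morgans (standard EIGENSTRAT); internal ROH lengths elsewhere
in the package are centimorgans, converted from these positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

PSEUDO_HAPLOID = "pseudo_haploid"
DIPLOID = "diploid"


class EigenstratFormatError(ValueError):
    """Malformed EIGENSTRAT input (dimension mismatch or bad characters)."""


@dataclass(frozen=True)
class SNPRecord:
    snp_id: str
    chromosome: str
    genetic_pos: float  # Morgans
    physical_pos: int  # 1-based bp
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.genetic_pos < 0:
            raise ValueError(f"{self.snp_id}: negative genetic position")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are equal")


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    declared_sex: str = "U"  # M, F or U
    group_label: str = "Unknown"


class GenotypeMatrix:
    """Cohort genotypes at a fixed SNP panel.

    calls[i, s] is the alt-allele dosage of individual i at SNP s, or MISSING.
    """

    def __init__(self, individuals, snps, calls, ploidy_mode=PSEUDO_HAPLOID):
        self.individuals = list(individuals)
        self.snps = list(snps)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.ploidy_mode = ploidy_mode
        self.validate()

    def validate(self) -> None:
        n_ind, n_snp = len(self.individuals), len(self.snps)
        if self.calls.shape != (n_ind, n_snp):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n_ind}, {n_snp})"
            )
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        if self.ploidy_mode not in (PSEUDO_HAPLOID, DIPLOID):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        hi = 1 if self.ploidy_mode == PSEUDO_HAPLOID else 2
        bad = (self.calls != MISSING) & ((self.calls < 0) | (self.calls > hi))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} calls outside {{0..{hi}, MISSING}} for "
                f"{self.ploidy_mode} data"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def individual_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    def genetic_positions(self) -> np.ndarray:
        """Genetic positions in Morgans, one per SNP."""
        return np.array([s.genetic_pos for s in self.snps], dtype=float)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.snps == other.snps
            and self.ploidy_mode == other.ploidy_mode
            and np.array_equal(self.calls, other.calls)
        )


def _norm_chrom(raw: str) -> str:
    c = str(raw)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("23", "X"):
        return "X" if c == "X" else c
    return c


def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read ASCII EIGENSTRAT triplet into a GenotypeMatrix.

    Geno digit 9 maps to MISSING; 0/1/2 are alt-allele dosages. The matrix is
    flagged pseudo-haploid when no call of 2 occurs, diploid otherwise.
    """
    geno_path, snp_path, ind_path = Path(geno_path), Path(snp_path), Path(ind_path)
    for p in (geno_path, snp_path, ind_path):
        if not p.exists():
            raise FileNotFoundError(p)

    ind_df = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["id", "sex", "group"], dtype=str
    )
    individuals = [
        IndividualRecord(row.id, row.sex if row.sex in ("M", "F") else "U", row.group)
        for row in ind_df.itertuples()
    ]

    snp_df = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["snp_id", "chrom", "gpos", "ppos", "ref", "alt"],
        dtype={"snp_id": str, "chrom": str},
        float_precision="round_trip",
    )
    snps = [
        SNPRecord(
            r.snp_id, _norm_chrom(r.chrom), float(r.gpos), int(r.ppos),
            str(r.ref), str(r.alt),
        )
        for r in snp_df.itertuples()
    ]

    n_ind, n_snp = len(individuals), len(snps)
    lut = np.full(256, -2, dtype=np.int8)
    for ch, v in (("0", 0), ("1", 1), ("2", 2), ("9", MISSING)):
        lut[ord(ch)] = v
    calls = np.empty((n_ind, n_snp), dtype=np.int8)
    with open(geno_path, "rb") as fh:
        row = -1
        for row, line in enumerate(fh):
            line = line.strip()
            if row >= n_snp:
                raise EigenstratFormatError(
                    f"{geno_path}: more geno rows than SNPs ({n_snp})"
                )
            if len(line) != n_ind:
                raise EigenstratFormatError(
                    f"{geno_path} row {row + 1}: width {len(line)} != "
                    f"{n_ind} individuals"
                )
            vals = lut[np.frombuffer(line, dtype=np.uint8)]
            if (vals == -2).any():
                bad = chr(line[int(np.argmax(vals == -2))])
                raise EigenstratFormatError(
                    f"{geno_path} row {row + 1}: non-genotype character {bad!r}"
                )
            calls[:, row] = vals
    if row + 1 != n_snp:
        raise EigenstratFormatError(
            f"{geno_path}: {row + 1} geno rows != {n_snp} SNPs"
        )

    mode = DIPLOID if (calls == 2).any() else PSEUDO_HAPLOID
    return GenotypeMatrix(individuals, snps, calls, ploidy_mode=mode)


def write_eigenstrat(matrix: GenotypeMatrix, geno_path, snp_path, ind_path):
    """Write an ASCII EIGENSTRAT triplet; round-trips through read_eigenstrat."""
    if matrix.n_individuals == 0:
        raise ValueError("cannot write a matrix with no individuals")
    geno_path, snp_path, ind_path = Path(geno_path), Path(snp_path), Path(ind_path)

    digits = np.where(matrix.calls == MISSING, 9, matrix.calls).astype(np.uint8)
    chars = digits + ord("0")
    with open(geno_path, "wb") as fh:
        for s in range(matrix.n_snps):
            fh.write(chars[:, s].tobytes())
            fh.write(b"\n")

    with open(snp_path, "w") as fh:
        for s in matrix.snps:
            fh.write(
                f"{s.snp_id}\t{s.chromosome}\t{s.genetic_pos:.17g}\t"
                f"{s.physical_pos}\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for ind in matrix.individuals:
            fh.write(f"{ind.individual_id}\t{ind.declared_sex}\t{ind.group_label}\n")
    return geno_path, snp_path, ind_path


def pseudo_haploidize(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Randomly sample one allele per individual per SNP.

    Homozygotes map deterministically (0->0, 2->1); heterozygotes go to 0 or 1
    with probability 1/2 each under the given seed. The standard reduction for
    low-coverage ancient DNA, where confident diploid calls are unavailable.
    """
    if matrix.ploidy_mode != DIPLOID:
        raise ValueError("matrix is already pseudo-haploid")
    rng = np.random.default_rng(seed)
    calls = matrix.calls
    out = np.where(calls == 2, 1, calls).astype(np.int8)
    het = calls == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    out[calls == MISSING] = MISSING
    return GenotypeMatrix(
        matrix.individuals, matrix.snps, out, ploidy_mode=PSEUDO_HAPLOID
    )


def snp_coverage(matrix: GenotypeMatrix) -> pd.Series:
    """Number of non-missing calls per individual."""
    counts = (matrix.calls != MISSING).sum(axis=1)
    return pd.Series(counts, index=matrix.individual_ids, name="n_snps_covered")
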