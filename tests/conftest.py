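"""Shared fixtures: small genotype matrices and a reduced genetic map."""

import numpy as np
import pytest

from paleokin.eigenstrat import (
    DIPLOID,
    MISSING,
    PSEUDO_HAPLOID,
    GenotypeMatrix,
    IndividualRecord,
    SNPRecord,
)

# small two-chromosome map (cM) so unit tests don't need the full genome
SMALL_GMAP = {"1": 100.0, "2": 50.0}


def make_matrix(calls, ploidy=PSEUDO_HAPLOID, gmap=None, ids=None):
    """Build a GenotypeMatrix from a 2-D array with evenly spaced SNPs."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snp = calls.shape
    gmap = gmap or SMALL_GMAP
    chroms = list(gmap)
    per = [n_snp // len(chroms)] * len(chroms)
    per[0] += n_snp - sum(per)
    snps = []
    for chrom, n_c in zip(chroms, per):
        for i in range(n_c):
            pos_cm = (i + 0.5) / n_c * gmap[chrom]
            snps.append(
                SNPRecord(f"s{chrom}_{i}", chrom, pos_cm / 100.0,
                          int(pos_cm * 1e6) + 1, "A", "G")
            )
    ids = ids or [f"ind{i}" for i in range(n_ind)]
    individuals = [IndividualRecord(i, "U", "Test") for i in ids]
    return GenotypeMatrix(individuals, snps, calls, ploidy_mode=ploidy)


@pytest.fixture
def tiny_pseudo_haploid():
    """Five SNPs, two individuals, one missing call each side."""
    calls = np.array(
        [[0, 1, 0, 1, MISSING],
         [0, 1, 1, 1, 0]], dtype=np.int8
    )
    return make_matrix(calls)


@pytest.fixture
def tiny_diploid():
    calls = np.array(
        [[0, 1, 2, 1, MISSING],
         [2, 1, 0, 0, 2]], dtype=np.int8
    )
    return make_matrix(calls, ploidy=DIPLOID)
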