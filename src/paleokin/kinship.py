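"""Pairwise kinship from pseudo-haploid mismatch rates.

For two individuals whose calls are single randomly sampled alleles, the
probability that overlapping calls differ is (1 - phi) * base, where phi is
the kinship coefficient and base the expected mismatch rate of two unrelated
individuals from the same population. With b = base / 2 the relatedness
coefficient

    r = 1 - ((x - b) / b) = 2 - x / b

has expectation 2*phi: 1 for duplicates/identical twins, 0.5 first degree,
0.25 second, 0.125 third, 0 for unrelated pairs. The baseline is calibrated
as the median pairwise mismatch rate among well-covered individuals
(> 100,000 SNPs by default), assuming most pairs are unrelated.

Standard errors are delete-one block jackknives over contiguous genetic-map
blocks (5 cM default), robust to linkage. Degree windows default to midpoints
of the expected r values on a halving scale and are configurable; estimates
within 2 SE of a window boundary are flagged "unresolved" rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eigenstrat import MISSING, PSEUDO_HAPLOID, GenotypeMatrix
from .genmap import map_blocks

DEFAULT_MIN_BASELINE_SNPS = 100_000
DEFAULT_MIN_PAIR_OVERLAP = 15_000

#: degree -> [low, high) window on r; midpoints of {1, 1/2, 1/4, 1/8, 0}
DEFAULT_DEGREE_WINDOWS: dict[str, tuple[float, float]] = {
    "identical": (0.7, np.inf),
    "first": (0.35, 0.7),
    "second": (0.1875, 0.35),
    "third": (0.09375, 0.1875),
    "unrelated": (-np.inf, 0.09375),
}

CLOSE_DEGREES = ("identical", "first", "second", "third")


@dataclass(frozen=True)
class BaselineCalibration:
    """Unrelated-pair mismatch baseline and its half, b."""

    base: float
    b: float
    qualifying_ids: tuple[str, ...]
    min_snps: int


@dataclass
class KinshipConfig:
    seed: int
    min_baseline_snps: int = DEFAULT_MIN_BASELINE_SNPS
    min_pair_overlap: int = DEFAULT_MIN_PAIR_OVERLAP
    block_cm: float = 5.0
    degree_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DEGREE_WINDOWS)
    )


def _pair_block_counts(matrix: GenotypeMatrix, block_cm: float):
    """Blockwise mismatch and overlap counts for every pair, via BLAS.

    For 0/1 calls with mask m, pairwise mismatches are B C^T + C B^T with
    B = m*a and C = m*(1-a); overlap is M M^T. Returns (mism, ovl) of shape
    (n_blocks, n_ind, n_ind) plus the block ids.
    """
    calls = matrix.calls
    mask = (calls != MISSING).astype(np.float32)
    a = np.where(calls == MISSING, 0, calls).astype(np.float32)
    blocks = map_blocks(matrix.chromosomes(), matrix.genetic_positions(), block_cm)
    n_blocks = int(blocks.max()) + 1 if len(blocks) else 0
    n = matrix.n_individuals
    mism = np.empty((n_blocks, n, n), dtype=np.float64)
    ovl = np.empty((n_blocks, n, n), dtype=np.float64)
    # blocks are contiguous runs after map sorting; use slices where possible
    order = np.argsort(blocks, kind="stable")
    a, mask, blocks_sorted = a[:, order], mask[:, order], blocks[order]
    starts = np.searchsorted(blocks_sorted, np.arange(n_blocks))
    ends = np.append(starts[1:], len(blocks_sorted))
    for bidx in range(n_blocks):
        sl = slice(starts[bidx], ends[bidx])
        B = mask[:, sl] * a[:, sl]
        C = mask[:, sl] - B
        mism[bidx] = (B @ C.T + C @ B.T).astype(np.float64)
        ovl[bidx] = (mask[:, sl] @ mask[:, sl].T).astype(np.float64)
    return mism, ovl


def pairwise_mismatch(
    matrix: GenotypeMatrix, min_overlap: int = 0, block_cm: float = 5.0
) -> pd.DataFrame:
    """Mismatch rate x for every unordered pair with enough overlap.

    Returns a frame with columns id_a, id_b, overlap_snps, mismatches, x;
    block-level counts are stashed in ``attrs`` for jackknife reuse.
    """
    if matrix.ploidy_mode != PSEUDO_HAPLOID:
        raise ValueError("pairwise mismatch requires pseudo-haploid calls")
    if matrix.n_individuals < 2:
        raise ValueError("need at least two individuals")
    mism_b, ovl_b = _pair_block_counts(matrix, block_cm)
    mism, ovl = mism_b.sum(axis=0), ovl_b.sum(axis=0)
    ids = matrix.individual_ids
    ia, ib = np.triu_indices(matrix.n_individuals, k=1)
    keep = ovl[ia, ib] >= min_overlap
    ia, ib = ia[keep], ib[keep]
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(ovl[ia, ib] > 0, mism[ia, ib] / ovl[ia, ib], np.nan)
    out = pd.DataFrame(
        {
            "id_a": [ids[i] for i in ia],
            "id_b": [ids[i] for i in ib],
            "overlap_snps": ovl[ia, ib].astype(np.int64),
            "mismatches": mism[ia, ib].astype(np.int64),
            "x": x,
        }
    )
    out.attrs["block_mismatches"] = mism_b
    out.attrs["block_overlap"] = ovl_b
    out.attrs["pair_index"] = (ia, ib)
    return out


def calibrate_baseline(
    mismatches: pd.DataFrame,
    coverage: pd.Series,
    min_snps: int = DEFAULT_MIN_BASELINE_SNPS,
) -> BaselineCalibration:
    """Median pairwise mismatch among individuals with > min_snps calls.

    Assumes most pairs in the cohort are unrelated, so the median is a robust
    estimate of the unrelated mismatch rate even with some close kin present.
    """
    qualifying = set(coverage.index[coverage > min_snps])
    sel = mismatches["id_a"].isin(qualifying) & mismatches["id_b"].isin(qualifying)
    rates = mismatches.loc[sel, "x"].dropna()
    if rates.empty:
        raise ValueError(
            f"no pair with both individuals above {min_snps} covered SNPs"
        )
    base = float(rates.median())
    return BaselineCalibration(
        base=base, b=base / 2.0, qualifying_ids=tuple(sorted(qualifying)),
        min_snps=min_snps,
    )


def relatedness(x: float, calibration: BaselineCalibration) -> float:
    """r = 1 - ((x - b)/b); not clamped, sampling noise may exceed [0, 1]."""
    if calibration.b == 0:
        raise ValueError("baseline b is zero; cannot scale mismatch rates")
    return 1.0 - ((x - calibration.b) / calibration.b)


def classify_degree(
    r: float,
    se_r: float,
    windows: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Map r into a relationship-degree window; flag boundary cases.

    Returns "unresolved" when r lies within 2*se_r of a window boundary,
    since pseudo-haploid noise makes the class assignment unreliable there.
    """
    if windows is None:
        windows = DEFAULT_DEGREE_WINDOWS
    _validate_windows(windows)
    if se_r < 0 or not np.isfinite(r):
        raise ValueError("invalid r or se_r")
    boundaries = sorted(
        {lo for lo, _ in windows.values() if np.isfinite(lo)}
        | {hi for _, hi in windows.values() if np.isfinite(hi)}
    )
    for bnd in boundaries:
        if abs(r - bnd) < 2 * se_r:
            return "unresolved"
    for degree, (lo, hi) in windows.items():
        if lo <= r < hi:
            return degree
    return "unresolved"


def _validate_windows(windows: dict[str, tuple[float, float]]) -> None:
    intervals = sorted(windows.values())
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        if hi1 > lo2:
            raise ValueError("degree windows overlap")
        if hi1 < lo2:
            raise ValueError("degree windows leave a gap")


def _jackknife_r(mism_b, ovl_b, ia, ib, b_half) -> np.ndarray:
    """Delete-one-block jackknife SE of r for the selected pairs."""
    tot_m = mism_b.sum(axis=0)[ia, ib]
    tot_o = ovl_b.sum(axis=0)[ia, ib]
    se = np.zeros(len(ia))
    n_blocks = mism_b.shape[0]
    if n_blocks < 2:
        return np.full(len(ia), np.nan)
    loo_m = tot_m[None, :] - mism_b[:, ia, ib]
    loo_o = tot_o[None, :] - ovl_b[:, ia, ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        loo_x = loo_m / loo_o
    loo_r = 2.0 - loo_x / b_half
    mean_r = np.nanmean(loo_r, axis=0)
    nb_eff = np.sum(~np.isnan(loo_r), axis=0)
    with np.errstate(invalid="ignore"):
        var = (nb_eff - 1) / nb_eff * np.nansum((loo_r - mean_r) ** 2, axis=0)
    se = np.sqrt(var)
    return se


def kinship_table(matrix: GenotypeMatrix, config: KinshipConfig):
    """Full cohort kinship analysis.

    Returns (table, calibration, r_matrix) where the table has one row per
    pair (id_a, id_b, overlap_snps, mismatches, x, r, se_r, degree; pairs
    below min_pair_overlap keep x but are left unclassified) and r_matrix is
    a square frame of r for plotting. Table attrs carry the ids of
    individuals with at least one close (3rd-degree or closer) relative.
    """
    from .eigenstrat import snp_coverage

    pm = pairwise_mismatch(matrix, min_overlap=0, block_cm=config.block_cm)
    coverage = snp_coverage(matrix)
    calib = calibrate_baseline(pm, coverage, config.min_baseline_snps)

    r = 2.0 - pm["x"].to_numpy() / calib.b
    ia, ib = pm.attrs["pair_index"]
    se = _jackknife_r(
        pm.attrs["block_mismatches"], pm.attrs["block_overlap"], ia, ib, calib.b
    )
    classified = pm["overlap_snps"].to_numpy() >= config.min_pair_overlap
    degrees = [
        classify_degree(ri, si, config.degree_windows) if ok and np.isfinite(ri)
        else "unclassified"
        for ri, si, ok in zip(r, se, classified)
    ]
    table = pm.drop(columns=[]).copy()
    table["r"] = r
    table["se_r"] = se
    table["degree"] = degrees

    ids = matrix.individual_ids
    rarr = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(rarr, 1.0)
    rarr[ia, ib] = r
    rarr[ib, ia] = r
    rmat = pd.DataFrame(rarr, index=ids, columns=ids)

    close = set()
    for row in table.itertuples():
        if row.degree in CLOSE_DEGREES:
            close.add(row.id_a)
            close.add(row.id_b)
    table.attrs["close_kin_ids"] = sorted(close)
    table.attrs["n_close_kin"] = len(close)
    table.attrs["block_mismatches"] = pm.attrs["block_mismatches"]
    table.attrs["block_overlap"] = pm.attrs["block_overlap"]
    return table, calib, rmat
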