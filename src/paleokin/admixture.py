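"""f4-statistics and qpAdm-style admixture-proportion estimation.

f4(A, B; C, D) is the mean over SNPs of (p_A - p_B)(p_C - p_D); its standard
error comes from a delete-one block jackknife over contiguous genetic-map
blocks (5 cM default), robust to linkage. A target population T is modelled
as a mixture of source populations S_1..S_k by expressing its f4-vector
against an outgroup set O_1..O_m,

    F_t[j] = f4(T, O_1; O_j, O_1),    j = 2..m,

as a weighted combination of the sources' vectors and solving a generalised
least-squares problem subject to the weights summing to one, with the
jackknife covariance of the residual vector as weighting matrix. Weight
standard errors come from delete-one-block re-estimation.

This is deliberately a reduced qpAdm: a single mixture fit with no rank tests
or nested-model p-values, matching the single two-source use case it serves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eigenstrat import SNPRecord
from .genmap import map_blocks


class SingularModelError(np.linalg.LinAlgError):
    """The source f4 system is rank-deficient (e.g. duplicated sources)."""


@dataclass
class AlleleFrequencyTable:
    """Alt-allele frequencies (populations x SNPs), NaN = missing."""

    populations: list[str]
    snps: list[SNPRecord]
    freq: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.populations), len(self.snps)):
            raise ValueError("freq shape does not match populations x snps")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq) < 0 or np.nanmax(self.freq) > 1:
                raise ValueError("frequencies outside [0, 1]")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population labels")

    def row(self, pop: str) -> np.ndarray:
        try:
            return self.freq[self.populations.index(pop)]
        except ValueError:
            raise KeyError(f"population {pop!r} not in table") from None

    def block_ids(self, block_cm: float) -> np.ndarray:
        chroms = np.array([s.chromosome for s in self.snps])
        gpos = np.array([s.genetic_pos for s in self.snps])
        return map_blocks(chroms, gpos, block_cm)


@dataclass(frozen=True)
class F4Result:
    quadruple: tuple[str, str, str, str]
    value: float
    se: float
    z: float
    n_snps_used: int
    n_blocks: int


@dataclass(frozen=True)
class MixtureModel:
    target: str
    sources: tuple[str, ...]
    outgroups: tuple[str, ...]
    weights: np.ndarray
    se_weights: np.ndarray
    fit_residual_stat: float
    feasible: bool


def _block_f4_sums(table, a, b, c, d, block_cm):
    """Per-block sums and SNP counts of (p_A - p_B)(p_C - p_D), complete-case."""
    pa, pb, pc, pd_ = (table.row(x) for x in (a, b, c, d))
    prod = (pa - pb) * (pc - pd_)
    ok = np.isfinite(prod)
    if not ok.any():
        raise ValueError(f"no SNP with complete data for ({a},{b};{c},{d})")
    blocks = table.block_ids(block_cm)
    n_blocks = int(blocks.max()) + 1
    sums = np.bincount(blocks[ok], weights=prod[ok], minlength=n_blocks)
    counts = np.bincount(blocks[ok], minlength=n_blocks).astype(float)
    return sums, counts


def f4(
    table: AlleleFrequencyTable,
    a: str, b: str, c: str, d: str,
    block_cm: float = 5.0,
) -> F4Result:
    """f4-statistic with delete-one block-jackknife standard error."""
    sums, counts = _block_f4_sums(table, a, b, c, d, block_cm)
    nonempty = counts > 0
    if nonempty.sum() < 2:
        raise ValueError("need at least two non-empty jackknife blocks")
    tot_s, tot_n = sums.sum(), counts.sum()
    value = tot_s / tot_n
    loo = (tot_s - sums[nonempty]) / (tot_n - counts[nonempty])
    # weighted (unequal block size) delete-one jackknife variance
    h = tot_n / counts[nonempty]
    pseudo = h * value - (h - 1.0) * loo
    nb = len(loo)
    se = float(np.sqrt(np.sum((pseudo - value) ** 2 / (h - 1.0)) / nb))
    z = value / se if se > 0 else np.inf * np.sign(value) if value else 0.0
    return F4Result((a, b, c, d), float(value), se, float(z),
                    int(tot_n), int(nonempty.sum()))


def _f4_vector_blocks(table, left_pops, outgroups, block_cm):
    """Block sums/counts of f4(L, O1; Oj, O1) for each left pop L and j >= 2.

    Returns (S, C): S[l, j-1] per-block sums array of shape (n_left, m-1,
    n_blocks) and the shared complete-case per-block SNP counts. A single
    complete-case mask across all involved populations keeps every statistic
    on the same SNP set, so f4 linearity holds exactly.
    """
    o1 = outgroups[0]
    rows = {p: table.row(p) for p in list(left_pops) + list(outgroups)}
    mask = np.ones(len(table.snps), dtype=bool)
    for p in rows.values():
        mask &= np.isfinite(p)
    if not mask.any():
        raise ValueError("no SNP with complete data across all populations")
    blocks = table.block_ids(block_cm)
    n_blocks = int(blocks.max()) + 1
    counts = np.bincount(blocks[mask], minlength=n_blocks).astype(float)
    p1 = rows[o1]
    sums = np.zeros((len(left_pops), len(outgroups) - 1, n_blocks))
    for li, lp in enumerate(left_pops):
        dl = rows[lp] - p1
        for j, oj in enumerate(outgroups[1:]):
            prod = dl * (rows[oj] - p1)
            sums[li, j] = np.bincount(
                blocks[mask], weights=prod[mask], minlength=n_blocks
            )
    return sums, counts


def _solve_constrained_gls(ft, fs, sigma_inv):
    """Minimise (ft - fs w)' Sigma^-1 (ft - fs w) s.t. sum(w) = 1 (KKT).

    Identifiability requires the source f4-vectors to differ; the check is on
    the centred design (differences between source columns), since the
    sum-to-one constraint absorbs any common component.
    """
    k = fs.shape[1]
    centred = fs[:, 1:] - fs[:, :1]
    if k > 1:
        sv = np.linalg.svd(centred, compute_uv=False)
        scale = max(np.abs(fs).max(), 1e-300)
        if sv.size == 0 or sv[-1] < 1e-9 * scale:
            raise SingularModelError(
                "source f4 system is singular (indistinguishable sources)"
            )
    ata = fs.T @ sigma_inv @ fs
    atb = fs.T @ sigma_inv @ ft
    s = max(np.abs(ata).max(), 1e-300)  # equilibrate KKT block scales
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * ata / s
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * atb / s, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError(f"constrained GLS system singular: {exc}") from exc
    return sol[:k]


def qpadm_lite(
    table: AlleleFrequencyTable,
    target: str,
    sources: list[str],
    outgroups: list[str],
    block_cm: float = 5.0,
) -> MixtureModel:
    """Estimate admixture proportions of ``target`` from ``sources``.

    Requires >= 2 sources and >= len(sources)+1 outgroups, all disjoint from
    each other and the target. Two-step feasible GLS: OLS weights first, then
    the block-jackknife covariance of the residual f4-vector at those weights
    re-weights the fit. Raises SingularModelError for indistinguishable
    sources; a singular jackknife covariance falls back to its diagonal.
    """
    if len(sources) < 2:
        raise ValueError("need at least two sources")
    if len(outgroups) < len(sources) + 1:
        raise ValueError("need at least len(sources)+1 outgroups")
    all_pops = [target] + list(sources) + list(outgroups)
    if len(set(all_pops)) != len(all_pops):
        raise ValueError("target, sources and outgroups must be disjoint")

    left = [target] + list(sources)
    sums, counts = _f4_vector_blocks(table, left, outgroups, block_cm)
    tot_n = counts.sum()
    tot = sums.sum(axis=2) / tot_n  # (1 + k, m-1)
    ft, fs = tot[0], tot[1:].T  # (m-1,), (m-1, k)

    k, m1 = len(sources), len(outgroups) - 1

    def weights_from(ft_v, fs_m, sigma_inv):
        return _solve_constrained_gls(ft_v, fs_m, sigma_inv)

    w_ols = weights_from(ft, fs, np.eye(m1))

    # jackknife covariance of the residual vector e = F_t - F_s w at w_ols
    nonempty = counts > 0
    nb = int(nonempty.sum())
    if nb < m1 + 1:
        raise ValueError("too few jackknife blocks for covariance estimation")
    loo_tot = (sums.sum(axis=2)[:, :, None] - sums[:, :, nonempty]) / (
        tot_n - counts[nonempty]
    )  # (1+k, m-1, nb)
    loo_e = loo_tot[0] - np.einsum("kjb,k->jb", loo_tot[1:], w_ols)
    dev = loo_e - loo_e.mean(axis=1, keepdims=True)
    sigma = (nb - 1) / nb * (dev @ dev.T)
    if np.trace(sigma) < 1e-30:
        sigma_inv = np.eye(m1)  # exact/noise-free data: plain least squares
    else:
        try:
            sigma_inv = np.linalg.inv(sigma)
            if np.linalg.cond(sigma) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            sigma_inv = np.diag(1.0 / np.maximum(np.diag(sigma), 1e-300))

    w = weights_from(ft, fs, sigma_inv)

    # delete-one-block re-estimation for weight SEs
    loo_w = np.empty((nb, k))
    for bi in range(nb):
        loo_w[bi] = weights_from(loo_tot[0, :, bi], loo_tot[1:, :, bi].T, sigma_inv)
    w_bar = loo_w.mean(axis=0)
    se_w = np.sqrt((nb - 1) / nb * np.sum((loo_w - w_bar) ** 2, axis=0))

    resid = ft - fs @ w
    stat = float(resid @ sigma_inv @ resid)
    feasible = bool(np.all((w >= 0) & (w <= 1)))
    return MixtureModel(
        target=target, sources=tuple(sources), outgroups=tuple(outgroups),
        weights=w, se_weights=se_w, fit_residual_stat=stat, feasible=feasible,
    )


def read_freq_table(path, sep="\t") -> AlleleFrequencyTable:
    """Frequency table file: snp_id, chromosome, genetic_pos, physical_pos,
    ref, alt, then one column per population."""
    df = pd.read_csv(path, sep=sep)
    meta = ["snp_id", "chromosome", "genetic_pos", "physical_pos", "ref", "alt"]
    missing = set(meta) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pops = [c for c in df.columns if c not in meta]
    snps = [
        SNPRecord(str(r.snp_id), str(r.chromosome), float(r.genetic_pos),
                  int(r.physical_pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    return AlleleFrequencyTable(pops, snps, df[pops].to_numpy().T)
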