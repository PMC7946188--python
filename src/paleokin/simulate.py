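"""Synthetic cohorts with known ground truth for every pipeline stage.

Generates: founder allele frequencies with drift, Mendelian transmission
through small pedigrees (unlinked per-SNP for kinship expectations, or linked
haplotype mosaics with recombination for ROH realism), pseudo-haploid
sampling and missingness, authenticity read counts, ROH segment lengths under
a constant-size panmictic coalescent, and admixed allele-frequency tables via
Balding-Nichols drift. Every generator is a pure function of its arguments
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admixture import AlleleFrequencyTable
from .eigenstrat import (
    DIPLOID,
    MISSING,
    GenotypeMatrix,
    IndividualRecord,
    SNPRecord,
)
from .genmap import genome_map
from .pedigree import Pedigree, UniparentalProfile, expected_kinship
from .qc import ReadCountSummary


# ---------------------------------------------------------------------------
# SNP panel


def make_snp_panel(n_snps: int, gmap: dict[str, float] | None = None) -> list[SNPRecord]:
    """Evenly spaced synthetic SNP panel over the genetic map (deterministic).

    SNPs are allocated to chromosomes proportionally to genetic length and
    placed at regular genetic intervals; physical positions use 1 cM ~ 1 Mb.
    """
    gmap = genome_map(gmap)
    total_cm = sum(gmap.values())
    snps: list[SNPRecord] = []
    chroms = list(gmap)
    counts = [max(1, int(round(n_snps * gmap[c] / total_cm))) for c in chroms]
    # adjust rounding drift on the largest chromosome
    counts[0] += n_snps - sum(counts)
    for chrom, n_c in zip(chroms, counts):
        length_cm = gmap[chrom]
        pos_cm = (np.arange(n_c) + 0.5) / n_c * length_cm
        for i, pc in enumerate(pos_cm):
            snps.append(
                SNPRecord(
                    snp_id=f"snp_{chrom}_{i}",
                    chromosome=str(chrom),
                    genetic_pos=float(pc) / 100.0,
                    physical_pos=int(round(pc * 1e6)) + 1,
                    ref_allele="A",
                    alt_allele="G",
                )
            )
    return snps


def founder_frequencies(n_snps: int, rng: np.random.Generator,
                        law: tuple = ("uniform", 0.05, 0.95)) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=n_snps)
    if kind == "beta":
        return rng.beta(law[1], law[2], size=n_snps)
    raise ValueError(f"unknown founder frequency law {kind!r}")


# ---------------------------------------------------------------------------
# Cohort specification


@dataclass
class CohortSpec:
    """Pedigreed cohort blueprint: who is sampled, their sex and lineages,
    and the parent links (which may involve unsampled placeholder ids)."""

    sampled: list[str]
    sexes: dict[str, str]
    mt: dict[str, str]
    y: dict[str, str | None]
    trios: list[tuple[str, str | None, str | None]] = field(default_factory=list)
    duplicates: dict[str, str] = field(default_factory=dict)  # new_id -> source_id

    def pedigree(self) -> Pedigree:
        ped = Pedigree()
        for ind in self.all_ids():
            ped.members.add(ind)
        for child, mother, father in self.trios:
            ped.add_trio(child, mother, father)
        return ped

    def all_ids(self) -> list[str]:
        ids: dict[str, None] = {}
        for child, mother, father in self.trios:
            for x in (mother, father, child):
                if x is not None:
                    ids.setdefault(x)
        for s in self.sampled:
            if s not in self.duplicates:
                ids.setdefault(s)
        return list(ids)

    def sexes_of_sampled(self) -> dict[str, str]:
        return {i: self.sexes[i] for i in self.sampled}

    def profiles(self) -> dict[str, UniparentalProfile]:
        return {
            i: UniparentalProfile(i, self.mt[i], self.y.get(i), self.sexes[i])
            for i in self.sampled
        }


def fig5_cohort_spec() -> CohortSpec:
    """A 38-individual cohort with four planted pedigrees and 27 singletons.

    Structure: (i) a man, his two daughters and his fraternal nephew;
    (ii) two sisters and their first cousin; (iii) a father-son pair;
    (iv) a boy and his paternal aunt. Exactly 11 individuals have a relative
    at 3rd degree or closer. Sexes 20 F / 18 M; 30 distinct mtDNA lineages
    and 6 distinct Y lineages.
    """
    trios = [
        # pedigree (i): P1_father + unsampled brother line
        ("P1_father", "p1_gm", "p1_gf"),
        ("p1_uncle", "p1_gm", "p1_gf"),
        ("P1_daughterA", "p1_wife", "P1_father"),
        ("P1_daughterB", "p1_wife", "P1_father"),
        ("P1_nephew", "p1_auntw", "p1_uncle"),
        # pedigree (ii): two sisters + first cousin through their father's brother
        ("p2_dad", "p2_gm", "p2_gf"),
        ("p2_dadbro", "p2_gm", "p2_gf"),
        ("P2_sisterA", "p2_mom", "p2_dad"),
        ("P2_sisterB", "p2_mom", "p2_dad"),
        ("P2_cousin", "p2_brow", "p2_dadbro"),
        # pedigree (iii): father and son
        ("P3_son", "p3_mom", "P3_father"),
        # pedigree (iv): boy and his paternal aunt
        ("p4_dad", "p4_gm", "p4_gf"),
        ("P4_aunt", "p4_gm", "p4_gf"),
        ("P4_boy", "p4_mom", "p4_dad"),
    ]
    sampled = [
        "P1_father", "P1_daughterA", "P1_daughterB", "P1_nephew",
        "P2_sisterA", "P2_sisterB", "P2_cousin",
        "P3_father", "P3_son",
        "P4_boy", "P4_aunt",
    ] + [f"single_{i:02d}" for i in range(27)]

    sexes = {
        "P1_father": "M", "P1_daughterA": "F", "P1_daughterB": "F",
        "P1_nephew": "M",
        "P2_sisterA": "F", "P2_sisterB": "F", "P2_cousin": "M",
        "P3_father": "M", "P3_son": "M",
        "P4_boy": "M", "P4_aunt": "F",
    }
    # singletons: 12 male, 15 female -> cohort totals 18 M / 20 F
    for i in range(27):
        sexes[f"single_{i:02d}"] = "M" if i < 12 else "F"

    mt = {
        "P1_father": "U5a", "P1_daughterA": "H1", "P1_daughterB": "H1",
        "P1_nephew": "K1a",
        "P2_sisterA": "J1c", "P2_sisterB": "J1c", "P2_cousin": "T2b",
        "P3_father": "N1a", "P3_son": "H5",
        "P4_boy": "W6", "P4_aunt": "X2",
    }
    # 27 singletons over 21 distinct mt labels -> 9 + 21 = 30 distinct overall
    singleton_mt = [f"mt_{j:02d}" for j in range(21)] + [
        "mt_00", "mt_01", "mt_02", "mt_03", "mt_04", "mt_05",
    ]
    for i in range(27):
        mt[f"single_{i:02d}"] = singleton_mt[i]

    y: dict[str, str | None] = {i: None for i in sampled}
    # paternal lines: father and fraternal nephew share Y; father-son share Y
    y["P1_father"] = "G2"
    y["P1_nephew"] = "G2"
    y["P2_cousin"] = "I2"
    y["P3_father"] = "C-V20"
    y["P3_son"] = "C-V20"
    y["P4_boy"] = "G2"
    male_singletons = [f"single_{i:02d}" for i in range(12)]
    singleton_y = ["G2", "G2", "I2", "I2", "I2", "C-V20",
                   "J2a", "J2a", "J2a", "H2", "H2", "R1b-V88"]
    for sid, lin in zip(male_singletons, singleton_y):
        y[sid] = lin

    return CohortSpec(sampled=sampled, sexes=sexes, mt=mt, y=y, trios=trios)


def calibration_pairs_spec() -> CohortSpec:
    """Planted pairs at kinship phi = 1/2, 1/4, 1/8, 1/16 plus 12 unrelated
    singletons (two of which serve as the phi = 0 pair)."""
    trios = [
        ("PO_child", "po_mom", "PO_parent"),
        ("HS_a", "hs_momA", "hs_dad"),
        ("HS_b", "hs_momB", "hs_dad"),
        ("fc_p1", "fc_gm", "fc_gf"),
        ("fc_p2", "fc_gm", "fc_gf"),
        ("FC_a", "fc_w1", "fc_p1"),
        ("FC_b", "fc_w2", "fc_p2"),
    ]
    sampled = (
        ["DUP_a", "DUP_b", "PO_parent", "PO_child", "HS_a", "HS_b",
         "FC_a", "FC_b"]
        + [f"u_{i:02d}" for i in range(12)]
    )
    sexes = {i: ("M" if k % 2 else "F") for k, i in enumerate(sampled)}
    mt = {i: f"mt_{i}" for i in sampled}
    y: dict[str, str | None] = {i: None for i in sampled}
    return CohortSpec(
        sampled=sampled, sexes=sexes, mt=mt, y=y, trios=trios,
        duplicates={"DUP_b": "DUP_a"},
    )


# ---------------------------------------------------------------------------
# Genotype simulation


def _topological_order(spec: CohortSpec) -> list[str]:
    parents = {c: (m, f) for c, m, f in spec.trios}
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(n: str) -> None:
        if state.get(n) == 2:
            return
        if state.get(n) == 1:
            raise ValueError(f"pedigree cycle at {n!r}")
        state[n] = 1
        for p in parents.get(n, (None, None)):
            if p is not None:
                visit(p)
        state[n] = 2
        order.append(n)

    for ind in spec.all_ids():
        visit(ind)
    return order


def simulate_cohort(
    spec: CohortSpec,
    n_snps: int = 500_000,
    seed: int = 0,
    gmap: dict[str, float] | None = None,
    founder_law: tuple = ("uniform", 0.05, 0.95),
    coverage_range: tuple[float, float] = (0.85, 1.0),
    linked: bool = False,
) -> tuple[GenotypeMatrix, dict]:
    """Simulate diploid genotypes through the spec's pedigrees.

    Founders draw alleles from shared population frequencies; children by
    Mendelian transmission — per-SNP independent by default (sufficient for
    mismatch/kinship expectations), or linked haplotype mosaics with
    crossovers at 1 per Morgan when ``linked`` (required for ROH realism).
    Returns the sampled individuals' diploid matrix plus a truth record with
    every pairwise kinship coefficient, sexes, lineages and close-kin ids.
    """
    rng = np.random.default_rng(seed)
    snps = make_snp_panel(n_snps, gmap)
    n_snps = len(snps)
    p = founder_frequencies(n_snps, rng, founder_law)
    order = _topological_order(spec)
    parents = {c: (m, f) for c, m, f in spec.trios}

    if linked:
        gpos = np.array([s.genetic_pos for s in snps])
        chrom = np.array([s.chromosome for s in snps])
        haplos = _simulate_linked(order, parents, p, gpos, chrom, rng)
        genos = {i: (haplos[i][0] + haplos[i][1]).astype(np.int8) for i in order}
    else:
        genos = {}
        for ind in order:
            mo, fa = parents.get(ind, (None, None))
            if mo is None and fa is None:
                genos[ind] = rng.binomial(2, p).astype(np.int8)
            else:
                g = np.zeros(n_snps, dtype=np.int8)
                for par in (mo, fa):
                    src = genos[par] if par is not None else rng.binomial(
                        2, p
                    ).astype(np.int8)
                    g += (rng.random(n_snps) < src / 2.0).astype(np.int8)
                genos[ind] = g

    calls = np.empty((len(spec.sampled), n_snps), dtype=np.int8)
    cov_lo, cov_hi = coverage_range
    coverage_frac = rng.uniform(cov_lo, cov_hi, size=len(spec.sampled))
    for i, ind in enumerate(spec.sampled):
        src = spec.duplicates.get(ind, ind)
        calls[i] = genos[src]
        if coverage_frac[i] < 1.0:
            miss = rng.random(n_snps) >= coverage_frac[i]
            calls[i, miss] = MISSING

    individuals = [
        IndividualRecord(ind, spec.sexes.get(ind, "U"), "Synthetic")
        for ind in spec.sampled
    ]
    matrix = GenotypeMatrix(individuals, snps, calls, ploidy_mode=DIPLOID)

    ped = spec.pedigree()
    phi: dict[tuple[str, str], float] = {}
    for i, a in enumerate(spec.sampled):
        for b in spec.sampled[i + 1:]:
            ga, gb = spec.duplicates.get(a, a), spec.duplicates.get(b, b)
            if ga == gb:
                phi[(a, b)] = 0.5
            else:
                phi[(a, b)], _ = expected_kinship(ped, ga, gb)
    close = sorted(
        {x for (a, b), k in phi.items() if k >= 1 / 32 for x in (a, b)}
    )
    truth = {
        "phi": phi,
        "sexes": dict(spec.sexes),
        "mt": dict(spec.mt),
        "y": dict(spec.y),
        "close_kin_ids": close,
        "allele_freqs": p,
        "pedigree": ped,
        "coverage_frac": dict(zip(spec.sampled, coverage_frac)),
    }
    return matrix, truth


def _simulate_linked(order, parents, p, gpos, chrom, rng):
    """Haplotype-mosaic transmission: crossovers at 1 per Morgan."""
    chrom_labels = list(dict.fromkeys(chrom))
    chrom_slices = {c: np.flatnonzero(chrom == c) for c in chrom_labels}
    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def gamete(parent_haps):
        h = np.empty(len(p), dtype=np.int8)
        for c in chrom_labels:
            idx = chrom_slices[c]
            pos = gpos[idx]
            length = pos[-1] - pos[0] + 1e-9
            n_x = rng.poisson(length)
            cuts = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
            seg = np.searchsorted(cuts, pos, side="right")
            use_second = (seg + rng.integers(0, 2)) % 2 == 1
            h[idx] = np.where(use_second, parent_haps[1][idx], parent_haps[0][idx])
        return h

    for ind in order:
        mo, fa = parents.get(ind, (None, None))
        hs = []
        for par in (mo, fa):
            if par is None:
                hs.append((rng.random(len(p)) < p).astype(np.int8))
            else:
                hs.append(gamete(haplos[par]))
        haplos[ind] = (hs[0], hs[1])
    return haplos


def simulate_diploid_with_tracts(
    n_snps: int,
    tracts: list[tuple[str, float, float]],
    seed: int = 0,
    gmap: dict[str, float] | None = None,
    founder_law: tuple = ("uniform", 0.05, 0.95),
    individual_id: str = "planted",
) -> GenotypeMatrix:
    """One diploid individual with autozygous tracts planted by copying one
    haplotype over the other within (chromosome, start_cM, end_cM) windows."""
    rng = np.random.default_rng(seed)
    snps = make_snp_panel(n_snps, gmap)
    p = founder_frequencies(len(snps), rng, founder_law)
    h1 = (rng.random(len(snps)) < p).astype(np.int8)
    h2 = (rng.random(len(snps)) < p).astype(np.int8)
    chroms = np.array([s.chromosome for s in snps])
    pos_cm = np.array([s.genetic_pos for s in snps]) * 100.0
    for chrom, start_cm, end_cm in tracts:
        inside = (chroms == str(chrom)) & (pos_cm >= start_cm) & (pos_cm < end_cm)
        h2[inside] = h1[inside]
    calls = (h1 + h2)[None, :]
    return GenotypeMatrix(
        [IndividualRecord(individual_id, "U", "Synthetic")], snps, calls,
        ploidy_mode=DIPLOID,
    )


# ---------------------------------------------------------------------------
# Read-count simulation for QC


def simulate_read_counts(
    sexes: dict[str, str],
    seed: int = 0,
    damage_rate: float = 0.05,
    contamination_rate: float = 0.0,
    terminal_total: int = 1000,
    mt_total: int = 1000,
    xy_reads: int = 1000,
    x_sites: int = 1000,
) -> list[ReadCountSummary]:
    """Authenticity read counts with known damage/contamination ground truth.

    Terminal damage ~ Binomial(total, damage_rate). mtDNA consensus matches
    drop with contamination (contaminant mt divergence ~2.5% plus 0.1%
    sequencing error). Y-read fraction centres at 0.45 for males and 0.005
    for females. X polymorphic sites (males) appear at 0.2% error rate plus a
    contamination-dependent excess.
    """
    rng = np.random.default_rng(seed)
    mt_match_p = max(0.0, 1.0 - 0.001 - contamination_rate * 0.025)
    x_poly_p = min(1.0, 0.002 + contamination_rate * 0.05)
    out = []
    for ind, sex in sexes.items():
        y_p = 0.45 if sex == "M" else 0.005
        out.append(
            ReadCountSummary(
                individual_id=ind,
                terminal_ct_damaged=int(rng.binomial(terminal_total, damage_rate)),
                terminal_ct_total=terminal_total,
                mt_match=int(rng.binomial(mt_total, mt_match_p)),
                mt_total=mt_total,
                x_poly_sites=int(rng.binomial(x_sites, x_poly_p)),
                x_sites_ge2x=x_sites,
                y_reads=int(rng.binomial(xy_reads, y_p)),
                xy_reads=xy_reads,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ROH segment lengths under a constant-size panmictic coalescent


def _size_biased_slow_cdf(p: float, t_split: int):
    """Truncated size-biased geometric pmf/cdf for t = 1..t_split.

    Along the genome, the time of the tract covering a random segment (by
    count) is size-biased: Q(t) proportional to t * P(t). Only "slow" tracts
    (t <= t_split) can exceed the reporting floor.
    """
    t = np.arange(1, t_split + 1, dtype=float)
    q = 1.0 - p
    pmf = t * p**2 * q ** (t - 1.0)
    mass = float(pmf.sum())
    cdf = np.cumsum(pmf) / mass
    return t, pmf, mass, cdf


def _fast_moments(p: float, t_split: int, slow_mass: float):
    """Mean/std of one fast segment's map length (Morgans), exact sums."""
    q = 1.0 - p
    # E_Q[L ; t > ts] = sum t p^2 q^(t-1) * 1/(2t) = (p/2) q^ts
    m1 = 0.5 * p * q**t_split
    # E_Q[L^2 ; t > ts] = (p^2/2) * sum_{t>ts} q^(t-1)/t, via -log(p) closed form
    ts = np.arange(1, t_split + 1, dtype=float)
    partial = float(np.sum(q**ts / ts))
    s2 = (-np.log(p) - partial) / q
    m2 = 0.5 * p**2 * s2
    fast_mass = 1.0 - slow_mass
    mu = m1 / fast_mass
    var = max(m2 / fast_mass - mu**2, 0.0)
    return mu, np.sqrt(var)


def simulate_roh_lengths(
    true_ne: float,
    n_individuals: int,
    seed: int = 0,
    gmap: dict[str, float] | None = None,
    min_report_cm: float = 4.0,
    mode: str = "fast",
    id_prefix: str = "sim",
) -> list:
    """Monte-Carlo ROH genomes under constant diploid size ``true_ne``.

    Renewal approximation of the pairwise coalescent along each chromosome:
    the chromosome-start segment has stationary coalescence time
    t ~ Geometric(1/2Ne) and residual length Exp(2t); each subsequent segment
    draws a size-biased time (t = G1 + G2 - 1 for two geometrics) and length
    Exp(2t), truncated at the chromosome end. Segments of at least
    ``min_report_cm`` are emitted.

    ``mode="exact"`` walks every segment (feasible for small Ne or maps);
    ``mode="fast"`` draws only segments capable of reaching the floor
    exactly and aggregates intervening runs of short segments by a
    moment-matched normal approximation of their summed length.
    """
    from .roh import ROHSegment

    if true_ne < 2:
        raise ValueError("true_ne must be >= 2")
    rng = np.random.default_rng(seed)
    gmap = genome_map(gmap)
    p = 1.0 / (2.0 * true_ne)
    segments: list[ROHSegment] = []
    ids = [f"{id_prefix}_{i:04d}" for i in range(n_individuals)]

    if mode == "exact":
        for ind in ids:
            for chrom, length_cm in gmap.items():
                for s, e in _walk_exact(rng, p, length_cm / 100.0):
                    if (e - s) * 100.0 >= min_report_cm:
                        segments.append(
                            ROHSegment(ind, str(chrom), s * 100.0, e * 100.0)
                        )
        return segments
    if mode != "fast":
        raise ValueError(f"unknown mode {mode!r}")

    floor_m = max(min_report_cm, 0.5) / 100.0
    t_split = int(np.ceil(22.0 / floor_m / 2.0))  # exp(-2 t floor) < 3e-10 beyond
    t_split = max(t_split, 1)
    tvals, pmf, slow_mass, slow_cdf = _size_biased_slow_cdf(p, t_split)
    mu_f, sd_f = _fast_moments(p, t_split, slow_mass)
    e_slow_len = float(np.sum(pmf / (2 * tvals))) / slow_mass
    e_cycle = (1.0 / slow_mass - 1.0) * mu_f + e_slow_len

    for chrom, length_cm in gmap.items():
        g = length_cm / 100.0
        n_cyc = int(np.ceil(g / e_cycle * 1.5)) + 30
        starts, lens = _fast_chromosome_batch(
            rng, p, g, n_individuals, n_cyc, t_split, slow_cdf, slow_mass,
            mu_f, sd_f, tvals,
        )
        for i, ind in enumerate(ids):
            for s, ln in zip(starts[i], lens[i]):
                if ln * 100.0 >= min_report_cm:
                    segments.append(
                        ROHSegment(ind, str(chrom), s * 100.0, (s + ln) * 100.0)
                    )
    return segments


def _walk_exact(rng, p, g_morgans):
    """Yield (start, end) of every segment along one chromosome."""
    pos = 0.0
    first = True
    while pos < g_morgans:
        if first:
            t = rng.geometric(p)
            first = False
        else:
            t = rng.geometric(p) + rng.geometric(p) - 1  # size-biased
        ln = rng.exponential(1.0 / (2.0 * t))
        end = min(pos + ln, g_morgans)
        yield pos, end
        pos += ln


def _fast_chromosome_batch(
    rng, p, g, n_ind, n_cyc, t_split, slow_cdf, slow_mass, mu_f, sd_f, tvals
):
    """Vectorised fast-mode walk of one chromosome for all individuals.

    Returns per-individual lists of (start, length) for slow segments (and
    the exact first segment when slow), truncated at the chromosome end.
    """
    # first segment: exact stationary draw
    t0 = rng.geometric(p, size=n_ind)
    l0 = rng.exponential(1.0 / (2.0 * t0))

    def draw_block(n_cols):
        k = rng.geometric(slow_mass, size=(n_ind, n_cols))  # trials to success
        kf = (k - 1).astype(float)  # fast segments before the slow one
        gp = np.where(
            kf > 0,
            np.clip(rng.normal(kf * mu_f, np.sqrt(np.maximum(kf, 1e-12)) * sd_f),
                    0.0, None),
            0.0,
        )
        u = rng.random((n_ind, n_cols))
        t_slow = tvals[np.searchsorted(slow_cdf, u)]
        ls = rng.exponential(1.0 / (2.0 * t_slow))
        return gp, ls

    gaps, l_slow = draw_block(n_cyc)
    while np.any(l0 + (gaps + l_slow).sum(axis=1) < g):
        extra_g, extra_l = draw_block(max(n_cyc // 2, 8))
        gaps = np.concatenate([gaps, extra_g], axis=1)
        l_slow = np.concatenate([l_slow, extra_l], axis=1)

    cyc = gaps + l_slow
    cum_excl = np.cumsum(cyc, axis=1) - cyc
    starts = l0[:, None] + cum_excl + gaps
    valid = starts < g
    lens = np.minimum(l_slow, g - starts)

    out_starts: list[list[float]] = []
    out_lens: list[list[float]] = []
    for i in range(n_ind):
        s_i = list(starts[i][valid[i]])
        l_i = list(lens[i][valid[i]])
        if t0[i] <= t_split:  # first segment can be long enough to report
            s_i.insert(0, 0.0)
            l_i.insert(0, min(l0[i], g))
        out_starts.append(s_i)
        out_lens.append(l_i)
    return out_starts, out_lens


# ---------------------------------------------------------------------------
# Admixed allele-frequency tables (Balding-Nichols drift)


def _bn_drift(p0: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols: child frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f <= 0:
        return p0.copy()
    a = p0 * (1.0 - f) / f
    b = (1.0 - p0) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_admixed_freqs(
    n_snps: int = 100_000,
    seed: int = 0,
    alpha: float = 0.09,
    f_target: float = 0.005,
    f_sources: float = 0.005,
    n_outgroups: int = 8,
    gmap: dict[str, float] | None = None,
) -> tuple[AlleleFrequencyTable, dict]:
    """Two-source admixture scenario: target = drift(alpha*S1 + (1-alpha)*S2).

    The population tree gives outgroups O2 and O3 drift shared with S1 and S2
    respectively (via internal nodes), which makes the two sources'
    f4-vectors against the outgroups distinguishable; remaining outgroups
    branch straight off the root at varied drift.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if n_outgroups < 3:
        raise ValueError("need at least three outgroups")
    rng = np.random.default_rng(seed)
    snps = make_snp_panel(n_snps, gmap)
    p0 = rng.uniform(0.05, 0.95, size=len(snps))
    node_a = _bn_drift(p0, 0.02, rng)
    node_b = _bn_drift(p0, 0.02, rng)
    s1 = _bn_drift(node_a, f_sources, rng)
    s2 = _bn_drift(node_b, f_sources, rng)
    freqs = {"S1": s1, "S2": s2}
    outgroups = [f"O{i}" for i in range(1, n_outgroups + 1)]
    freqs["O1"] = _bn_drift(p0, 0.03, rng)
    freqs["O2"] = _bn_drift(node_a, 0.01, rng)
    freqs["O3"] = _bn_drift(node_b, 0.01, rng)
    for j, og in enumerate(outgroups[3:]):
        freqs[og] = _bn_drift(p0, 0.01 + 0.008 * j, rng)
    mix = alpha * s1 + (1.0 - alpha) * s2
    freqs["Target"] = _bn_drift(mix, f_target, rng)

    pops = ["Target", "S1", "S2"] + outgroups
    table = AlleleFrequencyTable(pops, snps, np.vstack([freqs[p] for p in pops]))
    truth = {"alpha": alpha, "sources": ("S1", "S2"), "outgroups": tuple(outgroups)}
    return table, truth
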