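"""Synthetic generators: reproducibility and agreement with their own truth."""

import numpy as np
import pytest

from paleokin.eigenstrat import MISSING, pseudo_haploidize
from paleokin.genmap import map_blocks
from paleokin.roh import expected_roh_counts, summarize_roh
from paleokin.simulate import (
    calibration_pairs_spec,
    fig5_cohort_spec,
    founder_frequencies,
    make_snp_panel,
    simulate_admixed_freqs,
    simulate_cohort,
    simulate_diploid_with_tracts,
    simulate_read_counts,
    simulate_roh_lengths,
)

SMALL_GMAP = {"1": 120.0, "2": 80.0}


class TestSnpPanel:
    def test_count_and_determinism(self):
        panel = make_snp_panel(1000, SMALL_GMAP)
        assert len(panel) == 1000
        assert panel == make_snp_panel(1000, SMALL_GMAP)

    def test_sorted_within_chromosome(self):
        panel = make_snp_panel(500, SMALL_GMAP)
        for chrom in SMALL_GMAP:
            pos = [s.genetic_pos for s in panel if s.chromosome == chrom]
            assert pos == sorted(pos)
            assert pos[-1] * 100 <= SMALL_GMAP[chrom]

    def test_allocation_proportional_to_map(self):
        panel = make_snp_panel(1000, SMALL_GMAP)
        n1 = sum(1 for s in panel if s.chromosome == "1")
        assert n1 == pytest.approx(600, abs=2)

    def test_founder_frequency_laws(self):
        rng = np.random.default_rng(0)
        u = founder_frequencies(1000, rng, ("uniform", 0.05, 0.95))
        assert u.min() >= 0.05 and u.max() <= 0.95
        with pytest.raises(ValueError):
            founder_frequencies(10, rng, ("zipf", 1.0))


class TestCohortSpecs:
    def test_fig5_invariants(self):
        spec = fig5_cohort_spec()
        assert len(spec.sampled) == 38
        sexes = list(spec.sexes_of_sampled().values())
        assert sexes.count("M") == 18 and sexes.count("F") == 20
        profiles = spec.profiles()
        assert len({p.mt_lineage for p in profiles.values()}) == 30
        y = {p.y_lineage for p in profiles.values()
             if p.sex_call == "M" and p.y_lineage}
        assert len(y) == 6

    def test_fig5_close_kin_truth(self):
        _, truth = simulate_cohort(fig5_cohort_spec(), n_snps=200, seed=0)
        assert len(truth["close_kin_ids"]) == 11
        assert all(i.startswith("P") for i in truth["close_kin_ids"])

    def test_calibration_pairs_phi(self):
        _, truth = simulate_cohort(calibration_pairs_spec(), n_snps=200, seed=0)
        phi = truth["phi"]
        assert phi[("DUP_a", "DUP_b")] == 0.5
        assert phi[("PO_parent", "PO_child")] == 0.25
        assert phi[("HS_a", "HS_b")] == 0.125
        assert phi[("FC_a", "FC_b")] == 0.0625
        assert phi[("u_00", "u_01")] == 0.0


class TestSimulateCohort:
    def test_reproducible(self):
        spec = calibration_pairs_spec()
        m1, _ = simulate_cohort(spec, n_snps=2000, seed=3)
        m2, _ = simulate_cohort(spec, n_snps=2000, seed=3)
        m3, _ = simulate_cohort(spec, n_snps=2000, seed=4)
        assert m1 == m2
        assert m1 != m3

    def test_duplicates_share_genotypes(self):
        spec = calibration_pairs_spec()
        m, _ = simulate_cohort(spec, n_snps=3000, seed=5,
                               coverage_range=(1.0, 1.0))
        ids = m.individual_ids
        a, b = m.calls[ids.index("DUP_a")], m.calls[ids.index("DUP_b")]
        assert np.array_equal(a, b)

    def test_coverage_missingness(self):
        spec = calibration_pairs_spec()
        m, truth = simulate_cohort(spec, n_snps=20_000, seed=6,
                                   coverage_range=(0.5, 0.6))
        frac = (m.calls != MISSING).mean(axis=1)
        assert np.all(frac > 0.45) and np.all(frac < 0.65)

    def test_unrelated_mismatch_matches_closed_form(self):
        """Pseudo-haploid mismatch of unrelated pairs = mean 2p(1-p)."""
        spec = calibration_pairs_spec()
        m, truth = simulate_cohort(spec, n_snps=50_000, seed=7,
                                   coverage_range=(1.0, 1.0))
        ph = pseudo_haploidize(m, seed=8)
        p = truth["allele_freqs"]
        expected = float(np.mean(2 * p * (1 - p)))
        ids = ph.individual_ids
        ia, ib = ids.index("u_02"), ids.index("u_03")
        x = float(np.mean(ph.calls[ia] != ph.calls[ib]))
        assert x == pytest.approx(expected, abs=0.005)

    def test_linked_mode_same_truth(self):
        spec = calibration_pairs_spec()
        m, truth = simulate_cohort(spec, n_snps=5000, seed=9, linked=True)
        assert m.n_individuals == len(spec.sampled)
        assert truth["phi"][("PO_parent", "PO_child")] == 0.25


class TestReadCounts:
    def test_oracle_rates(self):
        sexes = {f"m{i}": "M" for i in range(30)}
        sexes.update({f"f{i}": "F" for i in range(30)})
        counts = simulate_read_counts(sexes, seed=1, damage_rate=0.06)
        by_id = {c.individual_id: c for c in counts}
        dmg = np.mean([c.terminal_ct_damaged / c.terminal_ct_total
                       for c in counts])
        assert dmg == pytest.approx(0.06, abs=0.01)
        m_ratio = np.mean([by_id[f"m{i}"].y_reads / by_id[f"m{i}"].xy_reads
                           for i in range(30)])
        f_ratio = np.mean([by_id[f"f{i}"].y_reads / by_id[f"f{i}"].xy_reads
                           for i in range(30)])
        assert m_ratio == pytest.approx(0.45, abs=0.02)
        assert f_ratio == pytest.approx(0.005, abs=0.005)

    def test_contamination_degrades_mt_and_x(self):
        sexes = {f"m{i}": "M" for i in range(40)}
        clean = simulate_read_counts(sexes, seed=2, contamination_rate=0.0)
        dirty = simulate_read_counts(sexes, seed=2, contamination_rate=0.5)
        mt_clean = np.mean([c.mt_match for c in clean])
        mt_dirty = np.mean([c.mt_match for c in dirty])
        assert mt_dirty < mt_clean
        x_clean = np.mean([c.x_poly_sites for c in clean])
        x_dirty = np.mean([c.x_poly_sites for c in dirty])
        assert x_dirty > x_clean


class TestRohSimulator:
    def test_reproducible(self):
        a = simulate_roh_lengths(2000, 5, seed=3)
        b = simulate_roh_lengths(2000, 5, seed=3)
        assert a == b

    def test_exact_mode_matches_analytic(self):
        """Exact renewal walk agrees with the closed-form expected counts."""
        ne, n_ind = 500.0, 120
        gmap = {"1": 150.0}
        segs = simulate_roh_lengths(ne, n_ind, seed=4, gmap=gmap, mode="exact")
        n_obs = sum(1 for s in segs if 4.0 <= s.length_cm < 20.0)
        mu = expected_roh_counts(ne, gmap, (0.04, 0.20)) * n_ind
        assert abs(n_obs - mu) < 4 * np.sqrt(mu)

    def test_fast_mode_matches_exact_mode(self):
        ne, n_ind = 800.0, 150
        gmap = {"1": 120.0, "2": 90.0}
        mu = expected_roh_counts(ne, gmap, (0.04, 0.20)) * n_ind
        for mode, seed in (("exact", 5), ("fast", 6)):
            segs = simulate_roh_lengths(ne, n_ind, seed=seed, gmap=gmap,
                                        mode=mode)
            n_obs = sum(1 for s in segs if 4.0 <= s.length_cm < 20.0)
            assert abs(n_obs - mu) < 4 * np.sqrt(mu), mode

    def test_reported_segments_respect_floor(self):
        segs = simulate_roh_lengths(1000, 20, seed=7, gmap={"1": 100.0})
        assert all(s.length_cm >= 4.0 for s in segs)
        assert all(0.0 <= s.start_cm < s.end_cm <= 100.0 + 1e-9 for s in segs)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_roh_lengths(1.0, 5)
        with pytest.raises(ValueError):
            simulate_roh_lengths(1000, 5, mode="magic")


class TestTractsAndAdmixed:
    def test_planted_tract_is_autozygous(self):
        m = simulate_diploid_with_tracts(
            3000, [("1", 30.0, 50.0)], seed=8, gmap={"1": 100.0}
        )
        pos_cm = m.genetic_positions() * 100
        inside = (pos_cm >= 30.0) & (pos_cm < 50.0)
        assert not np.any(m.calls[0, inside] == 1)  # no hets inside
        assert np.any(m.calls[0, ~inside] == 1)     # hets elsewhere

    def test_admixed_freqs_structure(self):
        table, truth = simulate_admixed_freqs(n_snps=2000, seed=9, alpha=0.4)
        assert table.populations[:3] == ["Target", "S1", "S2"]
        assert truth["alpha"] == 0.4
        assert np.isfinite(table.freq).all()
        assert table.freq.min() >= 0.0 and table.freq.max() <= 1.0
        t2, _ = simulate_admixed_freqs(n_snps=2000, seed=9, alpha=0.4)
        assert np.array_equal(table.freq, t2.freq)

    def test_admixed_alpha_validation(self):
        with pytest.raises(ValueError):
            simulate_admixed_freqs(n_snps=100, alpha=1.5)
        with pytest.raises(ValueError):
            simulate_admixed_freqs(n_snps=100, n_outgroups=2)


def test_map_blocks_dense_and_contiguous():
    panel = make_snp_panel(300, SMALL_GMAP)
    chroms = np.array([s.chromosome for s in panel])
    gpos = np.array([s.genetic_pos for s in panel])
    blocks = map_blocks(chroms, gpos, block_cm=5.0)
    uniq = np.unique(blocks)
    assert uniq[0] == 0 and uniq[-1] == len(uniq) - 1  # dense ids
    # within a chromosome, block ids are non-decreasing along the map
    for chrom in SMALL_GMAP:
        sel = chroms == chrom
        assert np.all(np.diff(blocks[sel]) >= 0)
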