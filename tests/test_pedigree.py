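"""Expected kinship recursion, consistency rules, lineage diversity."""

import numpy as np
import pandas as pd
import pytest

from paleokin.pedigree import (
    Pedigree,
    UniparentalProfile,
    check_consistency,
    expected_kinship,
    lineage_diversity,
    read_pedigree_tsv,
    to_dot,
    unrelated_fraction,
)


def family() -> Pedigree:
    """Three-generation family used across the expected-kinship tests."""
    ped = Pedigree()
    ped.add_trio("dad", "gm", "gf")
    ped.add_trio("uncle", "gm", "gf")
    ped.add_trio("child1", "mom", "dad")
    ped.add_trio("child2", "mom", "dad")
    ped.add_trio("cousin", "auntw", "uncle")
    ped.add_trio("halfsib", "mom2", "dad")
    ped.members.add("stranger")
    return ped


class TestExpectedKinship:
    @pytest.mark.parametrize("a,b,phi", [
        ("dad", "child1", 0.25),       # parent-offspring
        ("child1", "child2", 0.25),    # full siblings
        ("gf", "child1", 0.125),       # grandparent
        ("uncle", "child1", 0.125),    # avuncular
        ("child1", "halfsib", 0.125),  # half siblings
        ("child1", "cousin", 0.0625),  # first cousins
        ("child1", "stranger", 0.0),   # unrelated
        ("mom", "dad", 0.0),           # founders unrelated
    ])
    def test_textbook_values(self, a, b, phi):
        ped = family()
        k, r = expected_kinship(ped, a, b)
        assert k == pytest.approx(phi)
        assert r == pytest.approx(2 * phi)
        # symmetric
        assert expected_kinship(ped, b, a)[0] == pytest.approx(phi)

    def test_self_kinship_outbred(self):
        assert expected_kinship(family(), "child1", "child1")[0] == 0.5

    def test_self_kinship_inbred(self):
        # child of half siblings: F = phi(halfsib, child1) = 1/8
        ped = family()
        ped.add_trio("inbred", "halfsib", "child1")
        assert expected_kinship(ped, "inbred", "inbred")[0] == pytest.approx(
            0.5 * (1 + 0.125)
        )

    def test_unknown_individual(self):
        with pytest.raises(KeyError):
            expected_kinship(family(), "dad", "nobody")

    def test_gene_dropping_monte_carlo_oracle(self):
        """Empirical IBD probability from allele dropping matches phi."""
        ped = family()
        pairs = [("dad", "child1"), ("child1", "cousin"), ("uncle", "child1")]
        rng = np.random.default_rng(99)
        founders = [m for m in ped.members if ped.parents(m) == (None, None)]
        order = []
        remaining = set(ped.members)
        while remaining:  # topological order by repeated sweeps
            for m in sorted(remaining):
                ps = [p for p in ped.parents(m) if p is not None]
                if all(p not in remaining for p in ps):
                    order.append(m)
                    remaining.discard(m)
        n_rep = 40_000
        label = {}
        next_lab = iter(range(10**6))
        for f in founders:
            label[f] = (next(next_lab), next(next_lab))
        alleles = {
            f: np.array([[label[f][0]] * n_rep, [label[f][1]] * n_rep])
            for f in founders
        }
        for m in order:
            mo, fa = ped.parents(m)
            if mo is None and fa is None:
                continue
            hm = alleles[mo][rng.integers(0, 2, n_rep), np.arange(n_rep)]
            hf = alleles[fa][rng.integers(0, 2, n_rep), np.arange(n_rep)]
            alleles[m] = np.array([hm, hf])
        for a, b in pairs:
            pick_a = alleles[a][rng.integers(0, 2, n_rep), np.arange(n_rep)]
            pick_b = alleles[b][rng.integers(0, 2, n_rep), np.arange(n_rep)]
            phi_hat = float(np.mean(pick_a == pick_b))
            phi_exp = expected_kinship(ped, a, b)[0]
            assert phi_hat == pytest.approx(phi_exp, abs=0.01)


class TestPedigreeStructure:
    def test_cycle_rejected(self):
        ped = Pedigree()
        ped.add_trio("b", "a", None)
        with pytest.raises(ValueError, match="cycle"):
            ped.add_trio("a", "b", None)

    def test_read_tsv(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text("child\tmom\tdad\norphan\t0\t0\nhalf\tmom\t0\n")
        ped = read_pedigree_tsv(path)
        assert ped.parents("child") == ("mom", "dad")
        assert ped.parents("orphan") == (None, None)
        assert ped.parents("half") == ("mom", None)


class TestUniparentalProfile:
    def test_y_requires_male(self):
        with pytest.raises(ValueError, match="not M"):
            UniparentalProfile("x", "H1", "R1b", "F")

    def test_valid(self):
        UniparentalProfile("x", "H1", "R1b", "M")
        UniparentalProfile("x", "H1", None, "F")


class TestConsistencyRules:
    def _setup(self, child_mt="H1", son_y="G2", mother_sex="F", degree="first",
               r_obs=0.5):
        ped = Pedigree()
        ped.add_trio("son", "mother", "father")
        profiles = {
            "mother": UniparentalProfile("mother", "H1", None, mother_sex),
            "father": UniparentalProfile("father", "U5", "G2", "M"),
            "son": UniparentalProfile("son", child_mt, son_y, "M"),
        }
        table = pd.DataFrame({
            "id_a": ["mother", "father", "mother"],
            "id_b": ["son", "son", "father"],
            "r": [r_obs, 0.5, 0.0],
            "se_r": [0.01, 0.01, 0.01],
            "degree": [degree, "first", "unrelated"],
        })
        return ped, profiles, table

    def _violations(self, findings, rule):
        sel = findings[(findings.rule_id == rule)
                       & (findings.status == "violation")]
        return len(sel)

    def test_all_consistent(self):
        findings = check_consistency(*self._setup())
        assert (findings["status"] == "ok").all()

    def test_r1_mt_violation(self):
        findings = check_consistency(*self._setup(child_mt="K1"))
        assert self._violations(findings, "R1") == 1

    def test_r2_y_violation(self):
        findings = check_consistency(*self._setup(son_y="I2"))
        assert self._violations(findings, "R2") == 1

    def test_r3_degree_violation(self):
        findings = check_consistency(
            *self._setup(degree="unrelated", r_obs=0.0)
        )
        assert self._violations(findings, "R3") >= 1

    def test_r3_unresolved_near_expected_ok(self):
        findings = check_consistency(
            *self._setup(degree="unresolved", r_obs=0.36)
        )
        assert self._violations(findings, "R3") == 0

    def test_r4_mother_sex_violation(self):
        findings = check_consistency(*self._setup(mother_sex="M"))
        assert self._violations(findings, "R4") == 1

    def test_unsampled_parent_exempt(self):
        ped, profiles, table = self._setup()
        del profiles["mother"]
        findings = check_consistency(ped, profiles, table)
        assert (findings["status"] == "ok").all()
        assert not (findings["involved"] == "mother->son").any() or (
            findings.loc[findings.involved == "mother->son", "rule_id"]
            .isin(["R3"]).all()
        )


class TestLineageDiversity:
    def test_counts(self):
        profiles = [
            UniparentalProfile("a", "H1", "G2", "M"),
            UniparentalProfile("b", "H1", "I2", "M"),
            UniparentalProfile("c", "U5", None, "F"),
        ]
        n_mt, n_y, tallies = lineage_diversity(profiles)
        assert n_mt == 2
        assert n_y == 2
        assert tallies["mt"] == {"H1": 2, "U5": 1}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lineage_diversity([])


def test_unrelated_fraction():
    table = pd.DataFrame({
        "id_a": ["a", "a", "c"],
        "id_b": ["b", "c", "d"],
        "degree": ["first", "unrelated", "third"],
    })
    cohort = ["a", "b", "c", "d", "e", "f"]
    # close: a, b, c, d -> 2 of 6 unrelated
    assert unrelated_fraction(table, cohort) == pytest.approx(2 / 6)
    with pytest.raises(ValueError):
        unrelated_fraction(table, [])


def test_to_dot_contains_members():
    ped = family()
    profiles = {
        "dad": UniparentalProfile("dad", "H1", "G2", "M"),
        "child1": UniparentalProfile("child1", "U5", None, "F"),
    }
    dot = to_dot([ped], profiles)
    assert '"dad" -> "child1"' in dot
    assert dot.startswith("digraph")
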