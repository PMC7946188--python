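"""Pedigree kinship expectations and consistency checks.

Pedigrees are parent->child DAGs with optional unsampled founders. Expected
kinship coefficients come from the standard recursion

    phi(a, a) = (1 + F_a) / 2,  F_a = phi(father_a, mother_a)
    phi(a, b) = (phi(father_b, a) + phi(mother_b, a)) / 2   (b not ancestor of a)

with founders mutually unrelated. Consistency rules check a proposed pedigree
against genetic observations: maternal mtDNA transmission, paternal Y
transmission, pairwise degree classes, and parental sex roles. Relationships
with equal kinship (half-siblings, avuncular, grandparent-grandchild, all
phi = 1/8) are a single equivalence class for autosomal data and are only
separable by uniparental markers, sex, or age — the checks preserve that
ambiguity rather than resolving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import CLOSE_DEGREES, DEFAULT_DEGREE_WINDOWS


@dataclass(frozen=True)
class UniparentalProfile:
    individual_id: str
    mt_lineage: str
    y_lineage: str | None
    sex_call: str

    def __post_init__(self):
        if self.y_lineage is not None and self.sex_call != "M":
            raise ValueError(
                f"{self.individual_id}: Y lineage present but sex is not M"
            )


@dataclass
class Pedigree:
    """members: ids (sampled or placeholder founders); parents: child -> (mother, father)."""

    members: set[str] = field(default_factory=set)
    mothers: dict[str, str] = field(default_factory=dict)
    fathers: dict[str, str] = field(default_factory=dict)
    sexes: dict[str, str] = field(default_factory=dict)  # optional, for R4

    def add_trio(self, child: str, mother: str | None, father: str | None) -> None:
        self.members.add(child)
        if mother:
            self.members.add(mother)
            self.mothers[child] = mother
        if father:
            self.members.add(father)
            self.fathers[child] = father
        self._check_acyclic()

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self.mothers.get(ind), self.fathers.get(ind)

    def _check_acyclic(self) -> None:
        seen_state: dict[str, int] = {}

        def visit(node: str) -> None:
            state = seen_state.get(node, 0)
            if state == 1:
                raise ValueError(f"pedigree cycle involving {node!r}")
            if state == 2:
                return
            seen_state[node] = 1
            for p in self.parents(node):
                if p is not None:
                    visit(p)
            seen_state[node] = 2

        for m in self.members:
            visit(m)


def read_pedigree_tsv(path) -> Pedigree:
    """TSV trio format: child, mother-or-0, father-or-0 (tab separated)."""
    ped = Pedigree()
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "mother", "father"],
                     dtype=str, comment="#")
    for r in df.itertuples():
        mother = None if r.mother in ("0", None) else r.mother
        father = None if r.father in ("0", None) else r.father
        ped.add_trio(r.child, mother, father)
    return ped


def expected_kinship(ped: Pedigree, id_a: str, id_b: str) -> tuple[float, float]:
    """Kinship coefficient phi and expected relatedness r = 2*phi."""
    for i in (id_a, id_b):
        if i not in ped.members:
            raise KeyError(f"{i!r} not in pedigree")

    depth_cache: dict[str, int] = {}

    def depth(n: str) -> int:
        if n not in depth_cache:
            ps = [p for p in ped.parents(n) if p is not None]
            depth_cache[n] = 0 if not ps else 1 + max(depth(p) for p in ps)
        return depth_cache[n]

    cache: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        if a == b:
            mo, fa = ped.parents(a)
            f_a = phi(fa, mo) if (mo and fa) else 0.0
            val = 0.5 * (1.0 + f_a)
        else:
            # recurse on the individual with the deeper pedigree so the
            # recursion never ascends through the other's descendants
            if depth(a) < depth(b):
                a, b = b, a
            mo, fa = ped.parents(a)
            val = 0.0
            if mo:
                val += 0.5 * phi(mo, b)
            if fa:
                val += 0.5 * phi(fa, b)
        cache[key] = val
        return val

    k = phi(id_a, id_b)
    return k, 2.0 * k


def _expected_degree(r_expected: float) -> str:
    for degree, (lo, hi) in DEFAULT_DEGREE_WINDOWS.items():
        if lo <= r_expected < hi:
            return degree
    return "unrelated"


_DEGREE_ORDER = {"identical": 0, "first": 1, "second": 2, "third": 3, "unrelated": 4}


def check_consistency(
    ped: Pedigree,
    profiles: dict[str, UniparentalProfile],
    kinship_table: pd.DataFrame,
) -> pd.DataFrame:
    """Check a proposed pedigree against genetic observations.

    Rules: R1 child shares the mother's mt lineage; R2 a son shares the
    father's Y lineage; R3 each in-pedigree pair's observed degree class
    matches the expected r window (one class of slack when the estimate is
    boundary-flagged "unresolved"); R4 parental roles match sex calls.
    Unsampled founders (no profile) are exempt from R1/R2/R4.
    """
    findings: list[dict] = []

    def emit(rule, who, status, detail=""):
        findings.append(
            {"rule_id": rule, "involved": who, "status": status, "detail": detail}
        )

    for child in sorted(ped.mothers):
        mother = ped.mothers[child]
        pc, pm = profiles.get(child), profiles.get(mother)
        if pc and pm:
            ok = pc.mt_lineage == pm.mt_lineage
            emit("R1", f"{mother}->{child}", "ok" if ok else "violation",
                 "" if ok else f"mt {pc.mt_lineage} != mother's {pm.mt_lineage}")
    for child in sorted(ped.fathers):
        father = ped.fathers[child]
        pc, pf = profiles.get(child), profiles.get(father)
        if pc and pf and pc.sex_call == "M":
            ok = pc.y_lineage == pf.y_lineage
            emit("R2", f"{father}->{child}", "ok" if ok else "violation",
                 "" if ok else f"Y {pc.y_lineage} != father's {pf.y_lineage}")

    pair_lookup: dict[tuple[str, str], pd.Series] = {}
    for row in kinship_table.itertuples():
        key = tuple(sorted((row.id_a, row.id_b)))
        pair_lookup[key] = row
    sampled = sorted(m for m in ped.members if m in profiles)
    for i, a in enumerate(sampled):
        for b in sampled[i + 1:]:
            row = pair_lookup.get((a, b))
            if row is None or row.degree == "unclassified":
                continue
            _, r_exp = expected_kinship(ped, a, b)
            exp_deg = _expected_degree(r_exp)
            if row.degree == exp_deg:
                emit("R3", f"{a}~{b}", "ok")
            elif row.degree == "unresolved":
                # boundary-flagged estimate: accept if within one class
                near = abs(_DEGREE_ORDER[exp_deg] - _nearest_order(row.r)) <= 1
                emit("R3", f"{a}~{b}", "ok" if near else "violation",
                     f"unresolved r={row.r:.3f}, expected {exp_deg}")
            else:
                emit("R3", f"{a}~{b}", "violation",
                     f"observed {row.degree} (r={row.r:.3f}), expected {exp_deg}")

    for child, mother in sorted(ped.mothers.items()):
        pm = profiles.get(mother)
        if pm and pm.sex_call == "M":
            emit("R4", f"{mother}->{child}", "violation",
                 "proposed mother has male sex call")
        elif pm:
            emit("R4", f"{mother}->{child}", "ok")
    for child, father in sorted(ped.fathers.items()):
        pf = profiles.get(father)
        if pf and pf.sex_call == "F":
            emit("R4", f"{father}->{child}", "violation",
                 "proposed father has female sex call")
        elif pf:
            emit("R4", f"{father}->{child}", "ok")

    return pd.DataFrame(findings, columns=["rule_id", "involved", "status", "detail"])


def _nearest_order(r_obs: float) -> int:
    expected = {"identical": 1.0, "first": 0.5, "second": 0.25, "third": 0.125,
                "unrelated": 0.0}
    best = min(expected, key=lambda d: abs(expected[d] - r_obs))
    return _DEGREE_ORDER[best]


def lineage_diversity(profiles: list[UniparentalProfile]):
    """Distinct mtDNA and Y lineage counts (Y counted among males only)."""
    if not profiles:
        raise ValueError("no profiles")
    mt_counts: dict[str, int] = {}
    y_counts: dict[str, int] = {}
    for p in profiles:
        mt_counts[p.mt_lineage] = mt_counts.get(p.mt_lineage, 0) + 1
        if p.sex_call == "M" and p.y_lineage is not None:
            y_counts[p.y_lineage] = y_counts.get(p.y_lineage, 0) + 1
    return len(mt_counts), len(y_counts), {"mt": mt_counts, "y": y_counts}


def unrelated_fraction(kinship_table: pd.DataFrame, cohort: list[str]) -> float:
    """Fraction of the cohort with no relative at 3rd degree or closer."""
    close = set()
    for row in kinship_table.itertuples():
        if row.degree in CLOSE_DEGREES:
            close.add(row.id_a)
            close.add(row.id_b)
    if not cohort:
        raise ValueError("empty cohort")
    return sum(1 for i in cohort if i not in close) / len(cohort)


def to_dot(
    pedigrees: list[Pedigree], profiles: dict[str, UniparentalProfile]
) -> str:
    """GraphViz export of pedigrees with mt-lineage colouring."""
    palette = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
               "#ffff33", "#a65628", "#f781bf", "#999999"]
    lineages = sorted({p.mt_lineage for p in profiles.values()})
    colour = {lin: palette[i % len(palette)] for i, lin in enumerate(lineages)}
    lines = ["digraph pedigrees {", "  node [style=filled];"]
    for pi, ped in enumerate(pedigrees):
        lines.append(f"  subgraph cluster_{pi} {{")
        for m in sorted(ped.members):
            prof = profiles.get(m)
            shape = "plaintext"
            fill = "#ffffff"
            if prof:
                shape = "box" if prof.sex_call == "M" else "ellipse"
                fill = colour[prof.mt_lineage]
            lines.append(f'    "{m}" [shape={shape}, fillcolor="{fill}"];')
        for child, mo in sorted(ped.mothers.items()):
            lines.append(f'    "{mo}" -> "{child}";')
        for child, fa in sorted(ped.fathers.items()):
            lines.append(f'    "{fa}" -> "{child}";')
        lines.append("  }")
    lines.append("}")
    return "\n".join(lines)
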