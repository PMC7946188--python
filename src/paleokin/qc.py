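"""Ancient-DNA authenticity screening and genetic sex assignment.

Implements four count-based authenticity criteria commonly applied to
1240k-capture ancient DNA libraries:

1. terminal C->T deamination damage rate >= 3% (signature of authentic aDNA);
2. mtDNA consensus match rate with 95% CI upper bound > 98%;
3. X-chromosome polymorphism rate (males only, >= 200 sites covered >= 2x)
   with 95% CI lower bound < 1%;
4. genetic sex from the Y / (X+Y) read ratio: male > 35%, female < 3%.

Confidence bounds use the Wilson score interval by default (well behaved at
extreme proportions); Clopper-Pearson is available via ``ci_method``.
Criteria that cannot be evaluated (zero denominators, females for the X test)
are reported as ``not_evaluable`` and never fail an individual outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

PASS = "pass"
FAIL = "fail"
NOT_EVALUABLE = "not_evaluable"

DAMAGE_MIN_RATE = 0.03
MT_CI_UPPER_MIN = 0.98
X_CI_LOWER_MAX = 0.01
X_MIN_SITES = 200
SEX_MALE_MIN_RATIO = 0.35
SEX_FEMALE_MAX_RATIO = 0.03

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


@dataclass(frozen=True)
class ReadCountSummary:
    """Per-individual read-count inputs to the authenticity criteria."""

    individual_id: str
    terminal_ct_damaged: int
    terminal_ct_total: int
    mt_match: int
    mt_total: int
    x_poly_sites: int
    x_sites_ge2x: int
    y_reads: int
    xy_reads: int

    def __post_init__(self):
        pairs = [
            ("terminal_ct_damaged", "terminal_ct_total"),
            ("mt_match", "mt_total"),
            ("x_poly_sites", "x_sites_ge2x"),
            ("y_reads", "xy_reads"),
        ]
        for num, den in pairs:
            k, n = getattr(self, num), getattr(self, den)
            if k < 0 or n < 0:
                raise ValueError(f"{self.individual_id}: negative count {num}/{den}")
            if k > n:
                raise ValueError(f"{self.individual_id}: {num} > {den}")


def _ci(count: int, nobs: int, ci_method: str) -> tuple[float, float]:
    try:
        method = _CI_METHODS[ci_method]
    except KeyError:
        raise ValueError(f"unknown ci_method {ci_method!r}") from None
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=method)
    return float(lo), float(hi)


def damage_check(damaged: int, total: int) -> tuple[float | None, str]:
    """Terminal-deamination criterion: damage rate of at least 3%."""
    if total == 0:
        return None, NOT_EVALUABLE
    rate = damaged / total
    return rate, (PASS if rate >= DAMAGE_MIN_RATE else FAIL)


def mt_consensus_check(
    match: int, total: int, ci_method: str = "wilson"
) -> tuple[float | None, float | None, str]:
    """mtDNA contamination criterion: CI upper bound of match rate > 98%."""
    if total == 0:
        return None, None, NOT_EVALUABLE
    rate = match / total
    _, upper = _ci(match, total, ci_method)
    return rate, upper, (PASS if upper > MT_CI_UPPER_MIN else FAIL)


def x_contamination_check(
    x_poly_sites: int,
    x_sites_ge2x: int,
    sex_call: str,
    ci_method: str = "wilson",
) -> tuple[float | None, float | None, str]:
    """X-polymorphism criterion, evaluable only for males with >= 200 sites.

    Males carry one X, so sites showing both alleles at >= 2x coverage indicate
    contamination (or error); requires the CI lower bound of that rate < 1%.
    """
    if sex_call != "M" or x_sites_ge2x < X_MIN_SITES:
        return None, None, NOT_EVALUABLE
    rate = x_poly_sites / x_sites_ge2x
    lower, _ = _ci(x_poly_sites, x_sites_ge2x, ci_method)
    return rate, lower, (PASS if lower < X_CI_LOWER_MAX else FAIL)


def assign_sex(y_reads: int, xy_reads: int) -> tuple[float | None, str]:
    """Genetic sex from the fraction of Y among X+Y mapped reads."""
    if xy_reads == 0:
        return None, "U"
    ratio = y_reads / xy_reads
    if ratio > SEX_MALE_MIN_RATIO:
        return ratio, "M"
    if ratio < SEX_FEMALE_MAX_RATIO:
        return ratio, "F"
    return ratio, "U"


def run_qc(
    summaries: list[ReadCountSummary], ci_method: str = "wilson"
) -> pd.DataFrame:
    """Apply all four criteria to a cohort; one row per individual.

    ``overall`` is True only if the damage criterion passes and no other
    criterion fails; not_evaluable criteria are reported but do not fail an
    individual. The returned frame carries a ``sex_tally`` attribute.
    """
    if not summaries:
        raise ValueError("empty cohort")
    ids = [s.individual_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in QC input")

    rows = []
    for s in summaries:
        dmg_rate, dmg = damage_check(s.terminal_ct_damaged, s.terminal_ct_total)
        mt_rate, mt_upper, mt = mt_consensus_check(s.mt_match, s.mt_total, ci_method)
        sex_ratio, sex = assign_sex(s.y_reads, s.xy_reads)
        x_rate, x_lower, xc = x_contamination_check(
            s.x_poly_sites, s.x_sites_ge2x, sex, ci_method
        )
        reasons = []
        if dmg != PASS:
            reasons.append("damage")
        if mt == FAIL:
            reasons.append("mt_consensus")
        if xc == FAIL:
            reasons.append("x_contamination")
        rows.append(
            {
                "individual_id": s.individual_id,
                "damage_rate": dmg_rate,
                "damage_pass": dmg == PASS,
                "mt_match_rate": mt_rate,
                "mt_ci_upper": mt_upper,
                "mt_pass": mt,
                "x_poly_rate": x_rate,
                "x_ci_lower": x_lower,
                "x_contam_pass": xc,
                "y_ratio": sex_ratio,
                "sex_call": sex,
                "overall": dmg == PASS and mt != FAIL and xc != FAIL,
                "reasons": ";".join(reasons),
            }
        )
    report = pd.DataFrame(rows).set_index("individual_id")
    report.attrs["sex_tally"] = report["sex_call"].value_counts().to_dict()
    return report


def read_counts_tsv(path) -> list[ReadCountSummary]:
    """Load ReadCountSummary rows from a TSV with the documented header."""
    df = pd.read_csv(path, sep="\t")
    required = [
        "individual_id", "terminal_ct_damaged", "terminal_ct_total",
        "mt_match", "mt_total", "x_poly_sites", "x_sites_ge2x",
        "y_reads", "xy_reads",
    ]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ReadCountSummary(
            str(r.individual_id),
            int(r.terminal_ct_damaged), int(r.terminal_ct_total),
            int(r.mt_match), int(r.mt_total),
            int(r.x_poly_sites), int(r.x_sites_ge2x),
            int(r.y_reads), int(r.xy_reads),
        )
        for r in df.itertuples()
    ]
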