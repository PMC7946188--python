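"""End-to-end cohort analysis: QC -> sex tally -> kinship -> pedigree checks
-> lineage diversity -> ROH/Ne -> optional admixture.

One seed drives the whole run through named substreams, so a rerun with the
same config is identical. Inputs either come from files (EIGENSTRAT
genotypes, read-count TSV, uniparental-profile TSV, ROH TSV, frequency-table
TSV) or from the built-in synthetic preset with planted ground truth. Every
reported number is the direct output of one module; the pipeline adds no
computation of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture as adm
from . import eigenstrat as eig
from . import kinship as kin
from . import pedigree as ped
from . import qc as qcmod
from . import roh as rohmod
from . import simulate as sim

log = logging.getLogger("paleokin")


@dataclass
class RunConfig:
    seed: int
    output_dir: str | None = None
    # synthetic preset: "potocani-like" generates all inputs with known truth
    preset: str | None = None
    preset_n_snps: int = 200_000
    preset_true_ne: float = 5000.0
    # file inputs (ignored when preset is set)
    geno: str | None = None
    snp: str | None = None
    ind: str | None = None
    read_counts: str | None = None
    profiles: str | None = None
    roh_segments: str | None = None
    pedigree_trios: str | None = None
    freq_table: str | None = None
    admix_target: str | None = None
    admix_sources: list[str] = field(default_factory=list)
    admix_outgroups: list[str] = field(default_factory=list)
    # thresholds
    ci_method: str = "wilson"
    min_baseline_snps: int = kin.DEFAULT_MIN_BASELINE_SNPS
    min_pair_overlap: int = kin.DEFAULT_MIN_PAIR_OVERLAP
    block_cm: float = 5.0
    roh_min_snps: int = rohmod.DEFAULT_MIN_SNPS

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _substreams(seed: int, n: int) -> list[int]:
    """Named substream seeds derived from the single run seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _load_inputs(config: RunConfig):
    """Stage 0: assemble genotypes, read counts, profiles, ROH and pedigrees."""
    if config.preset == "potocani-like":
        s_geno, s_counts, s_roh = _substreams(config.seed, 3)
        spec = sim.fig5_cohort_spec()
        matrix, truth = sim.simulate_cohort(
            spec, n_snps=config.preset_n_snps, seed=s_geno
        )
        counts = sim.simulate_read_counts(spec.sexes_of_sampled(), seed=s_counts)
        profiles = spec.profiles()
        segments = sim.simulate_roh_lengths(
            config.preset_true_ne, n_individuals=len(spec.sampled), seed=s_roh
        )
        # relabel simulated genomes to the cohort ids
        id_map = {f"sim_{i:04d}": ind for i, ind in enumerate(spec.sampled)}
        segments = [
            rohmod.ROHSegment(id_map[s.individual_id], s.chromosome,
                              s.start_cm, s.end_cm)
            for s in segments
        ]
        pedigrees = [spec.pedigree()]
        # ROH eligibility floor rescaled to the thinned synthetic panel
        roh_min = int(round(config.preset_n_snps * 400_000 / 1_240_000))
        return matrix, counts, profiles, segments, pedigrees, roh_min, truth
    if config.preset is not None:
        raise ValueError(f"unknown preset {config.preset!r}")

    if not (config.geno and config.snp and config.ind):
        raise ValueError("geno/snp/ind paths are required without a preset")
    matrix = eig.read_eigenstrat(config.geno, config.snp, config.ind)
    counts = (
        qcmod.read_counts_tsv(config.read_counts) if config.read_counts else None
    )
    profiles = None
    if config.profiles:
        df = pd.read_csv(config.profiles, sep="\t")
        profiles = {
            str(r.individual_id): ped.UniparentalProfile(
                str(r.individual_id), str(r.mt_lineage),
                None if pd.isna(r.y_lineage) or r.y_lineage in ("", "0")
                else str(r.y_lineage),
                str(r.sex_call),
            )
            for r in df.itertuples()
        }
    segments = (
        rohmod.read_roh_tsv(config.roh_segments) if config.roh_segments else None
    )
    pedigrees = (
        [ped.read_pedigree_tsv(config.pedigree_trios)]
        if config.pedigree_trios else []
    )
    return matrix, counts, profiles, segments, pedigrees, config.roh_min_snps, None


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the cohort report as a JSON-serialisable dict.

    Partial results are kept in the report as stages complete; a stage error
    aborts the run with the stage name in the exception message.
    """
    report: dict = {
        "provenance": {"seed": config.seed, "config_hash": config.config_hash()}
    }
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage("load")
        (matrix, counts, profiles, segments, pedigrees, roh_min,
         truth) = _load_inputs(config)
        report["n_individuals"] = matrix.n_individuals
        report["n_snps"] = matrix.n_snps

        if counts is not None:
            stage("qc")
            qc_report = qcmod.run_qc(counts, ci_method=config.ci_method)
            report["sex_tally"] = qc_report.attrs["sex_tally"]
            report["qc_overall_pass"] = int(qc_report["overall"].sum())
            if outdir:
                qc_report.to_csv(outdir / "qc_report.tsv", sep="\t")

        stage("kinship")
        if matrix.ploidy_mode == eig.DIPLOID:
            (s_ph,) = _substreams(config.seed + 1, 1)
            ph = eig.pseudo_haploidize(matrix, seed=s_ph)
        else:
            ph = matrix
        kcfg = kin.KinshipConfig(
            seed=config.seed,
            min_baseline_snps=min(
                config.min_baseline_snps, int(0.5 * matrix.n_snps)
            ),
            min_pair_overlap=min(
                config.min_pair_overlap, int(0.1 * matrix.n_snps)
            ),
            block_cm=config.block_cm,
        )
        table, calib, rmat = kin.kinship_table(ph, kcfg)
        report["baseline_mismatch"] = calib.base
        report["n_close_kin_individuals"] = table.attrs["n_close_kin"]
        report["close_kin_ids"] = table.attrs["close_kin_ids"]
        report["unrelated_fraction"] = ped.unrelated_fraction(
            table, matrix.individual_ids
        )
        if outdir:
            table.drop(columns=[], errors="ignore").to_csv(
                outdir / "kinship.tsv", sep="\t", index=False
            )
            rmat.to_csv(outdir / "kinship_r_matrix.csv")

        if profiles:
            stage("pedigree")
            findings = []
            for pg in pedigrees:
                findings.append(ped.check_consistency(pg, profiles, table))
            if findings:
                fdf = pd.concat(findings, ignore_index=True)
                report["pedigree_violations"] = int(
                    (fdf["status"] == "violation").sum()
                )
                if outdir:
                    fdf.to_csv(outdir / "pedigree_findings.tsv", sep="\t",
                               index=False)
            n_mt, n_y, _ = ped.lineage_diversity(list(profiles.values()))
            report["n_mt_lineages"] = n_mt
            report["n_y_lineages"] = n_y

        if segments is not None:
            stage("roh")
            coverage = eig.snp_coverage(matrix)
            summary = rohmod.summarize_roh(segments, coverage, min_snps=roh_min)
            flags = rohmod.flag_inbreeding(summary[summary["eligible"]])
            report["n_roh_eligible"] = int(summary["eligible"].sum())
            report["n_inbreeding_flags"] = int(flags.sum())
            report["n_without_roh_gt4"] = int(
                (summary.loc[summary["eligible"], "sum_gt4"] == 0).sum()
            )
            ne = rohmod.ne_mle(summary)
            report["ne_hat"] = ne.ne_hat
            report["ne_ci_low"] = ne.ci_low
            report["ne_ci_high"] = ne.ci_high
            report["ne_total_segments_4_20"] = ne.total_segments_4_20
            if outdir:
                summary.to_csv(outdir / "roh_summary.tsv", sep="\t")

        if config.freq_table and config.admix_target:
            stage("admixture")
            ftab = adm.read_freq_table(config.freq_table)
            model = adm.qpadm_lite(
                ftab, config.admix_target, config.admix_sources,
                config.admix_outgroups, block_cm=config.block_cm,
            )
            report["admixture"] = {
                "sources": list(model.sources),
                "weights": [float(w) for w in model.weights],
                "se_weights": [float(s) for s in model.se_weights],
                "feasible": model.feasible,
            }

        if truth is not None:
            report["truth"] = {
                "close_kin_ids": truth["close_kin_ids"],
                "true_ne": config.preset_true_ne,
            }
    except Exception as exc:  # annotate failing stage, keep partials on disk
        if outdir:
            (outdir / "report_partial.json").write_text(
                json.dumps(report, indent=2, default=str)
            )
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )
    return report
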