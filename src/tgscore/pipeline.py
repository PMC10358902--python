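"""End-to-end discovery pipeline: QC -> screen -> confirm -> score -> regress.

Stage order is fixed: probe-consistency filtering and participant drops
happen before any statistics; monomorphic SNPs are removed; training-arm
responders are classified against the group mean percent improvement
computed over QC-surviving participants; the chi-square screen bands
candidates; ANOVA confirms them on response magnitude; SNPs whose cohort
frequencies deviate from the population expectation are excluded before
scoring; favorable alleles are assigned; per-participant totals are summed
and regressed against percent improvement.  All counts are book-kept into a
:class:`RunReport` and every intermediate artifact can be written out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from tgscore.genotype_io import (
    GenotypePanel,
    QCAudit,
    filter_inconsistent,
    read_genotypes,
    read_snp_metadata,
    remove_monomorphic,
)
from tgscore.phenotype import (
    CooperRecord,
    ResponseRecord,
    TrainingSession,
    compute_responses,
    dichotomize_responders,
    read_diary,
    read_phenotypes,
    training_load_summary,
)
from tgscore.popgen import FisherResult, flag_population_outliers
from tgscore.screen import (
    ScreenResult,
    anova_confirm,
    assign_favorable_allele,
    chi_square_screen,
)
from tgscore.scoring import AlleleScore, RegressionResult, score_all, score_regression, baseline_regression
from tgscore.stats import cohens_d_change, compare_groups, heterogeneity_test

logger = logging.getLogger("tgscore.pipeline")


@dataclass
class PipelineConfig:
    """Input paths, alpha levels and policy switches for a discovery run."""

    genotypes_path: str | Path | None = None
    meta_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    diary_path: str | Path | None = None
    out_dir: str | Path | None = None
    screen_alpha: float = 0.05
    secondary_band: tuple[float, float] = (0.051, 0.075)
    confirm_alpha: float = 0.05
    fisher_alpha: float = 0.05
    contingency_model: Literal["allele", "genotype"] = "allele"
    correction: Literal["none", "bonferroni", "bh"] = "none"
    missing_score_policy: Literal["zero", "exclude"] = "zero"
    missingness_ceiling: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("screen_alpha", "confirm_alpha", "fisher_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0,1), got {a}")


@dataclass
class RunReport:
    """Counts, per-SNP results, scores and regressions for one run."""

    counts: dict[str, int]
    screen: list[ScreenResult]
    fisher: list[FisherResult]
    scores: list[AlleleScore]
    responses: list[ResponseRecord]
    score_fit: RegressionResult | None
    baseline_fit: RegressionResult | None
    group_stats: dict
    audit: QCAudit

    def retained(self) -> list[ScreenResult]:
        return [r for r in self.screen if r.retained]

    def check_counts(self) -> None:
        c = self.counts
        assert c["input_snps"] == c["monomorphic_removed"] + c["polymorphic"], c
        assert c["final_snps"] <= c["anova_retained"] <= c["chi2_primary"] + c["chi2_secondary"], c
        assert c["final_snps"] == c["anova_retained"] - c["retained_population_excluded"] - c["favorable_unresolved"], c


def run_discovery(
    config: PipelineConfig,
    panel: GenotypePanel | None = None,
    phenotypes: Sequence[CooperRecord] | None = None,
    groups: dict[str, str] | None = None,
    diaries: Sequence[TrainingSession] | None = None,
) -> RunReport:
    """Execute the full discovery pipeline; inputs from memory or from paths.

    Raises on a participant-id mismatch between the genotype and phenotype
    inputs (listing the orphans).  Deterministic for fixed inputs/config.
    """
    if panel is None:
        meta = read_snp_metadata(config.meta_path)
        panel = read_genotypes(config.genotypes_path, meta, format="matrix")
    if phenotypes is None:
        phenotypes, groups = read_phenotypes(config.phenotypes_path)
    if groups is None:
        raise ValueError("group assignments required")
    if diaries is None and config.diary_path:
        diaries = read_diary(config.diary_path)

    pheno_ids = {r.participant_id for r in phenotypes}
    geno_ids = set(panel.participants)
    orphans = geno_ids - pheno_ids
    if orphans:
        raise ValueError(f"genotyped participants missing phenotypes: {sorted(orphans)}")

    counts: dict[str, int] = {"input_snps": panel.n_snps, "input_participants": len(panel.participants)}

    # --- QC: probe consistency, participant drops, monomorphic removal
    panel, audit = filter_inconsistent(panel, missingness_ceiling=config.missingness_ceiling)
    counts["participants_dropped"] = len(audit.dropped_participants)
    counts["inconsistent_calls"] = len(audit.inconsistent_calls)
    panel, n_mono = remove_monomorphic(panel)
    counts["monomorphic_removed"] = n_mono
    counts["polymorphic"] = panel.n_snps
    logger.info("QC: %d monomorphic removed, %d polymorphic retained, %d participants dropped",
                n_mono, panel.n_snps, counts["participants_dropped"])

    # --- responses: restrict to QC-surviving genotyped participants, re-classify
    responses_all = compute_responses(phenotypes, groups)
    kept = set(panel.participants)
    responses = dichotomize_responders(
        [r for r in responses_all if r.participant_id in kept or r.group == "CG"]
    )

    # --- population-frequency exclusions
    fisher = flag_population_outliers(panel, alpha=config.fisher_alpha)
    excluded_rsids = {f.rsid for f in fisher if f.excluded}
    counts["population_excluded"] = len(excluded_rsids)

    # --- screen and confirm
    screen = chi_square_screen(
        panel, responses,
        alpha=config.screen_alpha, secondary_band=config.secondary_band,
        model=config.contingency_model, correction=config.correction,
    )
    for r in screen:
        r.population_excluded = r.rsid in excluded_rsids
    counts["chi2_primary"] = sum(1 for r in screen if r.band == "primary")
    counts["chi2_secondary"] = sum(1 for r in screen if r.band == "secondary")
    screen = anova_confirm(panel, responses, screen, alpha=config.confirm_alpha)
    # significance before the population exclusion (the pre-exclusion count)
    pre_exclusion = [
        r for r in screen
        if r.band in ("primary", "secondary") and r.anova_p <= config.confirm_alpha
        and (np.isnan(r.levene_p) or r.levene_p > 0.05)
    ]
    counts["anova_retained"] = len(pre_exclusion)
    counts["retained_population_excluded"] = sum(1 for r in pre_exclusion if r.population_excluded)

    # --- favorable alleles
    unresolved = 0
    for r in screen:
        if r.retained and r.table is not None:
            r.favorable_allele = assign_favorable_allele(r.table)
            if r.favorable_allele is None:
                r.retained = False
                unresolved += 1
    counts["favorable_unresolved"] = unresolved
    final = [r for r in screen if r.retained]
    counts["final_snps"] = len(final)
    logger.info("screen: %d primary, %d secondary, %d confirmed, %d final",
                counts["chi2_primary"], counts["chi2_secondary"],
                counts["anova_retained"], counts["final_snps"])

    # --- scoring and regressions
    eg_kept = [r.participant_id for r in responses if r.group == "EG"]
    scores: list[AlleleScore] = []
    score_fit = baseline_fit = None
    if final:
        scores = score_all(panel, final, participants=eg_kept,
                           missing_policy=config.missing_score_policy)
        try:
            score_fit = score_regression(scores, responses)
        except ValueError as exc:
            logger.warning("score regression skipped: %s", exc)
    try:
        baseline_fit = baseline_regression(responses)
    except ValueError as exc:
        logger.warning("baseline regression skipped: %s", exc)
    counts["scored_participants"] = len(scores)

    # --- group statistics
    eg_pct = [r.pct_change for r in responses if r.group == "EG"]
    cg_pct = [r.pct_change for r in responses if r.group == "CG"]
    group_stats: dict = {}
    if len(eg_pct) >= 3 and len(cg_pct) >= 3:
        dec = compare_groups(eg_pct, cg_pct)
        het_eg, ci_eg = heterogeneity_test(eg_pct)
        het_cg, ci_cg = heterogeneity_test(cg_pct)
        eg_base = [r.baseline_km for r in responses if r.group == "EG"]
        cg_base = [r.baseline_km for r in responses if r.group == "CG"]
        eg_delta = [r.delta_km for r in responses if r.group == "EG"]
        cg_delta = [r.delta_km for r in responses if r.group == "CG"]
        group_stats = {
            "eg_mean_pct": float(np.mean(eg_pct)), "eg_sd_pct": float(np.std(eg_pct, ddof=1)),
            "cg_mean_pct": float(np.mean(cg_pct)), "cg_sd_pct": float(np.std(cg_pct, ddof=1)),
            "between": dataclasses.asdict(dec),
            "eg_heterogeneity": {"p": het_eg.p_value, "ci": ci_eg},
            "cg_heterogeneity": {"p": het_cg.p_value, "ci": ci_cg},
            "eg_effect_size": dataclasses.asdict(cohens_d_change(
                float(np.mean(eg_delta)), float(np.std(eg_base, ddof=1)),
                n=len(eg_delta), change_sd=float(np.std(eg_delta, ddof=1)))),
            "cg_effect_size": dataclasses.asdict(cohens_d_change(
                float(np.mean(cg_delta)), float(np.std(cg_base, ddof=1)),
                n=len(cg_delta), change_sd=float(np.std(cg_delta, ddof=1)))),
        }
        if diaries:
            eg_ids = {p for p, g in groups.items() if g == "EG"}
            eg_diary = [s for s in diaries if s.participant_id in eg_ids]
            cg_diary = [s for s in diaries if s.participant_id not in eg_ids]
            if eg_diary:
                group_stats["eg_load"] = dataclasses.asdict(training_load_summary(eg_diary))
            if cg_diary:
                group_stats["cg_load"] = dataclasses.asdict(training_load_summary(cg_diary))

    report = RunReport(
        counts=counts, screen=screen, fisher=fisher, scores=scores,
        responses=list(responses), score_fit=score_fit, baseline_fit=baseline_fit,
        group_stats=group_stats, audit=audit,
    )
    report.check_counts()
    if config.out_dir:
        write_report(report, panel, config.out_dir)
    return report


_CODING = {"missense", "synonymous", "stop-gain"}


def render_table1(report: RunReport, panel: GenotypePanel) -> pd.DataFrame:
    """Candidate-SNP table sorted by chi-square p ascending.

    Includes every SNP that passed both the band and ANOVA gates;
    population-excluded SNPs are annotated in the ``Excluded`` column rather
    than silently dropped.  Columns mirror a publication-style candidate
    list: SNP, Gene, Alleles, Type, Position, FisherExact, p_chi2, p_ANOVA,
    PositiveAllele, Coding, Excluded.
    """
    fisher_p = {f.rsid: f.p_value for f in report.fisher}
    rows = []
    for r in report.screen:
        if not (r.retained or (r.population_excluded and r.band != "none"
                               and r.anova_p <= 0.05)):
            continue
        m = panel.meta.get(r.rsid)
        if m is None:
            continue
        rows.append({
            "SNP": r.rsid,
            "Gene": m.gene,
            "Alleles": f"{m.ref_allele}>{m.alt_allele}",
            "Type": m.consequence,
            "Position": f"{m.chrom}:{m.pos}",
            "FisherExact": fisher_p.get(r.rsid, float("nan")),
            "p_chi2": r.chi2_p,
            "p_ANOVA": r.anova_p,
            "PositiveAllele": r.favorable_allele or "",
            "Coding": "Yes" if m.consequence in _CODING else "No",
            "Excluded": "Yes" if r.population_excluded else "No",
        })
    df = pd.DataFrame(rows, columns=["SNP", "Gene", "Alleles", "Type", "Position",
                                     "FisherExact", "p_chi2", "p_ANOVA",
                                     "PositiveAllele", "Coding", "Excluded"])
    return df.sort_values(["p_chi2", "SNP"]).reset_index(drop=True)


def write_report(report: RunReport, panel: GenotypePanel, out_dir: str | Path) -> None:
    """Write table1.csv, scores.csv, regression.json, stats.json, audit.csv, counts.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_table1(report, panel).to_csv(out / "table1.csv", index=False)
    retained_rsids = [r.rsid for r in report.retained()]
    score_rows = [
        {"participant_id": s.participant_id, "total": s.total, "n_missing": s.n_missing,
         **{rsid: s.per_snp.get(rsid, "") for rsid in retained_rsids}}
        for s in report.scores
    ]
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)
    reg = {}
    if report.score_fit:
        reg["score"] = dataclasses.asdict(report.score_fit)
    if report.baseline_fit:
        reg["baseline"] = dataclasses.asdict(report.baseline_fit)
    (out / "regression.json").write_text(json.dumps(reg, indent=1, sort_keys=True))
    (out / "stats.json").write_text(json.dumps(report.group_stats, indent=1, sort_keys=True, default=float))
    pd.DataFrame(report.audit.as_records()).to_csv(out / "audit.csv", index=False)
    (out / "counts.json").write_text(json.dumps(report.counts, indent=1, sort_keys=True))
    exclusions = [
        {"rsid": f.rsid, "p_value": f.p_value, "excluded": f.excluded,
         "reason": "population-frequency deviation" if f.excluded else ""}
        for f in report.fisher
    ]
    pd.DataFrame(exclusions).to_csv(out / "exclusions.csv", index=False)
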