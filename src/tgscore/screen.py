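"""Chi-square screen and ANOVA confirmation of trainability-associated SNPs.

Discovery proceeds in two passes over the polymorphic panel:

1. Every SNP is screened with Pearson's chi-square (no continuity
   correction) on a responder-class x allele-count contingency table.  SNPs
   land in a *primary* band (p <= 0.05), a *secondary* band (0.05 < p <=
   0.075), or neither.  No multiple-testing correction is applied by
   default — the screen is a deliberately permissive filter whose
   false-positive count grows with panel size; an optional
   Bonferroni/Benjamini-Hochberg switch exists for sensitivity analysis.

2. Because the class screen says nothing about response magnitude, banded
   candidates are confirmed by one-way ANOVA of the percent Cooper
   improvement across genotype groups, gated on Levene's homogeneity of
   variance.  A SNP is retained when its band is primary or secondary, its
   ANOVA p <= 0.05, and variances are homogeneous.

The "favorable" allele of a retained SNP is the allele whose relative
frequency is higher among responders than non-responders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from tgscore.genotype_io import GenotypePanel
from tgscore.phenotype import ResponseRecord

ContingencyModel = Literal["allele", "genotype"]
Band = Literal["primary", "secondary", "none"]


@dataclass(frozen=True)
class ContingencyTable:
    """Responder-class x allele (2x2) or genotype (2x3) count table.

    Rows are (responder, non-responder); columns follow ``labels`` — the two
    alleles in (ref, alt) order for the allele model, or genotype strings
    ordered by alternate-allele count for the genotype model.
    """

    rsid: str
    model: ContingencyModel
    labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], tuple[int, ...]]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


@dataclass
class ScreenResult:
    """Per-SNP screening and confirmation statistics."""

    rsid: str
    chi2_stat: float
    chi2_p: float
    band: Band
    anova_F: float = float("nan")
    anova_p: float = float("nan")
    levene_p: float = float("nan")
    favorable_allele: str | None = None
    population_excluded: bool = False
    retained: bool = False
    table: ContingencyTable | None = None
    adjusted_p: float | None = None


def _eg_classes(responses: Sequence[ResponseRecord]) -> dict[str, bool]:
    classes = {r.participant_id: r.responder for r in responses if r.group == "EG"}
    if any(v is None for v in classes.values()):
        raise ValueError("training-group responses are not yet dichotomized")
    return classes


def build_contingency(
    panel: GenotypePanel,
    responses: Sequence[ResponseRecord],
    rsid: str,
    model: ContingencyModel = "allele",
) -> ContingencyTable:
    """Count alleles (or genotypes) by responder class at one SNP.

    The allele model counts each participant's two allele copies; the
    genotype model counts participants per genotype class.  Participants
    with a missing call at this SNP are excluded from this SNP's table only.
    """
    classes = _eg_classes(responses)
    meta = panel.meta[rsid]
    ref, alt = meta.ref_allele, meta.alt_allele
    genos = panel.snp_genotypes(rsid)
    pairs = [(pid, genos[pid]) for pid in classes if pid in genos]
    if len(pairs) < 2:
        raise ValueError(f"{rsid}: fewer than 2 non-missing training-group participants")
    if model == "allele":
        labels = (ref, alt)
        counts = np.zeros((2, 2), dtype=int)
        for pid, geno in pairs:
            row = 0 if classes[pid] else 1
            for a in geno:
                if a == ref:
                    counts[row, 0] += 1
                elif a == alt:
                    counts[row, 1] += 1
                else:
                    raise ValueError(f"{rsid}: allele {a} not in panel alleles {ref}/{alt}")
    elif model == "genotype":
        labels = (ref + ref, "".join(sorted(ref + alt)), alt + alt)
        counts = np.zeros((2, 3), dtype=int)
        for pid, geno in pairs:
            row = 0 if classes[pid] else 1
            counts[row, geno.count(alt)] += 1
    else:
        raise ValueError(f"unknown contingency model {model!r}")
    return ContingencyTable(rsid, model, labels, tuple(map(tuple, counts)))


def pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; degenerate -> (0, 1)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 0.0, 1.0
    # drop all-zero columns (e.g. an allele absent from the EG entirely)
    arr = arr[:, arr.sum(axis=0) > 0]
    if arr.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def _classify_band(p: float, alpha: float, secondary_band: tuple[float, float]) -> Band:
    if p <= alpha:
        return "primary"
    if secondary_band[0] <= p <= secondary_band[1] or alpha < p <= secondary_band[1]:
        return "secondary"
    return "none"


def chi_square_screen(
    panel: GenotypePanel,
    responses: Sequence[ResponseRecord],
    alpha: float = 0.05,
    secondary_band: tuple[float, float] = (0.051, 0.075),
    model: ContingencyModel = "allele",
    correction: Literal["none", "bonferroni", "bh"] = "none",
) -> list[ScreenResult]:
    """Screen every polymorphic SNP for association with responder class.

    Returns one :class:`ScreenResult` per SNP, sorted by chi-square p-value
    ascending (rsid lexicographic tie-break).  ``correction`` optionally
    adjusts the banding p-values (Bonferroni or Benjamini-Hochberg) for
    sensitivity analysis; the default applies none.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel: nothing to screen")
    results = []
    for rsid in panel.rsids:
        try:
            table = build_contingency(panel, responses, rsid, model=model)
        except ValueError:
            results.append(ScreenResult(rsid, 0.0, 1.0, "none"))
            continue
        chi2, p = pearson_chi2(table)
        results.append(ScreenResult(rsid, chi2, p, "none", table=table))
    raw_p = np.array([r.chi2_p for r in results])
    if correction == "bonferroni":
        adj = np.minimum(raw_p * len(raw_p), 1.0)
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(raw_p, method="fdr_bh")[1]
    else:
        adj = raw_p
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
        r.band = _classify_band(float(a), alpha, secondary_band)
    results.sort(key=lambda r: (r.chi2_p, r.rsid))
    return results


def anova_confirm(
    panel: GenotypePanel,
    responses: Sequence[ResponseRecord],
    candidates: Sequence[ScreenResult],
    alpha: float = 0.05,
    levene_alpha: float = 0.05,
    small_group_policy: Literal["drop", "merge"] = "drop",
    min_group_size: int = 2,
) -> list[ScreenResult]:
    """Confirm banded SNPs by one-way ANOVA of percent improvement by genotype.

    For each candidate SNP the training-group percent Cooper changes are
    grouped by genotype; groups smaller than ``min_group_size`` are dropped
    (or merged into the heterozygote group with ``small_group_policy=
    "merge"``).  Levene's test gates homogeneity of variance.  A SNP is
    retained iff band in {primary, secondary}, ANOVA p <= ``alpha``, Levene
    p > ``levene_alpha``, and it is not population-excluded.
    """
    pct = {r.participant_id: r.pct_change for r in responses if r.group == "EG"}
    out = []
    for cand in candidates:
        res = replace_fields(cand)
        if cand.band == "none":
            out.append(res)
            continue
        genos = panel.snp_genotypes(cand.rsid)
        meta = panel.meta[cand.rsid]
        het = "".join(sorted(meta.ref_allele + meta.alt_allele))
        groups: dict[str, list[float]] = {}
        for pid, g in genos.items():
            if pid in pct:
                groups.setdefault(g, []).append(pct[pid])
        if small_group_policy == "merge":
            merged: dict[str, list[float]] = {}
            for g, vals in groups.items():
                if len(vals) < min_group_size and g != het:
                    merged.setdefault(het, []).extend(vals)
                else:
                    merged.setdefault(g, []).extend(vals)
            groups = merged
        groups = {g: v for g, v in groups.items() if len(v) >= min_group_size}
        if len(groups) < 2:
            res.anova_F, res.anova_p, res.levene_p = 0.0, 1.0, float("nan")
            res.retained = False
            out.append(res)
            continue
        samples = list(groups.values())
        if all(np.var(s) == 0 and np.mean(s) == np.mean(samples[0]) for s in samples):
            f_stat, f_p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, f_p = stats.f_oneway(*samples)
                lev_stat, lev_p = stats.levene(*samples, center="mean")
            res.levene_p = float(lev_p)
        res.anova_F = float(f_stat) if np.isfinite(f_stat) else 0.0
        res.anova_p = float(f_p) if np.isfinite(f_p) else 1.0
        res.retained = (
            cand.band in ("primary", "secondary")
            and res.anova_p <= alpha
            and (np.isnan(res.levene_p) or res.levene_p > levene_alpha)
            and not cand.population_excluded
        )
        out.append(res)
    return out


def replace_fields(r: ScreenResult) -> ScreenResult:
    return ScreenResult(
        rsid=r.rsid, chi2_stat=r.chi2_stat, chi2_p=r.chi2_p, band=r.band,
        anova_F=r.anova_F, anova_p=r.anova_p, levene_p=r.levene_p,
        favorable_allele=r.favorable_allele, population_excluded=r.population_excluded,
        retained=r.retained, table=r.table, adjusted_p=r.adjusted_p,
    )


def assign_favorable_allele(table: ContingencyTable) -> str | None:
    """The allele over-represented among responders, or ``None`` on a tie.

    Compares each allele's relative frequency in the responder row against
    the non-responder row.  Works on the allele-model table; a genotype
    table is first collapsed to allele counts.
    """
    arr = table.as_array()
    if table.model == "genotype":
        # columns ordered by alt-allele count 0,1,2
        ref_counts = 2 * arr[:, 0] + arr[:, 1]
        alt_counts = arr[:, 1] + 2 * arr[:, 2]
        arr = np.column_stack([ref_counts, alt_counts])
        labels = (table.labels[0][0], table.labels[2][0])
    else:
        labels = table.labels
    row_tot = arr.sum(axis=1)
    if (row_tot == 0).any():
        return None
    freq_resp = arr[0] / row_tot[0]
    freq_non = arr[1] / row_tot[1]
    diff = freq_resp - freq_non
    if np.isclose(diff[0], diff[1]) or np.isclose(diff.max(), 0.0):
        warnings.warn(f"{table.rsid}: allele frequencies tie between classes; unresolved",
                      stacklevel=2)
        return None
    return labels[int(np.argmax(diff))]
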