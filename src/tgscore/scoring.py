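"""Unweighted additive allele scoring and score-response regression.

Each retained SNP contributes the count of favorable-allele copies a
participant carries: homozygous favorable scores 2, heterozygous 1, and
homozygous for the other allele 0.  Per-SNP scores are summed into a total
genotype score, which is regressed (ordinary least squares) against the
percent improvement in Cooper 12-minute run distance.  The score is
deliberately unweighted — every favorable allele counts equally — matching
the additive model under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from tgscore.genotype_io import MISSING, GenotypePanel
from tgscore.phenotype import ResponseRecord
from tgscore.screen import ScreenResult


@dataclass(frozen=True)
class AlleleScore:
    """Per-participant favorable-allele count, per SNP and in total."""

    participant_id: str
    per_snp: dict[str, int]
    total: int
    n_missing: int

    def __post_init__(self) -> None:
        if self.total != sum(self.per_snp.values()):
            raise ValueError("total does not equal the sum of per-SNP scores")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of response on a single predictor."""

    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n: int


def score_genotype(genotype: str, favorable_allele: str) -> int:
    """Count favorable-allele copies in a genotype: 0, 1 or 2."""
    if genotype == MISSING:
        raise ValueError("cannot score a missing genotype")
    if len(genotype) != 2:
        raise ValueError(f"invalid genotype {genotype!r}")
    return genotype.count(favorable_allele)


def sum_scores(
    panel: GenotypePanel,
    retained: Sequence[ScreenResult],
    participant_id: str,
    missing_policy: Literal["zero", "exclude"] = "zero",
) -> AlleleScore | None:
    """Sum favorable-allele counts over the retained SNPs for one participant.

    Missing genotypes at retained SNPs are counted in ``n_missing`` and, by
    default, contribute 0 to the total; with ``missing_policy="exclude"`` a
    participant with any missing retained SNP gets ``None`` (the caller
    drops them, mirroring wholesale removal of inconsistent participants).
    """
    if participant_id not in panel.participants:
        raise KeyError(f"participant {participant_id!r} not in panel")
    scored = [r for r in retained if r.retained and r.favorable_allele is not None]
    if not scored:
        raise ValueError("no retained SNPs with an assigned favorable allele")
    per_snp: dict[str, int] = {}
    n_missing = 0
    for res in scored:
        geno = panel.genotype(participant_id, res.rsid)
        if geno == MISSING:
            n_missing += 1
            if missing_policy == "exclude":
                return None
            continue
        alleles = set(panel.meta[res.rsid].alleles)
        if not set(geno) <= alleles:
            raise ValueError(
                f"{res.rsid}: genotype {geno} of {participant_id} contains non-panel alleles"
            )
        per_snp[res.rsid] = score_genotype(geno, res.favorable_allele)
    return AlleleScore(
        participant_id=participant_id,
        per_snp=per_snp,
        total=sum(per_snp.values()),
        n_missing=n_missing,
    )


def score_all(
    panel: GenotypePanel,
    retained: Sequence[ScreenResult],
    participants: Sequence[str] | None = None,
    missing_policy: Literal["zero", "exclude"] = "zero",
) -> list[AlleleScore]:
    """Score every (or the given) panel participant; excluded ones dropped."""
    pids = participants if participants is not None else panel.participants
    scores = []
    for pid in pids:
        s = sum_scores(panel, retained, pid, missing_policy=missing_policy)
        if s is not None:
            scores.append(s)
    return scores


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) < 3:
        raise ValueError(f"need >=3 paired observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r2=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=len(x),
    )


def score_regression(
    scores: Sequence[AlleleScore], responses: Sequence[ResponseRecord]
) -> RegressionResult:
    """OLS of percent Cooper improvement on the total genotype score.

    Pairs scores with training-group responses by participant id; reports
    the slope, intercept, Pearson r, R^2 and the two-sided t-test p-value on
    the slope.
    """
    pct = {r.participant_id: r.pct_change for r in responses if r.group == "EG"}
    pairs = [(s.total, pct[s.participant_id]) for s in scores if s.participant_id in pct]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 scored training-group participants, got {len(pairs)}")
    x, y = map(np.asarray, zip(*pairs))
    return _ols(x.astype(float), y.astype(float))


def baseline_regression(responses: Sequence[ResponseRecord]) -> RegressionResult:
    """OLS of percent improvement on baseline Cooper distance (training arm).

    A negative slope indicates larger relative gains in participants who
    started less fit — the training-status effect.
    """
    eg = [r for r in responses if r.group == "EG"]
    if len(eg) < 3:
        raise ValueError(f"need >=3 training-group responses, got {len(eg)}")
    x = np.array([r.baseline_km for r in eg])
    y = np.array([r.pct_change for r in eg])
    return _ols(x, y)
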