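"""Hardy-Weinberg expected genotype frequencies and exact frequency tests.

Cohort allele frequencies are compared against published reference-population
frequencies: the published alternate-allele proportion gives Hardy-Weinberg
expected genotype counts (p^2, 2pq, q^2 at cohort size n), and an exact
conditional test compares the observed cohort counts against them.  With a
few dozen participants, and zero cells common, the asymptotic chi-square is
unreliable, so the exact test is used throughout.  A SNP whose cohort
frequencies differ from the population expectation at the chosen alpha is
flagged for exclusion (a likely genotyping or sampling artifact rather than
a trainability signal).

The two-sided exact p-value follows the standard convention: the sum of the
probabilities of all tables with the observed margins whose conditional
(multivariate hypergeometric) probability does not exceed the observed
table's.  For 2x2 tables this is Fisher's exact test; for 2x3 genotype
tables it is the Freeman-Halton extension, computed by full enumeration in
exact integer arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from math import comb
from typing import Literal, Sequence

import numpy as np

from tgscore.genotype_io import GenotypePanel


@dataclass(frozen=True)
class HWEExpectation:
    """Expected genotype proportions and counts under Hardy-Weinberg."""

    p: float  # reference-allele proportion
    n: int
    prop_ref_hom: float
    prop_het: float
    prop_alt_hom: float

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def proportions(self) -> tuple[float, float, float]:
        return (self.prop_ref_hom, self.prop_het, self.prop_alt_hom)

    @property
    def counts(self) -> tuple[float, float, float]:
        return tuple(self.n * x for x in self.proportions)

    def rounded_counts(self) -> tuple[int, int, int]:
        """Expected counts rounded to nearest integer (exact tests need integers)."""
        return tuple(int(round(c)) for c in self.counts)


def hwe_expected(p: float, n: int) -> HWEExpectation:
    """Hardy-Weinberg expected genotype frequencies at cohort size ``n``.

    ``p`` is the reference-allele proportion; genotype proportions are
    (p^2, 2p(1-p), (1-p)^2) for reference homozygote, heterozygote and
    alternate homozygote.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele proportion {p} outside [0,1]")
    if n < 1:
        raise ValueError(f"cohort size must be >=1, got {n}")
    q = 1.0 - p
    return HWEExpectation(p=p, n=n, prop_ref_hom=p * p, prop_het=2 * p * q, prop_alt_hom=q * q)


@dataclass(frozen=True)
class FisherResult:
    """Exact-test comparison of observed vs expected count vectors."""

    rsid: str
    table: tuple[tuple[int, ...], tuple[int, ...]]
    p_value: float
    excluded: bool


def exact_conditional_p(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact p for a 2xC contingency table by full enumeration.

    Conditions on both margins; enumerates every table with those margins,
    computing hypergeometric probabilities in exact integer arithmetic, and
    sums the probability of all tables no more probable than the observed
    one.  For C=2 this is Fisher's exact test; for C>2 the Freeman-Halton
    extension.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or tab.shape[0] != 2:
        raise ValueError(f"expected a 2xC table, got shape {tab.shape}")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    row1 = int(tab[0].sum())
    col_totals = tab.sum(axis=0).astype(int)
    total = int(tab.sum())
    if total == 0 or row1 == 0 or row1 == total or (col_totals == 0).all():
        return 1.0
    # weight(x) = prod_j C(c_j, x_j); P(table) = weight / C(N, r1)
    obs_weight = 1
    for c, x in zip(col_totals, tab[0]):
        obs_weight *= comb(int(c), int(x))
    denom = comb(total, row1)
    acc = 0
    ranges = [range(int(c) + 1) for c in col_totals[:-1]]
    last_cap = int(col_totals[-1])
    for head in product(*ranges):
        rest = row1 - sum(head)
        if 0 <= rest <= last_cap:
            w = 1
            for c, x in zip(col_totals[:-1], head):
                w *= comb(int(c), x)
            w *= comb(last_cap, rest)
            if w <= obs_weight:
                acc += w
    return min(acc / denom, 1.0)


def fisher_exact_counts(
    rsid: str,
    observed: Sequence[int],
    expected: Sequence[int],
    alpha: float = 0.05,
) -> FisherResult:
    """Exact test of observed vs expected genotype (or allele) counts.

    ``observed`` and ``expected`` are parallel count vectors (length 3 for
    genotype classes, 2 for alleles); ``expected`` must already be rounded
    to integers.  Classes with expected count 0 are collapsed to the 2x2
    allele representation by the caller (:func:`flag_population_outliers`).
    An all-zero row yields p = 1 with a warning.
    """
    obs = tuple(int(x) for x in observed)
    exp = tuple(int(x) for x in expected)
    if len(obs) != len(exp):
        raise ValueError("observed and expected must have the same length")
    if any(x < 0 for x in obs + exp):
        raise ValueError("counts must be non-negative")
    table = (obs, exp)
    if sum(obs) == 0 or sum(exp) == 0:
        warnings.warn(f"{rsid}: all-zero count row; exact test degenerate, p=1", stacklevel=2)
        return FisherResult(rsid, table, 1.0, excluded=False)
    p = exact_conditional_p(table)
    return FisherResult(rsid, table, p, excluded=p <= alpha)


def genotype_counts(panel: GenotypePanel, rsid: str) -> tuple[int, int, int]:
    """Observed (ref-hom, het, alt-hom) counts among non-missing calls."""
    meta = panel.meta[rsid]
    ref, alt = meta.ref_allele, meta.alt_allele
    counts = [0, 0, 0]
    for geno in panel.snp_genotypes(rsid).values():
        n_alt = geno.count(alt)
        n_ref = geno.count(ref)
        if n_alt + n_ref != 2:
            raise ValueError(f"{rsid}: genotype {geno} not composed of panel alleles {ref}/{alt}")
        counts[n_alt] = counts[n_alt] + 1
    return tuple(counts)


def flag_population_outliers(
    panel: GenotypePanel,
    alpha: float = 0.05,
    model: Literal["genotype", "allele"] = "genotype",
) -> list[FisherResult]:
    """Flag SNPs whose cohort frequencies deviate from population expectation.

    For each SNP with a published alternate-allele frequency, Hardy-Weinberg
    expected genotype counts at the cohort's non-missing sample size are
    compared with observed counts by the exact test; SNPs with p <= alpha
    are marked excluded.  SNPs lacking a population frequency are skipped
    with a warning.  When any expected genotype class rounds to zero (or
    under ``model="allele"``), the comparison falls back to the 2x2
    allele-count table.
    """
    results = []
    for rsid in panel.rsids:
        meta = panel.meta[rsid]
        if meta.pop_alt_freq is None:
            warnings.warn(f"{rsid}: no population allele frequency; skipped", stacklevel=2)
            continue
        obs = genotype_counts(panel, rsid)
        n = sum(obs)
        if n == 0:
            warnings.warn(f"{rsid}: no non-missing calls; skipped", stacklevel=2)
            continue
        exp = hwe_expected(1.0 - meta.pop_alt_freq, n).rounded_counts()
        use_allele = model == "allele" or any(e == 0 for e in exp)
        if use_allele:
            obs2 = (2 * obs[0] + obs[1], obs[1] + 2 * obs[2])  # (ref, alt) allele counts
            p_alt = meta.pop_alt_freq
            exp2 = (int(round(2 * n * (1 - p_alt))), int(round(2 * n * p_alt)))
            results.append(fisher_exact_counts(rsid, obs2, exp2, alpha=alpha))
        else:
            results.append(fisher_exact_counts(rsid, obs, exp, alpha=alpha))
    return results
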