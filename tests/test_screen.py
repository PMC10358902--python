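"""Chi-square screening, ANOVA confirmation, and favorable-allele assignment."""

import numpy as np
import pytest

from tgscore.genotype_io import MISSING
from tgscore.phenotype import ResponseRecord
from tgscore.screen import (
    ContingencyTable,
    ScreenResult,
    anova_confirm,
    assign_favorable_allele,
    build_contingency,
    chi_square_screen,
    pearson_chi2,
)
from tgscore.simulate import SimulationConfig, simulate_cohort
from tests.conftest import make_panel, snp


def _responses(classes: dict[str, bool], pcts: dict[str, float] | None = None):
    out = []
    for pid, is_resp in classes.items():
        pct = (pcts or {}).get(pid, 20.0 if is_resp else 2.0)
        out.append(ResponseRecord(pid, "EG", 2.0, 2.0 * pct / 100, pct, responder=is_resp))
    return out


FOUR = make_panel(
    {"rs1": {"A": "CC", "B": "CT", "C": "TT", "D": "TT"}},
    {"rs1": snp("rs1", "C", "T")},
)


class TestContingency:
    def test_allele_model_hand_count(self):
        resp = _responses({"A": True, "B": True, "C": False, "D": False})
        table = build_contingency(FOUR, resp, "rs1", model="allele")
        assert table.labels == ("C", "T")
        assert table.counts == ((3, 1), (0, 4))

    def test_genotype_model_hand_count(self):
        resp = _responses({"A": True, "B": True, "C": False, "D": False})
        table = build_contingency(FOUR, resp, "rs1", model="genotype")
        assert table.labels == ("CC", "CT", "TT")
        assert table.counts == ((1, 1, 0), (0, 0, 2))

    def test_missing_participant_excluded_from_table_only(self):
        panel = make_panel(
            {"rs1": {"A": "CC", "B": MISSING, "C": "TT", "D": "TT"}},
            {"rs1": snp("rs1", "C", "T")},
        )
        resp = _responses({"A": True, "B": True, "C": False, "D": False})
        table = build_contingency(panel, resp, "rs1")
        assert table.counts == ((2, 0), (0, 4))


class TestPearsonChi2:
    def test_perfect_separation(self):
        t = ContingencyTable("rs1", "allele", ("C", "T"), ((10, 0), (0, 10)))
        chi2, p = pearson_chi2(t)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_independence(self):
        t = ContingencyTable("rs1", "allele", ("C", "T"), ((5, 5), (5, 5)))
        chi2, p = pearson_chi2(t)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_closed_form_2x2(self, rng):
        """Pearson chi-square equals N(ad-bc)^2 / (r1 r2 c1 c2) to 1e-9."""
        for _ in range(200):
            a, b, c, d = rng.integers(1, 30, size=4)
            t = ContingencyTable("rs1", "allele", ("C", "T"), ((int(a), int(b)), (int(c), int(d))))
            chi2, _ = pearson_chi2(t)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(closed, abs=1e-9)

    def test_degenerate_margin_is_p_one(self):
        t = ContingencyTable("rs1", "allele", ("C", "T"), ((0, 0), (5, 5)))
        assert pearson_chi2(t) == (0.0, 1.0)


class TestScreen:
    def test_results_sorted_by_p_then_rsid(self, small_cohort):
        from tgscore.genotype_io import remove_monomorphic
        from tgscore.phenotype import compute_responses

        panel, _ = remove_monomorphic(small_cohort.panel)
        responses = compute_responses(small_cohort.phenotypes, small_cohort.groups)
        results = chi_square_screen(panel, responses)
        keys = [(r.chi2_p, r.rsid) for r in results]
        assert keys == sorted(keys)
        assert len(results) == panel.n_snps

    def test_null_primary_band_fraction_near_alpha(self):
        """Permutation-style null: no planted effects, large arm for asymptotics."""
        cfg = SimulationConfig(
            n_train=100, n_control=2, n_snps=400, monomorphic_fraction=0.0,
            n_causal=2, per_allele_effect=0.0, train_intercept=11.5, noise_sd=9.0,
            seed=11,
        )
        cohort = simulate_cohort(cfg)
        from tgscore.phenotype import compute_responses

        responses = compute_responses(cohort.phenotypes, cohort.groups)
        results = chi_square_screen(cohort.panel, responses)
        frac = np.mean([r.band == "primary" for r in results])
        assert frac == pytest.approx(0.05, abs=0.03)

    def test_bonferroni_never_increases_band_counts(self, small_cohort):
        from tgscore.genotype_io import remove_monomorphic
        from tgscore.phenotype import compute_responses

        panel, _ = remove_monomorphic(small_cohort.panel)
        responses = compute_responses(small_cohort.phenotypes, small_cohort.groups)
        plain = chi_square_screen(panel, responses, correction="none")
        bonf = chi_square_screen(panel, responses, correction="bonferroni")
        n_banded = lambda rs: sum(1 for r in rs if r.band != "none")
        assert n_banded(bonf) <= n_banded(plain)


class TestAnovaConfirm:
    def _candidate(self, panel, responses, rsid, band="primary"):
        table = build_contingency(panel, responses, rsid)
        chi2, p = pearson_chi2(table)
        return ScreenResult(rsid, chi2, p, band, table=table)

    def test_identical_group_means_give_f_zero(self):
        panel = make_panel(
            {"rs1": {"A": "CC", "B": "CC", "C": "TT", "D": "TT"}},
            {"rs1": snp("rs1", "C", "T")},
        )
        resp = _responses({"A": True, "B": False, "C": True, "D": False},
                          pcts={"A": 10, "B": 10, "C": 10, "D": 10})
        cand = self._candidate(panel, resp, "rs1")
        out = anova_confirm(panel, resp, [cand])[0]
        assert out.anova_F == 0.0 and out.anova_p == 1.0

    def test_matches_sum_of_squares_oracle(self):
        """Hand ANOVA decomposition for groups {10,12} vs {20,22}."""
        panel = make_panel(
            {"rs1": {"A": "CC", "B": "CC", "C": "TT", "D": "TT"}},
            {"rs1": snp("rs1", "C", "T")},
        )
        pcts = {"A": 10.0, "B": 12.0, "C": 20.0, "D": 22.0}
        resp = _responses({"A": False, "B": False, "C": True, "D": True}, pcts=pcts)
        cand = self._candidate(panel, resp, "rs1")
        out = anova_confirm(panel, resp, [cand])[0]
        # grand mean 16; SSB = 2*(11-16)^2 + 2*(21-16)^2 = 100; SSW = 2+2 = 4
        # F = (100/1) / (4/2) = 50
        assert out.anova_F == pytest.approx(50.0)
        assert out.retained == (out.anova_p <= 0.05)

    def test_single_genotype_group_not_retained(self):
        panel = make_panel(
            {"rs1": {"A": "CT", "B": "CT", "C": "CT", "D": "CT"}},
            {"rs1": snp("rs1", "C", "T")},
        )
        resp = _responses({"A": True, "B": False, "C": True, "D": False})
        cand = self._candidate(panel, resp, "rs1")
        out = anova_confirm(panel, resp, [cand])[0]
        assert out.anova_p == 1.0 and not out.retained

    def test_planted_additive_snp_usually_retained(self):
        """Per-allele effect ~ noise SD at n=100 confirms with high probability."""
        retained = 0
        reps = 20
        for seed in range(reps):
            cfg = SimulationConfig(
                n_train=100, n_control=2, n_snps=1, monomorphic_fraction=0.0,
                n_causal=1, causal_freq=0.5, per_allele_effect=6.0,
                train_intercept=5.0, noise_sd=6.0, seed=1000 + seed,
            )
            cohort = simulate_cohort(cfg)
            from tgscore.phenotype import compute_responses

            responses = compute_responses(cohort.phenotypes, cohort.groups)
            results = chi_square_screen(cohort.panel, responses)
            results = anova_confirm(cohort.panel, responses, results)
            retained += results[0].retained
        assert retained >= 0.9 * reps


class TestFavorableAllele:
    def test_responder_enriched_allele(self):
        t = ContingencyTable("rs1", "allele", ("C", "T"), ((3, 1), (0, 4)))
        assert assign_favorable_allele(t) == "C"

    def test_symmetric_table_unresolved(self):
        t = ContingencyTable("rs1", "allele", ("C", "T"), ((2, 2), (2, 2)))
        with pytest.warns(UserWarning, match="tie"):
            assert assign_favorable_allele(t) is None

    def test_genotype_table_collapsed_to_alleles(self):
        t = ContingencyTable("rs1", "genotype", ("CC", "CT", "TT"), ((1, 1, 0), (0, 0, 2)))
        assert assign_favorable_allele(t) == "C"

    def test_causal_snps_recover_true_favorable_allele(self):
        """All planted causal SNPs recover their favorable allele at n=100."""
        cfg = SimulationConfig(
            n_train=100, n_control=2, n_snps=8, monomorphic_fraction=0.0,
            n_causal=8, causal_freq=0.4, per_allele_effect=6.0,
            train_intercept=0.0, noise_sd=6.0, seed=5,
        )
        cohort = simulate_cohort(cfg)
        from tgscore.phenotype import compute_responses

        responses = compute_responses(cohort.phenotypes, cohort.groups)
        for rsid, true_allele in cohort.truth["causal"].items():
            table = build_contingency(cohort.panel, responses, rsid)
            assert assign_favorable_allele(table) == true_allele
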