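"""Linear association, Bonferroni arithmetic, cohort intersection, mediation, KD test."""

import numpy as np
import pytest

from mitocleave import (
    bonferroni_threshold,
    bootstrap_mediation,
    intersect_associations,
    kd_comparison,
    linear_association,
)
from mitocleave.association import (
    AssociationResult,
    CollinearityError,
    adjust_bonferroni,
    read_matrix_tsv,
    read_vcf_dosages,
)


class TestLinearAssociation:
    def test_exact_fit_recovers_slope(self):
        x = np.arange(10, dtype=float)
        res = linear_association(0.5 * x, x)
        assert res.beta == pytest.approx(0.5)
        assert res.direction == 1

    def test_recovery_with_noise_and_covariates(self):
        rng = np.random.default_rng(12)
        n = 500
        x = rng.normal(0, 1, n)
        cov = rng.normal(0, 1, (n, 3))
        y = 0.3 * x + cov @ np.array([0.2, -0.1, 0.4]) + rng.normal(0, 0.1, n)
        res = linear_association(y, x, cov)
        assert abs(res.beta - 0.3) < 3 * res.se

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        n, reps = 200, 600
        rejections = 0
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            x = rng.normal(0, 1, n)
            if linear_association(y, x).p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError):
            linear_association(np.arange(10.0), np.ones(10))

    def test_collinear_covariate_raises(self):
        x = np.arange(20, dtype=float)
        y = x + 1
        with pytest.raises(CollinearityError):
            linear_association(y, x, covariates=2 * x)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            linear_association(np.ones(3), np.arange(3.0), np.ones((3, 4)))

    def test_matches_closed_form_without_covariates(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 2, 100)
        y = rng.normal(0, 1, 100) + 0.4 * x
        res = linear_association(y, x)
        beta_hat = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.beta == pytest.approx(beta_hat)


class TestBonferroni:
    def test_genome_wide_over_54_sites(self):
        assert bonferroni_threshold(5e-8, 54) == pytest.approx(9.26e-10, rel=5e-3)

    def test_nominal_over_26_variants(self):
        assert bonferroni_threshold(0.05, 26) == pytest.approx(0.00192, rel=5e-3)

    def test_identity_and_monotonicity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        ms = [1, 2, 10, 100]
        ts = [bonferroni_threshold(0.05, m) for m in ms]
        assert ts == sorted(ts, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)

    def test_adjusted_p_capped_at_one(self):
        assert adjust_bonferroni(0.3, 10) == 1.0
        assert adjust_bonferroni(0.001, 10) == pytest.approx(0.01)


def assoc(site, pred, beta, p_adj):
    return AssociationResult(site, pred, beta, 0.1, p_adj, p_adj, 100)


class TestIntersectAssociations:
    def test_same_sign_significant_pair_kept(self):
        pairs = intersect_associations(
            [assoc(1, "g", -0.2, 1e-4)], [assoc(1, "g", -0.3, 1e-3)]
        )
        assert len(pairs) == 1

    def test_opposite_signs_dropped(self):
        pairs = intersect_associations(
            [assoc(1, "g", -0.2, 1e-4)], [assoc(1, "g", 0.1, 1e-3)]
        )
        assert pairs == []

    def test_nonsignificant_replication_dropped(self):
        pairs = intersect_associations(
            [assoc(1, "g", -0.2, 1e-4)], [assoc(1, "g", -0.3, 0.2)]
        )
        assert pairs == []

    def test_twin_cohort_simulation_recovers_shared_effects(self):
        rng = np.random.default_rng(21)
        n = 400
        true = {(s, "g") for s in range(10)}
        disc, rep = [], []
        for s in range(210):
            key = (s, "g")
            for cohort, out in ((0, disc), (1, rep)):
                x = rng.normal(0, 1, n)
                beta = 0.5 if key in true else 0.0
                y = beta * x + rng.normal(0, 1, n)
                out.append(linear_association(y, x, site=s, predictor_id="g",
                                              m_tests=210))
        pairs = intersect_associations(disc, rep)
        found = {(d.site, d.predictor) for d, _ in pairs}
        assert found == true


class TestBootstrapMediation:
    def test_full_mediation_recovery(self):
        rng = np.random.default_rng(31)
        n = 500
        x = rng.normal(0, 1, n)
        m = 0.5 * x + rng.normal(0, 0.2, n)
        y = 0.5 * m + rng.normal(0, 0.2, n)
        res = bootstrap_mediation(x, m, y, n_boot=500, rng_seed=1)
        assert res.ci_low <= 0.25 <= res.ci_high
        assert res.acme == pytest.approx(0.25, abs=0.05)
        assert res.p_mediation < 0.05

    def test_no_b_path_gives_null_acme(self):
        rng = np.random.default_rng(32)
        n = 400
        x = rng.normal(0, 1, n)
        m = 0.5 * x + rng.normal(0, 0.2, n)
        y = 0.7 * x + rng.normal(0, 0.2, n)  # Y depends on X only
        res = bootstrap_mediation(x, m, y, n_boot=300, rng_seed=2)
        assert abs(res.acme) < 0.05
        assert res.ci_low <= 0 <= res.ci_high

    def test_point_estimate_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(33)
        n = 200
        x = rng.normal(0, 1, n)
        m = 0.4 * x + rng.normal(0, 0.3, n)
        y = 0.6 * m + 0.2 * x + rng.normal(0, 0.3, n)
        res = bootstrap_mediation(x, m, y, n_boot=100, rng_seed=3)
        a = sm.OLS(m, sm.add_constant(x)).fit().params[1]
        b = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit().params[2]
        assert res.acme == pytest.approx(a * b, rel=1e-9)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(34)
        x = rng.normal(0, 1, 150)
        m = 0.5 * x + rng.normal(0, 0.2, 150)
        y = 0.5 * m + rng.normal(0, 0.2, 150)
        r1 = bootstrap_mediation(x, m, y, n_boot=200, rng_seed=9)
        r2 = bootstrap_mediation(x, m, y, n_boot=200, rng_seed=9)
        assert (r1.ci_low, r1.ci_high, r1.p_mediation) == (
            r2.ci_low, r2.ci_high, r2.p_mediation
        )

    def test_input_validation(self):
        x = np.arange(50.0)
        with pytest.raises(ValueError):
            bootstrap_mediation(x, x, x, n_boot=50)
        with pytest.raises(ValueError):
            bootstrap_mediation(np.ones(50), x, x, n_boot=100)


class TestKnockDownComparison:
    def test_identical_groups_give_half(self):
        g = np.array([0.1, 0.12, 0.11, 0.13])
        t, p, mc, mk = kd_comparison(g, g)
        assert p == pytest.approx(0.5)

    def test_reduced_kd_is_significant(self):
        control = np.array([0.12, 0.13, 0.12, 0.13])
        kd = np.array([0.06, 0.07, 0.06, 0.07])
        t, p, mc, mk = kd_comparison(control, kd)
        assert p < 0.05
        assert mk < mc
        # cross-check against the Welch formula
        se = np.sqrt(control.var(ddof=1) / 4 + kd.var(ddof=1) / 4)
        assert t == pytest.approx((kd.mean() - control.mean()) / se)

    def test_wrong_direction_not_significant(self):
        control = np.array([0.06, 0.07, 0.06, 0.07])
        kd = np.array([0.12, 0.13, 0.12, 0.13])
        _, p, _, _ = kd_comparison(control, kd, alternative="kd_less")
        assert p > 0.5

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            kd_comparison(np.array([0.1]), np.array([0.1, 0.2]))


class TestReaders:
    def test_matrix_tsv(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tg1\tg2\nA\t1.0\t2.0\nB\t3.0\t4.0\n")
        df = read_matrix_tsv(path)
        assert df.loc["B", "g2"] == 4.0

    def test_vcf_dosages(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n"
        )
        df = read_vcf_dosages(vcf)
        assert df.loc["A", "rs1"] == 0
        assert df.loc["B", "rs1"] == 1
        assert df.loc["C", "rs1"] == 2
        assert np.isnan(df.loc["B", "rs2"])
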