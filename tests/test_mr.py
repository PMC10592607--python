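"""Mendelian randomization: LD clumping against a brute-force oracle,
allele harmonization, IVW / Egger closed forms and error rates, 2SLS
against explicit matrix algebra, and cascade verdict logic."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cascadeqtl import mr, simulate
from cascadeqtl.datatypes import MRResult


def _inst(bx, sx, by, sy, gene="g", layer="mrna"):
    bx = np.asarray(bx, float)
    return mr.InstrumentSet(
        gene_id=gene, layer=layer,
        variant_ids=[f"v{i}" for i in range(bx.size)],
        exposure_beta=bx, exposure_se=np.asarray(sx, float),
        outcome_beta=np.asarray(by, float), outcome_se=np.asarray(sy, float),
    )


class TestLdClump:
    def test_perfect_ld_keeps_one(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        from cascadeqtl.datatypes import VariantTable
        g = VariantTable(
            variant_id=np.array([f"v{i}" for i in range(5)]),
            chrom=np.full(5, "1", object), pos=np.arange(1, 6) * 100,
            ref_allele=np.full(5, "A"), alt_allele=np.full(5, "G"),
            maf=np.full(5, 0.3), dosage=np.tile(d, (1, 5)),
            sample_ids=[f"S{i}" for i in range(200)],
        )
        stats_df = pd.DataFrame({
            "variant_id": g.variant_id, "pos": g.pos,
            "pvalue": [0.01, 0.002, 0.03, 0.001, 0.04],
        })
        assert mr.ld_clump(stats_df, g) == ["v3"]

    def test_independent_variants_all_kept(self):
        g = simulate.simulate_genotypes(500, 10, ld_block_size=1, seed=2)
        stats_df = pd.DataFrame({
            "variant_id": g.variant_id, "pos": g.pos, "pvalue": 0.01,
        })
        assert len(mr.ld_clump(stats_df, g)) == 10

    def test_threshold_filters(self):
        g = simulate.simulate_genotypes(200, 4, ld_block_size=1, seed=3)
        stats_df = pd.DataFrame({
            "variant_id": g.variant_id, "pos": g.pos,
            "pvalue": [0.2, 0.5, 0.9, 0.06],
        })
        assert mr.ld_clump(stats_df, g) == []

    def test_matches_brute_force_oracle(self):
        g = simulate.simulate_genotypes(300, 20, ld_block_size=4, ld_rho=0.7, seed=4)
        rng = np.random.default_rng(4)
        pv = rng.uniform(0, 0.05, 20)
        stats_df = pd.DataFrame({"variant_id": g.variant_id, "pos": g.pos, "pvalue": pv})
        got = mr.ld_clump(stats_df, g, r2_max=0.5, window_kb=1e6)

        # independent greedy oracle
        X = g.dosage
        Xs = (X - X.mean(0)) / X.std(0)
        r2 = (Xs.T @ Xs / X.shape[0]) ** 2
        alive = np.ones(20, bool)
        expect = []
        while alive.any():
            cand = np.flatnonzero(alive)
            j = cand[np.argmin(pv[cand])]
            expect.append(j)
            near = np.abs(g.pos - g.pos[j]) <= 1e9
            alive &= ~(near & (r2[j] > 0.5))
            alive[j] = False
        assert got == [str(g.variant_id[j]) for j in sorted(expect)]


class TestHarmonize:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["variant_id", "effect_allele", "other_allele", "beta", "se"]
        )

    def test_swapped_alleles_flip_sign(self):
        exp = self._frame([("v1", "A", "G", 0.3, 0.1)])
        out = self._frame([("v1", "G", "A", -0.2, 0.1)])
        h = mr.harmonize(exp, out)
        assert h["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_incompatible_alleles_dropped(self):
        exp = self._frame([("v1", "A", "G", 0.3, 0.1)])
        out = self._frame([("v1", "A", "C", 0.2, 0.1)])
        assert len(mr.harmonize(exp, out)) == 0

    def test_palindromic_dropped(self):
        exp = self._frame([("v1", "A", "T", 0.3, 0.1), ("v2", "C", "G", 0.2, 0.1)])
        out = self._frame([("v1", "A", "T", 0.1, 0.1), ("v2", "C", "G", 0.1, 0.1)])
        assert len(mr.harmonize(exp, out)) == 0


class TestIVW:
    def test_single_instrument_wald_ratio(self):
        res = mr.ivw(_inst([0.5], [0.05], [0.25], [0.05]))
        assert res.estimate == pytest.approx(0.5)

    def test_recovers_simulated_causal_effect(self):
        rng = np.random.default_rng(67)
        bx = rng.normal(0.4, 0.1, 20)
        sy = np.full(20, 0.02)
        by = 0.3 * bx + rng.normal(0, 0.02, 20)
        res = mr.ivw(_inst(bx, np.full(20, 0.02), by, sy))
        assert abs(res.estimate - 0.3) < 0.05

    def test_matches_weighted_least_squares_closed_form(self):
        bx = np.array([0.2, -0.4, 0.5, 0.1, -0.3])
        by = np.array([0.1, -0.1, 0.2, 0.05, -0.2])
        sy = np.array([0.05, 0.08, 0.04, 0.1, 0.06])
        res = mr.ivw(_inst(bx, np.full(5, 0.02), by, sy))
        w = 1 / sy**2
        expect = np.sum(w * bx * by) / np.sum(w * bx**2)
        expect_se = np.sqrt(1 / np.sum(w * bx**2))
        assert abs(res.estimate - expect) < 1e-10
        assert abs(res.se - expect_se) < 1e-10


class TestEgger:
    def test_pure_intercept_construction(self):
        bx = np.linspace(0.2, 0.6, 10)
        by = np.full(10, 0.1)  # outcome = 0.1 + 0*exposure
        res = mr.egger(_inst(bx, np.full(10, 0.02), by, np.full(10, 0.05)))
        assert res.intercept == pytest.approx(0.1, abs=1e-9)
        assert res.estimate == pytest.approx(0.0, abs=1e-9)

    def test_type_one_error_of_intercept_test(self):
        rng = np.random.default_rng(71)
        hits = 0
        n_genes = 200
        for _ in range(n_genes):
            bx = rng.normal(0.4, 0.15, 20) * rng.choice([-1, 1], 20)
            sy = np.full(20, 0.03)
            by = 0.25 * bx + rng.normal(0, 0.03, 20)
            res = mr.egger(_inst(bx, np.full(20, 0.02), by, sy))
            hits += res.intercept_p < 0.05
        assert hits / n_genes <= 0.08

    def test_power_against_directional_pleiotropy(self):
        # directional pleiotropy: a same-sign direct effect on the outcome
        # for 30% of instruments (exposure effects oriented positive, the
        # frame in which "directional" is defined)
        rng = np.random.default_rng(73)
        hits = 0
        n_genes = 100
        for _ in range(n_genes):
            bx = np.abs(rng.normal(0.4, 0.15, 20))
            sy = np.full(20, 0.03)
            by = 0.25 * bx + rng.normal(0, 0.03, 20)
            k = rng.choice(20, size=6, replace=False)  # 30% pleiotropic
            by[k] += 0.2
            res = mr.egger(_inst(bx, np.full(20, 0.02), by, sy))
            hits += res.intercept_p < 0.05
        assert hits / n_genes > 0.5

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr.egger(_inst([0.3, 0.4], [0.02] * 2, [0.1, 0.1], [0.05] * 2))


class TestVerdicts:
    def _res(self, fdr, ip=np.nan, method="IVW"):
        r = MRResult("g", "mrna", "gwas", method, 0.3, 0.05, 0.001, 5)
        r.fdr = fdr
        if not np.isnan(ip):
            r.intercept_p = ip
        return r

    @pytest.mark.parametrize(
        "fdr,ip,verdict",
        [
            (0.05, 0.5, "pass"),
            (0.05, 0.01, "fail_pleiotropy"),
            (0.5, 0.5, "fail_effect"),
        ],
    )
    def test_two_sample_rule(self, fdr, ip, verdict):
        egger = self._res(fdr, ip, method="Egger")
        assert mr.two_sample_verdict(self._res(fdr), egger) == verdict

    def test_requires_fdr(self):
        r = MRResult("g", "mrna", "gwas", "IVW", 0.3, 0.05, 0.001, 5)
        with pytest.raises(ValueError):
            mr.two_sample_verdict(r, None)

    @pytest.mark.parametrize(
        "up,down,cls",
        [
            (True, True, "both-passed"),
            (True, False, "single-passed"),
            (False, True, "single-passed"),
            (False, False, "none-passed"),
        ],
    )
    def test_cascade_classes(self, up, down, cls):
        def res(p):
            r = MRResult("g", "mrna", "ribo", "TSLS", 0.3, 0.05, 0.001, 5)
            r.verdict = "pass" if p else "fail_effect"
            return r

        v = mr.cascade_classify("g", res(up), res(down))
        assert v.cascade_class == cls

    def test_untested_pathway_counts_failed(self):
        v = mr.cascade_classify("g", None, None)
        assert v.cascade_class == "none-passed"


class TestTSLS:
    def test_noiseless_chain_exact(self):
        rng = np.random.default_rng(5)
        z = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        x = z @ [0.5, -0.2, 0.3]
        y = 2.0 * x
        res = mr.tsls(x, y, z)
        assert res.estimate == pytest.approx(2.0, abs=1e-10)

    def test_matches_matrix_algebra_oracle(self):
        rng = np.random.default_rng(6)
        n = 50
        Z = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        x = Z @ [0.4, 0.1, -0.3, 0.2] + rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        res = mr.tsls(x, y, Z)

        Z1 = np.column_stack([np.ones(n), Z])
        P = Z1 @ np.linalg.inv(Z1.T @ Z1) @ Z1.T
        X = np.column_stack([np.ones(n), x])
        bhat = np.linalg.inv(X.T @ P @ X) @ X.T @ P @ y
        resid = y - X @ bhat
        cov = resid @ resid / (n - 2) * np.linalg.inv(X.T @ P @ X)
        assert abs(res.estimate - bhat[1]) < 1e-10
        assert abs(res.se - np.sqrt(cov[1, 1])) < 1e-10

    def test_removes_confounding_bias(self):
        rng = np.random.default_rng(79)
        n = 500
        z = rng.binomial(2, 0.35, size=(n, 5)).astype(float)
        u = rng.normal(size=n)  # confounder
        x = z @ np.full(5, 0.3) + 0.5 * u + rng.normal(size=n)
        y = 0.3 * x + 0.5 * u + rng.normal(size=n)
        res = mr.tsls(x, y, z)
        naive = stats.linregress(x, y).slope
        assert abs(res.estimate - 0.3) < 0.07
        assert naive > 0.38  # visibly confounded
        assert abs(res.estimate - 0.3) < 0.2 * abs(naive - 0.3) + 0.07

    def test_collinear_instruments_dropped(self):
        rng = np.random.default_rng(8)
        z = rng.binomial(2, 0.4, size=(60, 2)).astype(float)
        Z = np.hstack([z, z[:, :1]])  # third column duplicates the first
        x = z @ [0.5, 0.3] + rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        res = mr.tsls(x, y, Z)
        assert res.n_instruments == 2

    def test_weak_instrument_flagged(self):
        rng = np.random.default_rng(9)
        z = rng.binomial(2, 0.4, size=(100, 5)).astype(float)
        x = 0.02 * z[:, 0] + rng.normal(size=100)
        y = rng.normal(size=100)
        res = mr.tsls(x, y, z)
        assert res.weak_instruments
        assert res.f_statistic < 10

    def test_consistency_with_sample_size(self):
        # confounded design: |bias| decreases with n
        biases = []
        for n in (200, 1000, 5000):
            rng = np.random.default_rng(100 + n)
            z = rng.binomial(2, 0.35, size=(n, 5)).astype(float)
            u = rng.normal(size=n)
            x = z @ np.full(5, 0.3) + 0.5 * u + rng.normal(size=n)
            y = 0.3 * x + 0.5 * u + rng.normal(size=n)
            biases.append(abs(mr.tsls(x, y, z).estimate - 0.3))
        assert biases[2] < biases[0]

    def test_statsmodels_cross_check(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        rng = np.random.default_rng(10)
        n = 200
        Z = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        x = Z @ [0.4, -0.2, 0.3] + rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        res = mr.tsls(x, y, Z)
        smres = IV2SLS(
            y, np.column_stack([np.ones(n), x]), np.column_stack([np.ones(n), Z])
        ).fit()
        assert abs(res.estimate - smres.params[1]) < 1e-8
        assert abs(res.se - smres.bse[1]) < 1e-8
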