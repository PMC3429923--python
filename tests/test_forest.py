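"""The forest kernel: OOB prediction, PVE and permutation importance."""

import numpy as np
import pytest

import snpforest as sf
from snpforest.forest import default_mtry_grid


def _sim_geno(rng, n, p):
    return rng.integers(0, 3, size=(n, p)).astype(np.float32)


class TestFitRF:
    def test_reproducibility_bit_identical(self, small_dataset):
        ds, _ = small_dataset
        cfg = sf.RFConfig(n_trees=80, seed=9)
        a = sf.fit_rf(ds.genotypes, ds.phenotype.values, cfg)
        b = sf.fit_rf(ds.genotypes, ds.phenotype.values, cfg)
        assert a.pve == b.pve
        assert np.array_equal(a.importance, b.importance)
        assert np.array_equal(a.oob_pred, b.oob_pred, equal_nan=True)

    def test_pve_identity_from_oob_predictions(self, small_dataset):
        """PVE recomputed independently from the stored OOB vector matches
        the reported PVE exactly."""
        ds, _ = small_dataset
        y = ds.phenotype.values
        fit = sf.fit_rf(ds.genotypes, y, sf.RFConfig(n_trees=100, seed=1),
                        compute_importance=False)
        ok = np.isfinite(fit.oob_pred)
        mse = np.mean((y[ok] - fit.oob_pred[ok]) ** 2)
        assert fit.pve == pytest.approx(100.0 * (1.0 - mse / np.var(y, ddof=1)), abs=1e-12)

    def test_deterministic_signal_recovered(self):
        """A trait that copies one SNP exactly is almost perfectly predicted."""
        rng = np.random.default_rng(0)
        X = _sim_geno(rng, 200, 11)
        y = X[:, 0].astype(float)
        fit = sf.fit_rf(X, y, sf.RFConfig(n_trees=150, seed=2), compute_importance=False)
        assert fit.pve > 80.0

    def test_pure_noise_has_no_pve(self):
        """OOB guards against overfitting: pure-noise traits score <= 5."""
        rng = np.random.default_rng(1)
        X = _sim_geno(rng, 200, 20)
        pves = []
        for s in range(10):
            y = np.random.default_rng(100 + s).normal(size=200)
            fit = sf.fit_rf(X, y, sf.RFConfig(n_trees=60, seed=s),
                            compute_importance=False)
            pves.append(fit.pve)
        assert np.mean(pves) <= 5.0

    def test_constant_phenotype_rejected(self):
        rng = np.random.default_rng(2)
        X = _sim_geno(rng, 30, 4)
        with pytest.raises(ValueError, match="constant phenotype"):
            sf.fit_rf(X, np.ones(30), sf.RFConfig(n_trees=10, seed=0))

    def test_mtry_cannot_exceed_p(self):
        rng = np.random.default_rng(3)
        X = _sim_geno(rng, 30, 4)
        with pytest.raises(ValueError, match="exceeds"):
            sf.fit_rf(X, rng.normal(size=30), sf.RFConfig(n_trees=10, mtry=9, seed=0))

    def test_noise_snps_do_not_raise_pve(self):
        """Adding pure-noise predictors never helps, within MC tolerance."""
        rng = np.random.default_rng(4)
        n = 250
        X = _sim_geno(rng, n, 5)
        y = 2.0 * X[:, 0] + rng.normal(size=n)
        Xwide = np.column_stack([X, _sim_geno(rng, n, 30)]).astype(np.float32)
        base, wide = [], []
        for s in range(10):
            base.append(sf.fit_rf(X, y, sf.RFConfig(n_trees=60, seed=s),
                                  compute_importance=False).pve)
            wide.append(sf.fit_rf(Xwide, y, sf.RFConfig(n_trees=60, seed=s),
                                  compute_importance=False).pve)
        assert np.mean(wide) <= np.mean(base) + 2.0


class TestImportance:
    def test_constant_column_importance_exactly_zero(self):
        rng = np.random.default_rng(5)
        n = 100
        X = np.column_stack([_sim_geno(rng, n, 6), np.ones(n)]).astype(np.float32)
        y = 1.5 * X[:, 0] + rng.normal(size=n)
        fit = sf.fit_rf(X, y, sf.RFConfig(n_trees=60, seed=3))
        assert fit.importance[-1] == 0.0

    def test_planted_effect_is_top_ranked(self):
        """y = 3*g1 + noise among 19 noise SNPs: g1 tops the ranking in
        >= 9/10 seeded runs."""
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            X = _sim_geno(rng, 200, 20)
            y = 3.0 * X[:, 0] + rng.normal(size=200)
            fit = sf.fit_rf(X, y, sf.RFConfig(n_trees=80, seed=s))
            if np.argmax(fit.importance) == 0 and fit.importance[0] > 0:
                wins += 1
        assert wins >= 9

    def test_recompute_matches_fit(self, small_dataset):
        """permutation_importance re-run with the fit's derived seed equals
        the importance stored on the fit."""
        ds, _ = small_dataset
        y = ds.phenotype.values
        cfg = sf.RFConfig(n_trees=60, seed=11)
        fit = sf.fit_rf(ds.genotypes, y, cfg)
        again = sf.permutation_importance(
            fit, ds.genotypes, y, seed=sf.derive_seed(cfg.seed, "importance")
        )
        assert np.array_equal(fit.importance, again)


class TestTuneMtry:
    def test_singleton_grid(self, small_dataset):
        ds, _ = small_dataset
        p = ds.p
        m = int(np.sqrt(p))
        best = sf.tune_mtry(ds.genotypes, ds.phenotype.values, grid=[m],
                            config=sf.RFConfig(n_trees=40, seed=0))
        assert best == m

    def test_two_snp_exact_sum(self):
        """On y = g1 + g2 exactly, both grid values give PVE > 90 and the
        tuner returns the better (or smaller, on a tie) one."""
        rng = np.random.default_rng(8)
        X = _sim_geno(rng, 300, 2)
        y = X[:, 0] + X[:, 1].astype(float)
        cfg = sf.RFConfig(n_trees=100, seed=1)
        pves = {}
        for m in (1, 2):
            vals = [
                sf.fit_rf(X, y, sf.RFConfig(100, m, sf.derive_seed(1, "tune", m, s)),
                          compute_importance=False).pve
                for s in range(3)
            ]
            pves[m] = np.mean(vals)
        assert all(v > 90 for v in pves.values())
        best = sf.tune_mtry(X, y, grid=[1, 2], config=cfg)
        assert best == max(pves, key=lambda m: (pves[m], -m))

    def test_default_grid_contract(self):
        assert default_mtry_grid(100) == [5, 10, 20]
        assert default_mtry_grid(2) == [1, 2]  # clipped to [1, p]
        with pytest.raises(ValueError, match="empty"):
            sf.tune_mtry(np.zeros((20, 3), dtype=np.float32),
                         np.arange(20.0), grid=[])
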