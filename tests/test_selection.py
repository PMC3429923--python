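"""Backward purging and random-subset baselines."""

import numpy as np
import pytest

import snpforest as sf


def _planted_world(seed, n=300, p=50, effects=(3.0, 2.5, 2.0)):
    """Three strong causal SNPs among noise SNPs."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, p)).astype(np.float32)
    y = sum(b * X[:, j] for j, b in enumerate(effects)) + rng.normal(size=n)
    return X, np.asarray(y, dtype=float)


class TestBackwardPurge:
    def test_boundary_start_equals_min(self):
        X, y = _planted_world(0, n=100, p=10)
        traj = sf.backward_purge(X, y, start_k=2, replicates=2,
                                 config=sf.RFConfig(n_trees=30, seed=0))
        assert len(traj.steps) == 1
        assert len(traj.steps[0].snp_set) == 2
        assert traj.steps[0].purged_snp is None

    def test_invalid_start_k(self):
        X, y = _planted_world(0, n=50, p=10)
        with pytest.raises(ValueError, match="start_k"):
            sf.backward_purge(X, y, start_k=1, replicates=1)

    def test_step_structure_and_containment(self):
        X, y = _planted_world(1, n=120, p=20)
        traj = sf.backward_purge(X, y, start_k=8, replicates=2,
                                 config=sf.RFConfig(n_trees=40, seed=1))
        sizes = traj.sizes()
        assert sizes == list(range(8, 1, -1))
        for a, b in zip(traj.steps, traj.steps[1:]):
            assert a.purged_snp not in b.snp_set
            assert set(b.snp_set) < set(a.snp_set)
            # the purged SNP has the minimum mean importance of its step
            worst = min(a.mean_importance, key=lambda s: (a.mean_importance[s], s))
            assert a.purged_snp == worst

    def test_replay_determinism(self):
        X, y = _planted_world(2, n=100, p=15)
        cfg = sf.RFConfig(n_trees=40, seed=7)
        t1 = sf.backward_purge(X, y, start_k=6, replicates=2, config=cfg)
        t2 = sf.backward_purge(X, y, start_k=6, replicates=2, config=cfg)
        assert [s.purged_snp for s in t1.steps] == [s.purged_snp for s in t2.steps]
        assert [s.mean_pve for s in t1.steps] == [s.mean_pve for s in t2.steps]

    def test_planted_truth_survives_purge(self):
        """Three strong causal SNPs among 47 noise SNPs survive purging to
        the final 3-SNP set in >= 8/10 seeded runs."""
        hits = 0
        for s in range(10):
            X, y = _planted_world(300 + s)
            traj = sf.backward_purge(X, y, start_k=50, replicates=2,
                                     config=sf.RFConfig(n_trees=60, seed=s))
            final3 = set(sf.select_top(traj, 3))
            if final3 == {"snp0", "snp1", "snp2"}:
                hits += 1
        assert hits >= 8


@pytest.fixture(scope="module")
def traj():
    X, y = _planted_world(4, n=120, p=16)
    return sf.backward_purge(X, y, start_k=10, replicates=2,
                             config=sf.RFConfig(n_trees=40, seed=4))


class TestSelectTop:

    def test_endpoints(self, traj):
        assert len(sf.select_top(traj, 10)) == 10
        assert sf.select_top(traj, 10) == traj.steps[0].snp_set
        assert sf.select_top(traj, 2) == traj.steps[-1].snp_set

    def test_replay_oracle_mid_trajectory(self, traj):
        """The recorded k=6 set equals a brute-force replay that re-runs the
        purge loop step by step with the same derived seeds."""
        X, y = _planted_world(4, n=120, p=16)
        ids = [f"snp{j}" for j in range(16)]
        full = sf.fit_rf(X, y, sf.RFConfig(40, "sqrt", sf.derive_seed(4, "full")))
        order = sorted(range(16), key=lambda j: (-full.importance[j], ids[j]))
        current = sorted(order[:10])
        step = 0
        while len(current) > 6:
            imps = np.zeros(len(current))
            for r in range(2):
                cfg = sf.RFConfig(40, "sqrt", sf.derive_seed(4, "purge", step, r))
                imps += sf.fit_rf(X[:, current], y, cfg).importance
            worst = min(range(len(current)),
                        key=lambda j: (imps[j], ids[current[j]]))
            del current[worst]
            step += 1
        assert [ids[j] for j in current] == sf.select_top(traj, 6)

    def test_monotone_containment(self, traj):
        for k2 in range(2, 10):
            assert set(sf.select_top(traj, k2)) < set(sf.select_top(traj, k2 + 1))

    def test_out_of_range(self, traj):
        with pytest.raises(ValueError, match="outside"):
            sf.select_top(traj, 11)


class TestRandomBaseline:
    def test_degenerate_draw_equals_full_model(self):
        X, y = _planted_world(5, n=100, p=8)
        cfg = sf.RFConfig(n_trees=50, seed=3)
        table = sf.random_baseline(X, y, sizes=[8], reps=1, config=cfg)
        full = sf.fit_rf(
            X, y,
            sf.RFConfig(50, "sqrt", sf.derive_seed(3, "baseline", 8, 0)),
            compute_importance=False,
        )
        assert table.summary()[8] == pytest.approx(full.pve, abs=1e-12)

    def test_pure_noise_baselines_near_zero(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(200, 25)).astype(np.float32)
        y = rng.normal(size=200)
        table = sf.random_baseline(X, y, sizes=(2, 5, 10), reps=4,
                                   config=sf.RFConfig(n_trees=40, seed=0))
        assert (table.summary() <= 5.0).all()

    def test_draws_are_distinct_snps(self):
        X, y = _planted_world(7, n=80, p=12)
        table = sf.random_baseline(X, y, sizes=[5], reps=6,
                                   config=sf.RFConfig(n_trees=20, seed=1))
        for s in table.table.snp_set:
            names = s.split(",")
            assert len(names) == len(set(names)) == 5
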