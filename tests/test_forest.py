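"""Forest fitting, permutation importance, diagnostics, descriptives."""

import subprocess

import numpy as np
import pytest
from scipy import stats

from turntaking import (ConditionalTree, RegressionForest, descriptives,
                        diagnostics, group_contrast, kde_mode,
                        permutation_importance)


def _toy_data(rng, n=200, p=5, signal=60.0):
    X = rng.normal(size=(n, p))
    X[:, 0] = (X[:, 0] > 0).astype(float)
    y = signal * X[:, 0] + rng.normal(0, 30, size=n)
    return X, y


class TestRegressionForest:
    def test_fixed_seed_is_bit_identical(self, rng):
        X, y = _toy_data(rng)
        reps = []
        for _ in range(2):
            f = RegressionForest(n_trees=30, m_try=2, seed=9).fit(X, y)
            reps.append(permutation_importance(f, X, y))
        assert (reps[0].table["importance"].to_numpy()
                == reps[1].table["importance"].to_numpy()).all()

    def test_single_tree_forest_equals_its_tree(self, rng):
        X, y = _toy_data(rng)
        f = RegressionForest(n_trees=1, m_try=5, seed=3).fit(X, y)
        slot = f.trees_[0]
        pred = slot.estimator.predict(X[:, slot.features])
        assert np.array_equal(f.predict(X), pred)

    def test_constant_response_warns_and_zeroes_importance(self, rng):
        X, _ = _toy_data(rng, n=80)
        y = np.full(80, 5.0)
        with pytest.warns(UserWarning, match="constant response"):
            f = RegressionForest(n_trees=10, m_try=2, seed=1).fit(X, y)
        rep = permutation_importance(f, X, y)
        assert (rep.table["importance"] == 0).all()

    def test_constant_predictor_importance_zero(self, rng):
        X, y = _toy_data(rng, n=300)
        X[:, 3] = 7.0
        f = RegressionForest(n_trees=50, m_try=2, seed=2).fit(X, y)
        rep = permutation_importance(f, X, y,
                                     names=[f"x{j}" for j in range(5)])
        assert rep.importance("x3") == 0.0

    def test_m_try_exceeding_predictors_rejected(self, rng):
        X, y = _toy_data(rng, n=50)
        with pytest.raises(ValueError):
            RegressionForest(n_trees=2, m_try=9).fit(X, y)

    def test_ranks_are_a_permutation(self, rng):
        X, y = _toy_data(rng)
        f = RegressionForest(n_trees=40, m_try=2, seed=5).fit(X, y)
        rep = permutation_importance(f, X, y)
        assert sorted(rep.table["rank"]) == list(range(1, 6))
        assert np.isfinite(rep.table["importance"]).all()

    def test_brute_force_oracle_match(self, rng):
        """Importance equals an independent recomputation sharing the
        permutation streams, to machine precision (small-scale version
        of the acceptance check)."""
        from turntaking.forest import permutation_stream
        X, y = _toy_data(rng, n=60)
        f = RegressionForest(n_trees=5, m_try=2, seed=17).fit(X, y)
        rep = permutation_importance(f, X, y)
        diffs = {j: [] for j in range(5)}
        for t, slot in enumerate(f.trees_):
            Xo, yo = X[slot.oob][:, slot.features], y[slot.oob]
            base = np.mean((yo - slot.estimator.predict(Xo)) ** 2)
            for lj, j in enumerate(slot.features):
                perm = permutation_stream(17, t, int(j), len(slot.oob))
                Xp = Xo.copy()
                Xp[:, lj] = Xp[perm, lj]
                diffs[int(j)].append(
                    np.mean((yo - slot.estimator.predict(Xp)) ** 2) - base)
        for j, d in diffs.items():
            d = np.array(d)
            exp = (d.mean() / d.std(ddof=1)
                   if len(d) > 1 and d.std(ddof=1) > 0 else 0.0)
            assert rep.importance(f"x{j}") == pytest.approx(exp, abs=1e-12)

    def test_duplicate_predictor_shares_importance(self, rng):
        """Masking: duplicating a predictor dilutes how much error its
        permutation adds per tree (forest-wide mean, zeros included), so
        neither copy exceeds the original's solo value in >= 90% of
        seeded runs. The SD-normalized ratio is scale-free and does not
        carry this magnitude property."""
        X, y = _toy_data(rng, n=300, p=3)
        Xd = np.column_stack([X, X[:, 0]])

        def mean_diff(rep, j, n_trees):
            return float(np.sum(rep.diffs[j])) / n_trees

        wins = 0
        for s in range(20):
            solo = permutation_importance(
                RegressionForest(150, 2, seed=s).fit(X, y), X, y)
            dup = permutation_importance(
                RegressionForest(150, 2, seed=s).fit(Xd, y), Xd, y)
            ref = mean_diff(solo, 0, 150)
            if (mean_diff(dup, 0, 150) <= ref
                    and mean_diff(dup, 3, 150) <= ref):
                wins += 1
        assert wins >= 18


class TestConditionalTree:
    def test_fully_determined_binary_predictor(self, rng):
        X = rng.normal(size=(300, 3))
        X[:, 1] = (X[:, 1] > 0).astype(float)
        y = 4.0 * X[:, 1]
        d = diagnostics(X, y)
        assert d.single_tree_r == pytest.approx(1.0)

    def test_null_data_makes_no_splits(self, rng):
        X = rng.normal(size=(500, 4))
        y = rng.normal(100, 30, size=500)
        tree = ConditionalTree(alpha=0.001).fit(X, y)
        assert tree.n_splits_ == 0
        with pytest.warns(UserWarning, match="no splits"):
            d = diagnostics(X, y, tree=tree)
        assert d.single_tree_r == 0.0
        # constant positive prediction => accuracy equals the gap base rate
        assert d.gap_overlap_accuracy == pytest.approx(np.mean(y >= 0))

    def test_removing_true_driver_reduces_fit(self, rng):
        X = rng.normal(size=(400, 4))
        y = 50 * X[:, 0] + rng.normal(0, 20, 400)
        full = diagnostics(X, y)
        reduced = diagnostics(X[:, 1:], y)
        assert reduced.single_tree_r < full.single_tree_r

    def test_linear_r2_matches_population_value(self, rng):
        # y = 2x + e with Var(x)=1, Var(e)=1 => population R^2 = 0.8
        X = rng.normal(size=(4000, 1))
        y = 2 * X[:, 0] + rng.normal(size=4000)
        d = diagnostics(X, y)
        assert d.linear_r2 == pytest.approx(0.8, abs=0.03)


class TestDescriptives:
    def test_degenerate_sample(self):
        d = descriptives([0.0, 0.0, 0.0])
        assert d["mean"] == d["median"] == d["mode_kde"] == 0.0
        assert d["sd"] == 0.0

    def test_normal_sample_moments(self, rng):
        x = rng.normal(187, 448, size=40000)
        d = descriptives(x)
        assert d["mean"] == pytest.approx(187, abs=3 * 448 / 200)
        assert d["sd"] == pytest.approx(448, rel=0.02)
        assert d["mode_kde"] == pytest.approx(187, abs=40)

    def test_bimodal_mode_matches_dense_grid_argmax(self, rng):
        x = np.concatenate([rng.normal(-300, 50, 300),
                            rng.normal(200, 30, 600)])
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        bw = 0.9 * min(sd, iqr / 1.34) * len(x) ** -0.2
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, 20001)
        dens = np.exp(-0.5 * ((grid[:, None] - x) / bw) ** 2).sum(axis=1)
        assert kde_mode(x) == pytest.approx(grid[np.argmax(dens)], abs=5.0)

    def test_mode_matches_r_density_default(self, rng):
        """Cross-check the KDE mode against R's density() defaults."""
        x = np.round(rng.normal(150, 400, size=400), 3)
        r_code = ("x <- scan('stdin', quiet=TRUE); d <- density(x); "
                  "cat(d$x[which.max(d$y)])")
        try:
            out = subprocess.run(["Rscript", "-e", r_code],
                                 input="\n".join(map(str, x)),
                                 capture_output=True, text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        r_mode = float(out.stdout.strip())
        # same bandwidth rule (nrd0) and grid resolution ~ (range/512)
        assert kde_mode(x) == pytest.approx(r_mode, abs=15.0)


class TestGroupContrast:
    def test_identical_groups(self):
        y = np.r_[np.arange(10.0), np.arange(10.0)]
        g = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        c = group_contrast(y, g)
        assert c.difference == 0.0 and c.p == pytest.approx(1.0)

    def test_welch_formula_by_hand(self):
        a = np.array([120.0, 150, 170, 160, 140])
        b = np.array([200.0, 230, 210, 220, 260])
        c = group_contrast(np.r_[a, b],
                           np.r_[np.ones(5, bool), np.zeros(5, bool)])
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        t_hand = (a.mean() - b.mean()) / se
        df = se ** 4 / ((a.var(ddof=1) / 5) ** 2 / 4
                        + (b.var(ddof=1) / 5) ** 2 / 4)
        assert c.t == pytest.approx(t_hand)
        assert c.p == pytest.approx(2 * stats.t.sf(abs(t_hand), df))

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_contrast([1.0, 2.0, 3.0], [True, False, False])
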