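"""Prais–Winsten regression, compositional PCA and permutation nulls."""

import itertools

import numpy as np
import pandas as pd
import pytest

import traitsort as ts
from traitsort.inference import (
    TraitVsTrait,
    evaluate_statistic,
    pca_composition,
    permutation_test,
    prais_winsten,
    trait_vs_env,
)

from conftest import make_traits


def _ols(x, y):
    X = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(x) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta[1], beta[0], np.sqrt(cov[1, 1])


class TestPraisWinsten:
    def test_exact_line_gives_unit_correlation(self):
        x = np.arange(10.0)
        fit = prais_winsten(x, 3.0 - 2.0 * x)
        assert fit.r_pw == pytest.approx(-1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)
        assert fit.p_value < 1e-12

    def test_fixed_zero_rho_equals_ols_exactly(self, rng):
        x = rng.normal(size=30)
        y = 1.0 + 0.5 * x + rng.normal(size=30)
        fit = prais_winsten(x, y, fix_rho=0.0)
        slope, intercept, se = _ols(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.stderr == pytest.approx(se, abs=1e-12)
        assert fit.rho == 0.0

    def test_iid_noise_estimates_near_zero_rho(self, rng):
        x = rng.normal(size=500)
        y = 2.0 + 1.5 * x + rng.normal(size=500)
        fit = prais_winsten(x, y)
        slope, _, se = _ols(x, y)
        assert abs(fit.rho) < 0.1
        assert fit.slope == pytest.approx(slope, abs=5 * se / np.sqrt(500))

    def test_ar1_rho_recovery_single_series(self, rng):
        n = 2000
        u = np.empty(n)
        u[0] = rng.normal()
        eps = rng.normal(size=n)
        for t in range(1, n):
            u[t] = 0.6 * u[t - 1] + eps[t]
        x = rng.normal(size=n)
        fit = prais_winsten(x, 1.0 + 0.3 * x + u)
        assert fit.rho == pytest.approx(0.6, abs=0.1)

    def test_sign_consistency_of_r_pw(self, rng):
        x = np.arange(20.0)
        y = 5.0 + 0.4 * x + rng.normal(size=20)
        fit = prais_winsten(x, y)
        assert np.sign(fit.r_pw) == np.sign(fit.slope)
        assert abs(fit.r_pw) <= 1.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            prais_winsten(np.ones(10), np.arange(10.0))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            prais_winsten(np.arange(3.0), np.arange(3.0))


class TestPCA:
    def test_two_class_complement_loads_everything_on_pc1(self):
        share = np.array([0.2, 0.5, 0.3, 0.8, 0.6])
        g = pd.DataFrame({"a": share, "b": 1 - share})
        res = pca_composition(g)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_matrix_eigenvalues_match_characteristic_polynomial(self):
        """3×3 covariance eigenvalues vs brute-force cubic roots."""
        X = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
        g = pd.DataFrame(X, columns=list("abc"))
        res = pca_composition(g)
        C = np.cov(X - X.mean(0), rowvar=False, ddof=1)
        # characteristic polynomial of a 3x3 by explicit minors (no eig calls)
        tr = C[0, 0] + C[1, 1] + C[2, 2]
        m = (
            C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
            + C[0, 0] * C[2, 2] - C[0, 2] * C[2, 0]
            + C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1]
        )
        det = (
            C[0, 0] * (C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1])
            - C[0, 1] * (C[1, 0] * C[2, 2] - C[1, 2] * C[2, 0])
            + C[0, 2] * (C[1, 0] * C[2, 1] - C[1, 1] * C[2, 0])
        )
        roots = np.sort(np.roots([1.0, -tr, m, -det]).real)[::-1]
        assert np.allclose(np.sort(res.eigenvalues)[::-1], roots, atol=1e-10)

    def test_reconstruction_and_orthonormality(self, default_composition):
        _, _, comp = default_composition
        res = pca_composition(comp.g)
        assert np.allclose(res.reconstruct().to_numpy(), comp.g.to_numpy(), atol=1e-10)
        V = res.eigenvectors.to_numpy()
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.eigenvalues) <= 1e-15)

    def test_sign_convention_deterministic(self, default_composition):
        _, _, comp = default_composition
        res = pca_composition(comp.g)
        for col in res.eigenvectors.columns:
            v = res.eigenvectors[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_constant_matrix_rejected(self):
        g = pd.DataFrame({"a": [0.5, 0.5, 0.5], "b": [0.5, 0.5, 0.5]})
        with pytest.raises(ValueError, match="variance"):
            pca_composition(g)


def _weights_frame(rows, taxa):
    arr = np.asarray(rows, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)
    return pd.DataFrame(arr, index=pd.Index(range(len(arr)), name="year"), columns=taxa)


class TestPermutationTest:
    def test_identity_permutation_reproduces_observed(self, rng):
        W = _weights_frame(rng.uniform(0.1, 1, (6, 4)), ["a", "b", "c", "d"])
        traits = make_traits(a=(1.0, 5.0, 1.0), b=(2.0, 4.0, 1.0),
                             c=(3.0, 2.0, 1.0), d=(4.0, 1.0, 1.0))
        stat = TraitVsTrait("gamma", "alpha")
        obs = evaluate_statistic(W, traits, stat)
        assert evaluate_statistic(W, traits, stat, perm=np.arange(4)) == obs

    def test_identical_traits_give_full_tie_distribution(self, rng):
        """All taxa share one trait triple: p_strict = 0, p_addone = 1."""
        W = _weights_frame(rng.uniform(0.1, 1, (5, 3)), ["a", "b", "c"])
        traits = make_traits(a=(2.0, 3.0, 1.0), b=(2.0, 3.0, 1.0), c=(2.0, 3.0, 1.0))
        res = permutation_test(W, traits, TraitVsTrait("gamma", "alpha"), k=50, seed=1)
        assert res.p_strict == 0.0
        assert res.p_addone == 1.0

    def test_exhaustive_three_taxon_null_matches_bruteforce(self):
        """Every permuted statistic matches a direct enumeration of all 3! pairings."""
        W = _weights_frame(
            [[0.70, 0.25, 0.05], [0.45, 0.35, 0.20], [0.30, 0.45, 0.25],
             [0.15, 0.30, 0.55], [0.05, 0.15, 0.80]],
            ["a", "b", "c"],
        )
        traits = make_traits(a=(3.774, 3.234, 1.0), b=(7.280, 7.391, 1.0),
                             c=(1.448, 8.092, 1.0))
        ln_g = np.log([3.774, 7.280, 1.448])
        ln_a = np.log([3.234, 7.391, 8.092])
        Wn = W.to_numpy()

        def brute(perm):
            sa, sb = Wn @ ln_g[list(perm)], Wn @ ln_a[list(perm)]
            return np.corrcoef(sa, sb)[0, 1] ** 2

        stat = TraitVsTrait("gamma", "alpha")
        enumerated = {}
        for perm in itertools.permutations(range(3)):
            got = evaluate_statistic(W, traits, stat, perm=np.array(perm))
            assert got == pytest.approx(brute(perm), abs=1e-12)
            enumerated[perm] = brute(perm)
        # observed pairing is the strict maximum of the 6 -> p_strict must be 0
        values = np.array(list(enumerated.values()))
        obs = enumerated[(0, 1, 2)]
        assert obs == values.max() and (values < obs).sum() == 5
        res = permutation_test(W, traits, stat, k=120, seed=9)
        assert res.p_strict == 0.0
        for v in res.null:
            assert min(abs(v - e) for e in values) < 1e-12

    def test_seed_reproducibility_and_mc_error(self, default_dataset, default_composition):
        _, _, comp = default_composition
        stat = TraitVsTrait("gamma", "alpha")
        r1 = permutation_test(comp.b, default_dataset.traits, stat, k=2000, seed=5)
        r2 = permutation_test(comp.b, default_dataset.traits, stat, k=2000, seed=5)
        assert r1.p_addone == r2.p_addone
        assert np.array_equal(r1.null, r2.null)
        r3 = permutation_test(comp.b, default_dataset.traits, stat, k=2000, seed=6)
        p = max(r1.p_addone, 1 / 2001)
        mc = 2 * np.sqrt(p * (1 - p) / 2000)
        assert abs(r3.p_addone - r1.p_addone) <= max(3 * mc, 5 / 2001)

    def test_trait_vs_series_statistic_runs(self, default_dataset, default_composition):
        _, _, comp = default_composition
        tp = default_dataset.environment.series().loc[comp.years].to_numpy()
        stat = trait_vs_env("gamma", tp)
        res = permutation_test(comp.b, default_dataset.traits, stat, k=200, seed=3)
        assert 0 <= res.p_strict <= res.p_addone <= 1.0
        # strong sorting: observed R_pw^2 should beat essentially every draw
        assert res.p_addone < 0.05

    def test_missing_trait_cells_rejected(self, rng):
        W = _weights_frame(rng.uniform(0.1, 1, (4, 2)), ["a", "b"])
        traits = make_traits(a=(1.0, None, 1.0), b=(2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="missing cells"):
            permutation_test(W, traits, TraitVsTrait("gamma", "alpha"), k=10, seed=0)

    def test_p_addone_bounds_invariant(self, rng):
        W = _weights_frame(rng.uniform(0.1, 1, (6, 5)), list("abcde"))
        traits = make_traits(**{t: (float(g), float(a), 1.0) for t, g, a in
                                zip("abcde", [1, 2, 3, 4, 5], [5, 3, 1, 2, 4])})
        res = permutation_test(W, traits, TraitVsTrait("gamma", "alpha"), k=99, seed=2)
        assert 1 / 100 <= res.p_addone <= 1.0
        assert res.p_strict <= res.p_addone + 1 / 100
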