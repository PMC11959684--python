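"""Trait–environment statistics for yearly series.

Three tools, all geared to short (~40-point) annual time series:

* :func:`prais_winsten` — linear regression with AR(1)-correlated errors.
  The model ``y_t = a + b·x_t + u_t``, ``u_t = ρ·u_{t-1} + ε_t`` is estimated
  iteratively: OLS residuals give a lag-1 estimate of ρ, the data are
  quasi-differenced (the first observation retained, scaled by √(1−ρ²)),
  and the regression is re-fit until ρ converges.  The reported correlation
  ``R_pw`` is the signed square root of the transformed fit's R², and
  ``P_pw`` a two-sided t-test on the transformed slope.
* :func:`pca_composition` — covariance PCA of the year × class share matrix
  with a deterministic sign convention, used to summarise compositional
  change as PC scores that can be regressed on the environment.
* :func:`permutation_test` — the trait-shuffling null: taxon weight series
  keep their identity while complete trait *triples* are reassigned by a
  random permutation of taxa (sampling without replacement), the community
  mean trait series is recomputed, and the test statistic re-evaluated.
  The null hypothesis is that species sorting is blind to traits.  Two
  p-value estimators are returned: the strictly-greater fraction
  ``p_strict = #{stat* > stat}/k`` and the add-one estimator
  ``p_addone = (#{stat* ≥ stat}+1)/(k+1)``, which is guaranteed positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_tables import TRAITS, TraitTable

# ---------------------------------------------------------------------------
# Prais–Winsten


@dataclass(frozen=True)
class PWFit:
    """Result of an AR(1)-corrected (Prais–Winsten) regression."""

    rho: float
    slope: float
    intercept: float
    r_pw: float
    p_value: float
    stderr: float
    n: int
    n_iter: int


def _fit2(c: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Closed-form least squares for the two-column design [c, x]."""
    s00 = c @ c
    s01 = c @ x
    s11 = x @ x
    det = s00 * s11 - s01 * s01
    if det <= 0 or not np.isfinite(det):
        raise ValueError("design is singular: predictor has no variance")
    t0 = c @ y
    t1 = x @ y
    a = (s11 * t0 - s01 * t1) / det
    b = (s00 * t1 - s01 * t0) / det
    return a, b, det, s00, s01, s11


def _pw_transform(rho: float, c, x, y):
    f = np.sqrt(1.0 - rho * rho)
    cs = np.empty_like(c)
    xs = np.empty_like(x)
    ys = np.empty_like(y)
    cs[0] = f * c[0]
    xs[0] = f * x[0]
    ys[0] = f * y[0]
    cs[1:] = c[1:] - rho * c[:-1]
    xs[1:] = x[1:] - rho * x[:-1]
    ys[1:] = y[1:] - rho * y[:-1]
    return cs, xs, ys


def _pw_core(x, y, fix_rho=None, tol=1e-8, max_iter=50):
    """Iterative Prais–Winsten estimation; returns the converged pieces."""
    n = len(x)
    c = np.ones(n)
    if np.ptp(x) == 0:
        raise ValueError("prais_winsten: constant predictor")
    a, b, *_ = _fit2(c, x, y)
    e = y - a - b * x
    rho = 0.0
    trace = []
    converged = fix_rho is not None
    n_iter = 0
    if fix_rho is not None:
        rho = float(fix_rho)
    else:
        for n_iter in range(1, max_iter + 1):
            den = e[:-1] @ e[:-1]
            num = e[1:] @ e[:-1]
            rho_new = 0.0 if den <= 0 else float(np.clip(num / den, -0.999999, 0.999999))
            trace.append(rho_new)
            cs, xs, ys = _pw_transform(rho_new, c, x, y)
            a, b, *_ = _fit2(cs, xs, ys)
            e = y - a - b * x
            if abs(rho_new - rho) < tol:
                rho = rho_new
                converged = True
                break
            rho = rho_new
        if not converged:
            raise RuntimeError(f"prais_winsten: rho did not converge; trace={trace}")
    cs, xs, ys = _pw_transform(rho, c, x, y)
    a, b, det, s00, s01, s11 = _fit2(cs, xs, ys)
    fitted = a * cs + b * xs
    resid = ys - fitted
    ssr = float(resid @ resid)
    # generalised R^2: squared correlation between transformed y and fit
    fv = fitted - fitted.mean()
    yv = ys - ys.mean()
    denom = float((fv @ fv) * (yv @ yv))
    r2 = 0.0 if denom <= 0 else float((fv @ yv) ** 2 / denom)
    sigma2 = ssr / (n - 2)
    se = float(np.sqrt(sigma2 * s00 / det))
    return rho, a, b, r2, se, n, n_iter


def prais_winsten(x, y, fix_rho=None, tol=1e-8, max_iter=50) -> PWFit:
    """AR(1)-corrected regression of ``y`` on ``x`` (both yearly series).

    ``fix_rho`` skips estimation and applies the transform at the given ρ
    (``fix_rho=0`` reproduces OLS exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("missing/non-finite values are not allowed")
    rho, a, b, r2, se, n, n_iter = _pw_core(x, y, fix_rho, tol, max_iter)
    r_pw = float(np.sign(b) * np.sqrt(r2)) if b != 0 else 0.0
    if se > 0:
        t = b / se
        p = float(2 * sps.t.sf(abs(t), n - 2))
    else:
        p = 0.0
    return PWFit(
        rho=float(rho), slope=float(b), intercept=float(a), r_pw=r_pw,
        p_value=p, stderr=se, n=n, n_iter=n_iter,
    )


def _pw_rsq(x, y) -> float:
    """R_pw² only, for permutation loops; degenerate (constant y) → 0."""
    if np.ptp(y) == 0:
        return 0.0
    try:
        _, _, _, r2, _, _, _ = _pw_core(x, y)
    except RuntimeError:
        return float("nan")
    return r2


# ---------------------------------------------------------------------------
# PCA of class composition


@dataclass(frozen=True)
class PCAResult:
    """Covariance PCA of a year × class composition matrix."""

    eigenvectors: pd.DataFrame  # class × component
    eigenvalues: np.ndarray
    explained: np.ndarray
    scores: pd.DataFrame  # year × component
    column_means: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        """scores · eigenvectorsᵀ + column means."""
        rec = self.scores.to_numpy() @ self.eigenvectors.to_numpy().T
        return pd.DataFrame(
            rec + self.column_means.to_numpy(),
            index=self.scores.index,
            columns=self.eigenvectors.index,
        )


def pca_composition(g: pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA on the centred (optionally standardised) class-share matrix.

    Covariance PCA is the default: all shares live on the same scale, and
    correlation PCA would up-weight rare classes.  The sign of each
    component is fixed by making its largest-magnitude loading positive.
    """
    X = g.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("pca_composition: need at least 3 years")
    means = X.mean(axis=0)
    Xc = X - means
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("pca_composition: constant column under scaling")
        Xc = Xc / sd
    if not Xc.any():
        raise ValueError("pca_composition: matrix has no variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigenvalues = S**2 / (n - 1)
    explained = eigenvalues / eigenvalues.sum()
    comps = [f"PC{j + 1}" for j in range(len(S))]
    return PCAResult(
        eigenvectors=pd.DataFrame(Vt.T, index=g.columns, columns=comps),
        eigenvalues=eigenvalues,
        explained=explained,
        scores=pd.DataFrame(U * S, index=g.index, columns=comps),
        column_means=pd.Series(means, index=g.columns),
    )


# ---------------------------------------------------------------------------
# trait-shuffling permutation tests


@dataclass(frozen=True)
class TraitVsTrait:
    """Plain R² between two log community-mean-trait series."""

    trait_a: str
    trait_b: str

    @property
    def name(self) -> str:
        return f"{self.trait_a}_vs_{self.trait_b}"


@dataclass(frozen=True)
class TraitVsSeries:
    """R_pw² of a log community-mean-trait series against a yearly series."""

    trait: str
    series: tuple  # yearly values, aligned with the weight matrix rows
    label: str = "env"

    @property
    def name(self) -> str:
        return f"{self.trait}_vs_{self.label}"


def trait_vs_env(trait: str, env) -> TraitVsSeries:
    return TraitVsSeries(trait=trait, series=tuple(np.asarray(env, dtype=float)), label="tp_mix")


def trait_vs_biovolume(trait: str, totals) -> TraitVsSeries:
    return TraitVsSeries(trait=trait, series=tuple(np.asarray(totals, dtype=float)), label="biovolume")


@dataclass(frozen=True)
class PermutationResult:
    statistic: str
    observed: float
    k: int
    p_strict: float
    p_addone: float
    seed: int
    null: np.ndarray | None = field(repr=False, default=None)


def _ln_trait_vectors(traits: TraitTable, taxa) -> dict[str, np.ndarray]:
    tt = traits.table.set_index("taxon_id")
    missing = [t for t in taxa if t not in tt.index]
    if missing:
        raise ValueError(f"taxa without trait rows: {missing[:10]}")
    sub = tt.loc[list(taxa), list(TRAITS)]
    if sub.isna().any().any():
        raise ValueError("trait table has missing cells; impute first")
    return {tr: np.log(sub[tr].to_numpy()) for tr in TRAITS}


def _cmt_rows(ln_rows: np.ndarray, W: np.ndarray) -> np.ndarray:
    """log CMT series for a batch of trait orderings: (m, taxa) → (m, years).

    einsum keeps the summation order independent of the batch size, so the
    observed statistic and the permutation null share a bit-identical kernel
    (exact tie handling in the p-value estimators depends on this).
    """
    return np.einsum("mn,yn->my", ln_rows, W)


def _corr_sq_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = (Ac**2).sum(axis=1) * (Bc**2).sum(axis=1)
    out = np.zeros(len(A))
    ok = den > 0
    out[ok] = num[ok] ** 2 / den[ok]
    return out


def evaluate_statistic(weights: pd.DataFrame, traits: TraitTable, statistic, perm=None) -> float:
    """The observed (or one permuted) value of a permutation-test statistic.

    ``weights`` is the year × taxon matrix of annual relative biovolumes;
    ``perm`` is an index array pairing weight column ``i`` with the trait
    triple of taxon ``perm[i]`` (identity when omitted).
    """
    W = weights.to_numpy(dtype=float)
    ln = _ln_trait_vectors(traits, weights.columns)
    n = W.shape[1]
    perm = np.arange(n) if perm is None else np.asarray(perm)
    if isinstance(statistic, TraitVsTrait):
        sa = _cmt_rows(ln[statistic.trait_a][perm][None, :], W)
        sb = _cmt_rows(ln[statistic.trait_b][perm][None, :], W)
        return float(_corr_sq_rows(sa, sb)[0])
    if isinstance(statistic, TraitVsSeries):
        x = np.asarray(statistic.series, dtype=float)
        if len(x) != W.shape[0]:
            raise ValueError("series length does not match number of years")
        s = _cmt_rows(ln[statistic.trait][perm][None, :], W)[0]
        return _pw_rsq(x, s)
    raise TypeError(f"unknown statistic {statistic!r}")


def permutation_test(
    weights: pd.DataFrame,
    traits: TraitTable,
    statistic,
    k: int = 10_000,
    seed: int = 0,
    store_null: bool = True,
    chunk: int = 2_000,
) -> PermutationResult:
    """Trait-shuffling permutation test of a trait–trait or trait–series link.

    Each of the ``k`` permutations redraws which taxon's *complete* trait
    triple is paired with each weight series (triples are never split), the
    community mean trait series is recomputed, and the statistic compared
    with its observed value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    W = weights.to_numpy(dtype=float)
    ln = _ln_trait_vectors(traits, weights.columns)
    n = W.shape[1]
    observed = evaluate_statistic(weights, traits, statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(k)
    base = np.arange(n)
    done = 0
    while done < k:
        m = min(chunk, k - done)
        P = rng.permuted(np.tile(base, (m, 1)), axis=1)
        if isinstance(statistic, TraitVsTrait):
            Sa = _cmt_rows(ln[statistic.trait_a][P], W)
            Sb = _cmt_rows(ln[statistic.trait_b][P], W)
            null[done : done + m] = _corr_sq_rows(Sa, Sb)
        elif isinstance(statistic, TraitVsSeries):
            x = np.asarray(statistic.series, dtype=float)
            S = _cmt_rows(ln[statistic.trait][P], W)
            for j in range(m):
                null[done + j] = _pw_rsq(x, S[j])
        else:
            raise TypeError(f"unknown statistic {statistic!r}")
        done += m
    p_strict = float(np.count_nonzero(null > observed) / k)
    p_addone = float((np.count_nonzero(null >= observed) + 1) / (k + 1))
    return PermutationResult(
        statistic=statistic.name,
        observed=float(observed),
        k=k,
        p_strict=p_strict,
        p_addone=p_addone,
        seed=seed,
        null=null if store_null else None,
    )


def null_calibration(
    n_tests: int = 500,
    k: int = 999,
    seed: int = 0,
    n_taxa: int = 150,
    n_years: int = 42,
    weight_noise_sigma: float = 0.3,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Rejection rate of the permutation test when the null is true.

    Each replicate draws annual weights that are exchangeable with respect to
    traits (lognormal noise around a uniform community — the distribution a
    neutral, sorting-free community with multiplicative observation noise
    induces) together with a fresh trait pool, then runs the trait-vs-trait
    permutation test at ``k`` permutations.  Under the null the add-one
    p-value is (super-)uniform, so the rate of ``p ≤ alpha`` should sit at
    the nominal level up to binomial noise.  Returns ``(rate, p_values)``.
    """
    from .synthetic import SyntheticConfig, generate_trait_pool

    root = np.random.SeedSequence(seed)
    pvals = np.empty(n_tests)
    for i, child in enumerate(root.spawn(n_tests)):
        rng = np.random.default_rng(child)
        W = np.exp(rng.normal(0.0, weight_noise_sigma, size=(n_years, n_taxa)))
        W /= W.sum(axis=1, keepdims=True)
        pool_seed = int(rng.integers(0, 2**31 - 1))
        pool, _ = generate_trait_pool(SyntheticConfig(seed=pool_seed, n_taxa=n_taxa))
        weights = pd.DataFrame(W, columns=pool.taxa)
        res = permutation_test(
            weights, pool, TraitVsTrait("gamma", "alpha"),
            k=k, seed=int(rng.integers(0, 2**31 - 1)), store_null=False,
        )
        pvals[i] = res.p_addone
    rate = float(np.mean(pvals <= alpha))
    return rate, pvals
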