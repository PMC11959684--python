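"""Standardised major axis (SMA) fitting on log traits, with weights.

SMA is the symmetric line-fitting method of choice when both variables carry
error, as trait–trait allometries do: the slope is the ratio of standard
deviations signed by the correlation, ``b = sign(r)·SD_y/SD_x``, which makes
the fit equivariant under axis swap (slope(y,x) = 1/slope(x,y)) and
equivalent to minimising Σ w_i (y_i − a − b·x_i)² / |b|.

The study design calls for the same fit at three levels of integration:
unweighted unique trait pairs (community membership), pairs weighted by
long-term average relative biovolume b̄_i (average community composition),
and the across-year community mean trait series.  Confidence intervals for
the slope are analytic (via the correlation's t-distribution) in the
unweighted case and a weighted percentile bootstrap otherwise.  Points can
be projected onto the fitted axis (in SD-standardised coordinates) to give
scalar scores whose weighted percentiles summarise where biomass sits along
the trade-off axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_tables import TRAITS, TraitTable


@dataclass(frozen=True)
class SMAFit:
    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n: int
    n_effective: float
    ci_low: float
    ci_high: float
    weighting: str
    x_mean: float = field(repr=False, default=np.nan)
    y_mean: float = field(repr=False, default=np.nan)
    x_sd: float = field(repr=False, default=np.nan)
    y_sd: float = field(repr=False, default=np.nan)


@dataclass(frozen=True)
class AxisScores:
    """Scalar coordinates of points along a fitted SMA axis, with weights."""

    scores: np.ndarray
    weights: np.ndarray


def _weighted_moments(x, y, w):
    wn = w / w.sum()
    xm = float(wn @ x)
    ym = float(wn @ y)
    vx = float(wn @ (x - xm) ** 2)
    vy = float(wn @ (y - ym) ** 2)
    cxy = float(wn @ ((x - xm) * (y - ym)))
    return xm, ym, vx, vy, cxy


def _check_xyw(x, y, w):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if w is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match x and y in length")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    if np.count_nonzero(w > 0) < 3:
        raise ValueError("need at least 3 points with positive weight")
    return x, y, w


def sma_fit(
    x,
    y,
    w=None,
    alpha: float = 0.05,
    compute_ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> SMAFit:
    """Fit the (weighted) standardised major axis of ``y`` against ``x``.

    ``x`` and ``y`` are log trait values.  With no weights (or equal
    weights) this is the classical SMA; weights are normalised to sum to
    one, the effective sample size for the significance test being the
    Kish size (Σw)²/Σw².
    """
    user_weights = w is not None
    x, y, w = _check_xyw(x, y, w)
    weighted = user_weights and len(np.unique(w[w > 0])) > 1
    xm, ym, vx, vy, cxy = _weighted_moments(x, y, w)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in x or y: SMA undefined")
    r = cxy / np.sqrt(vx * vy)
    r = float(np.clip(r, -1.0, 1.0))
    if r == 0:
        raise ValueError("correlation is exactly zero: SMA slope sign undefined")
    slope = float(np.sign(r) * np.sqrt(vy / vx))
    intercept = ym - slope * xm
    n = int(np.count_nonzero(w > 0))
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    r2 = r * r
    if r2 >= 1.0:
        p = 0.0
    elif n_eff <= 2:
        # too few effective points for a correlation test
        p = float("nan")
    else:
        t = abs(r) * np.sqrt((n_eff - 2) / (1 - r2))
        p = float(2 * sps.t.sf(t, n_eff - 2))
    fit = SMAFit(
        slope=slope,
        intercept=float(intercept),
        r=r,
        r2=float(r2),
        p_value=p,
        n=n,
        n_effective=n_eff,
        ci_low=np.nan,
        ci_high=np.nan,
        weighting="weighted" if weighted else "unweighted",
        x_mean=xm,
        y_mean=ym,
        x_sd=float(np.sqrt(vx)),
        y_sd=float(np.sqrt(vy)),
    )
    if compute_ci:
        lo, hi = sma_ci(fit, x, y, w if weighted else None, alpha=alpha, n_boot=n_boot, seed=seed)
        fit = replace(fit, ci_low=lo, ci_high=hi)
    return fit


def sma_ci(fit: SMAFit, x, y, w=None, alpha: float = 0.05, n_boot: int = 2000, seed: int = 0):
    """95% (by default) confidence interval for the SMA slope.

    Unweighted: the analytic interval from the slope's log-variance via the
    correlation's t-distribution, ``b·(√(B+1) ± √B)`` with
    ``B = t²·(1−r²)/(n−2)``.  Weighted: a percentile bootstrap that resamples
    points with probability proportional to weight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("confidence interval needs at least 4 points")
    if w is None:
        tcrit = sps.t.ppf(1 - alpha / 2, n - 2)
        B = tcrit**2 * (1 - fit.r2) / (n - 2)
        lo = fit.slope * (np.sqrt(B + 1) - np.sqrt(B))
        hi = fit.slope * (np.sqrt(B + 1) + np.sqrt(B))
        return (float(min(lo, hi)), float(max(lo, hi)))
    w = np.asarray(w, dtype=float)
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=(n_boot, n), p=p)
    X = x[idx]
    Y = y[idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    vx = (Xc**2).mean(axis=1)
    vy = (Yc**2).mean(axis=1)
    cxy = (Xc * Yc).mean(axis=1)
    ok = (vx > 0) & (vy > 0) & (cxy != 0)
    slopes = np.sign(cxy[ok]) * np.sqrt(vy[ok] / vx[ok])
    if len(slopes) < max(100, n_boot // 10):
        raise RuntimeError("bootstrap produced too few valid resamples")
    lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def axis_scores(fit: SMAFit, x, y, w=None, standardized: bool = True) -> AxisScores:
    """Project points onto the fitted axis; returns scalar scores + weights.

    By default projection happens in SD-standardised coordinates (the SMA
    geometry, where the axis has slope ±1); ``standardized=False`` projects
    in raw log-trait space onto direction (1, slope).
    """
    x, y, w = _check_xyw(x, y, w)
    if w.sum() <= 0:
        raise ValueError("total weight is zero")
    s = np.sign(fit.r)
    if standardized:
        xs = (x - fit.x_mean) / fit.x_sd
        ys = (y - fit.y_mean) / fit.y_sd
        scores = (xs + s * ys) / np.sqrt(2)
    else:
        dx = x - fit.x_mean
        dy = y - fit.y_mean
        norm = np.sqrt(1 + fit.slope**2)
        scores = (dx + fit.slope * dy) / norm
    return AxisScores(scores=scores, weights=w)


def weighted_percentiles(scores: AxisScores | np.ndarray, probs, weights=None) -> np.ndarray:
    """Weighted percentiles by the cumulative-weight rule.

    Percentile ``p`` is the smallest score whose cumulative normalised
    weight reaches ``p``; zero-weight points are ignored, so p=0 and p=1
    return the extreme scores that carry positive weight.
    """
    if isinstance(scores, AxisScores):
        s, w = scores.scores, scores.weights
    else:
        s = np.asarray(scores, dtype=float)
        w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probs must lie in [0, 1]")
    mask = w > 0
    if not mask.any():
        raise ValueError("total weight is zero")
    s, w = s[mask], w[mask]
    order = np.argsort(s, kind="mergesort")
    s, w = s[order], w[order]
    cw = np.cumsum(w) / w.sum()
    out = np.empty(len(probs))
    for i, p in enumerate(probs):
        j = int(np.searchsorted(cw, p - 1e-12))
        out[i] = s[min(j, len(s) - 1)]
    return out


def collapse_phenotypes(traits: TraitTable, weights: pd.Series) -> pd.DataFrame:
    """Collapse taxa sharing an identical trait triple into phenotypes.

    ``weights`` maps taxon_id → weight (e.g. long-term average share b̄_i);
    a phenotype's weight is the sum over its member taxa.  Taxa absent from
    ``weights`` count zero.
    """
    df = traits.table
    if df[list(TRAITS)].isna().any().any():
        raise ValueError("trait table has missing cells; impute first")
    merged = df[["taxon_id", *TRAITS]].copy()
    merged["weight"] = merged["taxon_id"].map(weights).fillna(0.0)
    out = (
        merged.groupby(list(TRAITS), as_index=False, sort=True)
        .agg(weight=("weight", "sum"), n_taxa=("taxon_id", "size"))
    )
    return out


def sma_three_levels(
    traits: TraitTable,
    composition,
    trait_x: str,
    trait_y: str,
    cmt_values: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict[str, SMAFit]:
    """SMA of two log traits at the three levels of integration.

    ``membership``: unique phenotypes, equal weights; ``weighted``:
    phenotypes weighted by summed b̄_i; ``cmt``: the across-year community
    mean trait series (supply ``cmt_values`` to reuse a computed series,
    otherwise the all-taxa series is derived here).
    """
    from .cwm import cmt_series  # local import to avoid a cycle

    pheno = collapse_phenotypes(traits, composition.b_bar)
    x = np.log(pheno[trait_x].to_numpy())
    y = np.log(pheno[trait_y].to_numpy())
    out = {
        "membership": sma_fit(x, y, seed=seed),
        "weighted": sma_fit(x, y, w=pheno["weight"].to_numpy(), seed=seed),
    }
    if cmt_values is None:
        cmt_values = cmt_series(traits, composition).values
    out["cmt"] = sma_fit(
        np.log(cmt_values[trait_x].to_numpy()),
        np.log(cmt_values[trait_y].to_numpy()),
        seed=seed,
    )
    return out
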