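"""Synthetic community generator with Monod-fitness species sorting.

The generator produces datasets with the statistical structure the analysis
pipeline assumes, so every stage can be tested against known ground truth:

* a **trait pool** whose log traits are trivariate Gaussian with a weak
  anticorrelation between ln phosphate affinity and ln light affinity
  (default r = −0.24, i.e. a pool-level R² near 0.06) and a balanced
  taxonomy (genus → phylum) over the pool;
* a **nutrient trajectory**: total phosphorus at winter mixis rising
  log-linearly about threefold to a peak and then declining to roughly a
  tenth of the peak — an order-of-magnitude range over 42 years;
* **species sorting**: each year summer phosphate is a fixed drawdown
  fraction of TP, biomass rises with TP, effective light falls with
  self-shading, per-taxon fitness is the Liebig minimum of the two Monod
  growth rates, and annual relative biovolumes follow a softmax
  ``w_i ∝ exp(λ·μ_i)`` (λ = 0 gives a neutral community);
* **sampling**: biweekly observation dates, a smooth seasonal modulation of
  total biovolume, multiplicative lognormal observation noise, and a
  configurable sliver of small-celled taxa (cell volume < 30 μm³) carrying a
  prescribed share of biomass so the cell-volume filter has something to do.

The softmax shortcut replaces explicit resource-competition dynamics: it is
the simplest mechanism that concentrates biomass along the realised
trade-off axis and its ground truth is analytically checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import (
    EnvironmentTable,
    ObservationTable,
    TaxonomyTable,
    TraitTable,
)
from .traits import monod


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator; defaults are desk-scale realistic."""

    n_taxa: int = 150
    start_year: int = 1966
    n_years: int = 42
    # log-scale trait pool
    ln_gamma_mean: float = math.log(3.0)     # phosphate affinity ~3 L umol^-1 d^-1
    ln_gamma_sd: float = 0.9
    ln_alpha_mean: float = math.log(2e-6)    # light affinity, daily-light units
    ln_alpha_sd: float = 0.9
    ln_mumax_mean: float = math.log(0.8)     # max growth rate ~0.8 d^-1
    ln_mumax_sd: float = 0.12
    r_gamma_alpha: float = -0.24             # weak physiological trade-off
    r_alpha_mumax: float = 0.33
    r_gamma_mumax: float = 0.0
    pool_truncation: float = 2.5             # reject |z| > this many SD (no super-taxa)
    # nutrient trajectory (umol P L^-1 at winter mixis)
    tp_start: float = 0.9
    tp_peak: float = 2.8
    tp_end: float = 0.28
    peak_year: int = 1979
    # species sorting
    sorting_strength: float = 20.0           # lambda; 0 = neutral
    env_noise_sigma: float = 0.25            # interannual lognormal noise on P and I
    drawdown: float = 0.15                   # summer P as fraction of TP_mix
    light_incident: float = 4e6              # umol quanta m^-2 d^-1
    shading: float = 2.5e-6                  # per (um^3 L^-1) of biovolume
    biomass_per_tp: float = 1e6              # um^3 L^-1 per umol TP L^-1
    colimitation: str = "liebig"             # or "multiplicative"
    # sampling
    sampling_interval_days: int = 14
    noise_sigma: float = 0.3
    seasonal_amplitude: float = 0.5
    small_cell_fraction: float = 0.075       # share of taxa with cell volume < 30
    small_cell_share: float = 0.018          # their share of community biovolume
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3 or self.n_years < 2:
            raise ValueError("need at least 3 taxa and 2 years")
        for name in ("tp_start", "tp_peak", "tp_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.start_year <= self.peak_year <= self.start_year + self.n_years - 1:
            raise ValueError("peak_year outside the study period")
        if self.sorting_strength < 0:
            raise ValueError("sorting_strength must be >= 0")
        if self.env_noise_sigma < 0:
            raise ValueError("env_noise_sigma must be >= 0")
        if self.pool_truncation <= 0:
            raise ValueError("pool_truncation must be > 0")
        for r in (self.r_gamma_alpha, self.r_alpha_mumax, self.r_gamma_mumax):
            if not abs(r) < 1:
                raise ValueError("trait correlations must satisfy |r| < 1")
        if not 0 <= self.small_cell_fraction < 1:
            raise ValueError("small_cell_fraction must lie in [0, 1)")
        if not 0 <= self.small_cell_share < 1:
            raise ValueError("small_cell_share must lie in [0, 1)")
        if self.colimitation not in ("liebig", "multiplicative"):
            raise ValueError("colimitation must be 'liebig' or 'multiplicative'")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass(frozen=True)
class SyntheticDataset:
    """Everything the pipeline consumes plus the generator's ground truth."""

    config: SyntheticConfig
    observations: ObservationTable
    traits: TraitTable
    taxonomy: TaxonomyTable
    environment: EnvironmentTable
    true_weights: pd.DataFrame      # year x taxon, post-filter ground truth
    full_weights: pd.DataFrame      # year x taxon incl. small-cell taxa
    drivers: pd.DataFrame           # year, tp_mix, p_summer, i_effective, biovolume


def _taxon_ids(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n)]


def _balanced_taxonomy(taxa: list[str]) -> TaxonomyTable:
    rows = []
    for i, t in enumerate(taxa):
        g = i // 3
        f = g // 2
        o = f // 2
        c = o // 2
        p = c // 4
        rows.append(
            {
                "taxon_id": t,
                "genus": f"G{g:03d}",
                "family": f"F{f:03d}",
                "order": f"O{o:02d}",
                "class": f"C{c:02d}",
                "phylum": f"P{p:02d}",
            }
        )
    return TaxonomyTable(pd.DataFrame(rows))


def generate_trait_pool(cfg: SyntheticConfig, rng=None) -> tuple[TraitTable, TaxonomyTable]:
    """Draw the lognormal trait pool and its balanced taxonomy."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sds = np.array([cfg.ln_gamma_sd, cfg.ln_alpha_sd, cfg.ln_mumax_sd])
    corr = np.array(
        [
            [1.0, cfg.r_gamma_alpha, cfg.r_gamma_mumax],
            [cfg.r_gamma_alpha, 1.0, cfg.r_alpha_mumax],
            [cfg.r_gamma_mumax, cfg.r_alpha_mumax, 1.0],
        ]
    )
    cov = corr * np.outer(sds, sds)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("trait correlation matrix is not positive definite") from None
    means = np.array([cfg.ln_gamma_mean, cfg.ln_alpha_mean, cfg.ln_mumax_mean])
    # truncated draws: physiologically impossible all-round champions are
    # rejected, giving the pool a (soft) Pareto frontier like real trait data
    kept: list[np.ndarray] = []
    need = cfg.n_taxa
    while need > 0:
        z = rng.standard_normal((max(need * 2, 8), 3))
        z = z[(np.abs(z) <= cfg.pool_truncation).all(axis=1)]
        kept.append(z[:need])
        need -= len(z[:need])
    ln_traits = means + np.concatenate(kept) @ chol.T
    # phylogenetic signal: relatives share physiology, so the taxonomy is
    # carved from the pool ordered along the gamma-alpha trade-off axis
    order = np.argsort(ln_traits[:, 0] - ln_traits[:, 1], kind="stable")
    ln_traits = ln_traits[order]
    taxa = _taxon_ids(cfg.n_taxa)
    traits = TraitTable(
        pd.DataFrame(
            {
                "taxon_id": taxa,
                "gamma": np.exp(ln_traits[:, 0]),
                "alpha": np.exp(ln_traits[:, 1]),
                "mumax": np.exp(ln_traits[:, 2]),
            }
        )
    )
    return traits, _balanced_taxonomy(taxa)


def generate_tp_trajectory(cfg: SyntheticConfig) -> EnvironmentTable:
    """Piecewise log-linear rise-and-fall TP trajectory through the knots."""
    years = cfg.years
    knots_x = np.array([years[0], cfg.peak_year, years[-1]], dtype=float)
    knots_y = np.log([cfg.tp_start, cfg.tp_peak, cfg.tp_end])
    tp = np.exp(np.interp(years.astype(float), knots_x, knots_y))
    return EnvironmentTable(pd.DataFrame({"year": years, "tp_mix": tp}))


def simulate_sorting(
    pool: TraitTable, env: EnvironmentTable, cfg: SyntheticConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Softmax species sorting on Monod fitness; returns (weights, drivers).

    Per year: summer phosphate ``P = drawdown·TP``, biovolume
    ``B = biomass_per_tp·TP``, effective light ``I = I0/(1+shading·B)``,
    fitness the Liebig minimum (or normalised product) of the two Monod
    rates, and weights ``w_i ∝ exp(λ·μ_i)``.  With ``env_noise_sigma > 0``
    the realised P and I carry independent interannual lognormal noise
    (weather); the values the community actually experienced are returned in
    ``drivers`` so ground truth stays exactly checkable.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    tt = pool.table
    gamma = tt["gamma"].to_numpy()
    alpha = tt["alpha"].to_numpy()
    mumax = tt["mumax"].to_numpy()
    years = env.years
    tp = env.table["tp_mix"].to_numpy()
    biovolume = cfg.biomass_per_tp * tp
    p_summer = cfg.drawdown * tp
    i_eff = cfg.light_incident / (1.0 + cfg.shading * biovolume)
    if cfg.env_noise_sigma > 0:
        p_summer = p_summer * np.exp(rng.normal(0.0, cfg.env_noise_sigma, len(tp)))
        i_eff = i_eff * np.exp(rng.normal(0.0, cfg.env_noise_sigma, len(tp)))

    W = np.empty((len(years), len(gamma)))
    for k in range(len(years)):
        mu_p = monod(mumax, gamma, p_summer[k])
        mu_i = monod(mumax, alpha, i_eff[k])
        if cfg.colimitation == "liebig":
            mu = np.minimum(mu_p, mu_i)
        else:
            mu = mu_p * mu_i / mumax
        z = cfg.sorting_strength * mu
        z -= z.max()  # softmax stability
        w = np.exp(z)
        W[k] = w / w.sum()
    weights = pd.DataFrame(W, index=pd.Index(years, name="year"), columns=tt["taxon_id"])
    drivers = pd.DataFrame(
        {
            "year": years,
            "tp_mix": tp,
            "p_summer": p_summer,
            "i_effective": i_eff,
            "biovolume": biovolume,
        }
    )
    return weights, drivers


def sample_observations(
    weights: pd.DataFrame,
    drivers: pd.DataFrame,
    meta: pd.DataFrame,
    cfg: SyntheticConfig,
    rng=None,
) -> ObservationTable:
    """Biweekly noisy sampling of the annual weights.

    Observed biovolume of taxon *i* on date *t* in year *y* is
    ``B_y · w_iy · m(t) · exp(N(0, σ²))`` with a smooth seasonal modulation
    ``m`` shared by all taxa (it cancels from daily relative shares).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    years = weights.index.to_numpy()
    dates = pd.date_range(
        f"{years[0]}-01-01", f"{years[-1]}-12-31", freq=f"{cfg.sampling_interval_days}D"
    )
    byear = drivers.set_index("year")["biovolume"]
    doy = dates.day_of_year.to_numpy()
    season = np.exp(cfg.seasonal_amplitude * np.sin(2 * np.pi * (doy - 120) / 365.25))
    W = weights.to_numpy()
    yidx = np.searchsorted(years, dates.year.to_numpy())
    base = byear.to_numpy()[yidx][:, None] * W[yidx] * season[:, None]
    if cfg.noise_sigma > 0:
        base = base * np.exp(rng.normal(0.0, cfg.noise_sigma, size=base.shape))
    records = pd.DataFrame(
        {
            "date": np.repeat(dates, W.shape[1]),
            "taxon_id": np.tile(weights.columns.to_numpy(), len(dates)),
            "biovolume": base.ravel(),
        }
    )
    return ObservationTable(records, meta)


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Full generation chain: pool → TP → sorting → small-cell mix → sampling."""
    cfg = SyntheticConfig() if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed)
    traits, taxonomy = generate_trait_pool(cfg, rng)
    env = generate_tp_trajectory(cfg)
    weights, drivers = simulate_sorting(traits, env, cfg, rng)

    taxa = list(weights.columns)
    n_small = int(round(cfg.small_cell_fraction * cfg.n_taxa))
    small = set(taxa[:n_small])
    large = [t for t in taxa if t not in small]
    if n_small:
        w_small = weights[list(small)]
        w_large = weights[large]
        full = pd.concat(
            [
                w_small.div(w_small.sum(axis=1), axis=0) * cfg.small_cell_share,
                w_large.div(w_large.sum(axis=1), axis=0) * (1 - cfg.small_cell_share),
            ],
            axis=1,
        )[taxa]
        true_weights = w_large.div(w_large.sum(axis=1), axis=0)
    else:
        full = weights
        true_weights = weights

    cell_volume = np.where(
        np.isin(taxa, list(small)),
        rng.uniform(5.0, 29.5, size=len(taxa)),
        np.exp(rng.normal(np.log(500.0), 1.0, size=len(taxa))).clip(min=30.0),
    )
    classes = taxonomy.table.set_index("taxon_id")["class"]
    meta = pd.DataFrame(
        {
            "taxon_id": taxa,
            "cell_volume": cell_volume,
            "class_id": classes.loc[taxa].to_numpy(),
        }
    )
    obs = sample_observations(full, drivers, meta, cfg, rng)
    return SyntheticDataset(
        config=cfg,
        observations=obs,
        traits=traits,
        taxonomy=taxonomy,
        environment=env,
        true_weights=true_weights,
        full_weights=full,
        drivers=drivers,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the four input CSVs plus ground truth; returns written paths."""
    from pathlib import Path

    from . import io_tables as iot

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": out / "observations.csv",
        "observation_meta": out / "observation_meta.csv",
        "traits": out / "traits.csv",
        "taxonomy": out / "taxonomy.csv",
        "environment": out / "environment.csv",
        "ground_truth": out / "ground_truth.csv",
        "drivers": out / "drivers.csv",
    }
    iot.write_observations(ds.observations, paths["observations"], paths["observation_meta"])
    iot.write_traits(ds.traits, paths["traits"])
    iot.write_taxonomy(ds.taxonomy, paths["taxonomy"])
    iot.write_environment(ds.environment, paths["environment"])
    gt = ds.true_weights.reset_index().melt(id_vars="year", var_name="taxon_id", value_name="weight")
    gt.to_csv(paths["ground_truth"], index=False, float_format="%.17g")
    ds.drivers.to_csv(paths["drivers"], index=False, float_format="%.17g")
    return {k: str(v) for k, v in paths.items()}
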