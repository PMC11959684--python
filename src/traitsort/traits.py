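"""Monod growth kinetics and taxonomy-based trait imputation.

Growth under a single limiting resource follows the Monod form.  With
maximum growth rate ``μmax`` (d⁻¹) and resource *affinity* — the initial
slope of the growth–resource curve — the half-saturation constant is the
ratio ``μmax / affinity``:

    μ_P(P) = μmax · P / (μmax/γ + P)      k_P = μmax / γ
    μ_I(I) = μmax · I / (μmax/α + I)      k_I = μmax / α

where ``γ`` is phosphate affinity (L μmol⁻¹ d⁻¹) and ``α`` light affinity
(μmol quanta⁻¹ m²).  Both functions are increasing, concave, bounded by
μmax, and equal μmax/2 at the half-saturation constant.

Trait compilations never cover a whole species pool, so missing values are
filled from taxonomy: a missing trait is estimated as the geometric mean of
the trait values of the taxon's closest relatives with *measured* data,
walking genus → family → order → class → phylum and stopping at the first
rank with at least one measured relative.  Imputed values never feed further
imputations, which keeps the procedure order-independent and idempotent.
:func:`imputation_loo` quantifies imputation error by hiding each measured
value in turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import RANKS, TRAITS, TaxonomyTable, TraitTable


@dataclass(frozen=True)
class MonodTraits:
    """One taxon's Monod parameter triple."""

    mumax: float  # d^-1
    gamma: float  # L umol^-1 d^-1 (phosphate affinity)
    alpha: float  # umol quanta^-1 m^2 (light affinity)

    def __post_init__(self):
        if not (self.mumax > 0 and self.gamma > 0 and self.alpha > 0):
            raise ValueError("Monod traits must be strictly positive")

    @property
    def kp(self) -> float:
        """Phosphate half-saturation constant μmax/γ (μmol L⁻¹)."""
        return self.mumax / self.gamma

    @property
    def ki(self) -> float:
        """Light half-saturation constant μmax/α (μmol quanta m⁻² d⁻¹)."""
        return self.mumax / self.alpha


def monod(mumax, affinity, resource):
    """Vectorised Monod growth rate μmax·R/(μmax/affinity + R)."""
    mumax = np.asarray(mumax, dtype=float)
    affinity = np.asarray(affinity, dtype=float)
    resource = np.asarray(resource, dtype=float)
    if (resource < 0).any():
        raise ValueError("resource concentration must be non-negative")
    return mumax * resource / (mumax / affinity + resource)


def growth_p(traits: MonodTraits, phosphate):
    """Phosphate-limited growth rate (d⁻¹) at concentration ``phosphate`` (μmol L⁻¹)."""
    out = monod(traits.mumax, traits.gamma, phosphate)
    return float(out) if np.isscalar(phosphate) else out


def growth_i(traits: MonodTraits, light):
    """Light-limited growth rate (d⁻¹) at intensity ``light`` (μmol quanta m⁻² d⁻¹)."""
    out = monod(traits.mumax, traits.alpha, light)
    return float(out) if np.isscalar(light) else out


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _impute_one(
    taxon: str,
    measured: pd.Series,
    tax: pd.DataFrame,
) -> tuple[float, str] | None:
    """Rank-walk imputation of a single trait cell.

    Returns (value, rank used) or None when no measured relative exists at
    any rank.  ``measured`` holds measured values indexed by taxon_id; ``tax``
    is the taxonomy table indexed by taxon_id.
    """
    own = tax.loc[taxon]
    for rank in RANKS:
        label = own[rank]
        if label == "":
            continue
        relatives = tax.index[(tax[rank] == label) & (tax.index != taxon)]
        donors = measured.reindex(relatives).dropna()
        if len(donors):
            return _geometric_mean(donors.to_numpy()), rank
    return None


def impute_traits(
    traits: TraitTable,
    taxonomy: TaxonomyTable,
    allow_global_fallback: bool = False,
) -> TraitTable:
    """Fill missing trait values from measured relatives, per trait.

    Each trait is imputed independently; only originally-measured values are
    used as donors.  With ``allow_global_fallback`` a taxon with no measured
    relative at any rank receives the geometric mean of all measured values
    of that trait; otherwise such orphans raise ``ValueError``.
    """
    df = traits.table.copy()
    tax = taxonomy.table.set_index("taxon_id")
    unknown = [t for t in df["taxon_id"] if t not in tax.index]
    if unknown:
        raise ValueError(f"impute_traits: taxa absent from taxonomy: {unknown[:5]}")

    orphans: list[tuple[str, str]] = []
    for trait in TRAITS:
        scol = f"{trait}_status"
        measured = df.loc[df[scol] == "measured"].set_index("taxon_id")[trait]
        if measured.empty:
            raise ValueError(f"impute_traits: no measured values at all for {trait}")
        for idx in df.index[df[scol] == "missing"]:
            taxon = df.at[idx, "taxon_id"]
            hit = _impute_one(taxon, measured, tax)
            if hit is None:
                if allow_global_fallback:
                    df.at[idx, trait] = _geometric_mean(measured.to_numpy())
                    df.at[idx, scol] = "imputed"
                else:
                    orphans.append((taxon, trait))
            else:
                df.at[idx, trait] = hit[0]
                df.at[idx, scol] = "imputed"
    if orphans:
        raise ValueError(
            "impute_traits: no measured relative at any rank for "
            + ", ".join(f"{t}:{tr}" for t, tr in orphans[:10])
        )
    return TraitTable(df)


def imputation_loo(
    traits: TraitTable, taxonomy: TaxonomyTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out error of the imputation scheme.

    Every measured cell is hidden in turn and re-imputed from the remaining
    measured values.  Returns ``(errors, summary)`` where ``errors`` has one
    row per evaluable cell with the log10 ratio imputed/true, and ``summary``
    gives per-trait median, MAD and RMSE of those log10 errors.
    """
    df = traits.table
    tax = taxonomy.table.set_index("taxon_id")
    rows = []
    for trait in TRAITS:
        scol = f"{trait}_status"
        measured = df.loc[df[scol] == "measured"].set_index("taxon_id")[trait]
        if len(measured) < 2:
            raise ValueError(f"imputation_loo: need >=2 measured taxa for {trait}")
        for taxon, true_value in measured.items():
            rest = measured.drop(taxon)
            hit = _impute_one(taxon, rest, tax)
            if hit is None:
                continue
            est, rank = hit
            rows.append(
                {
                    "trait": trait,
                    "taxon_id": taxon,
                    "true": true_value,
                    "imputed": est,
                    "rank_used": rank,
                    "log10_ratio": np.log10(est / true_value),
                }
            )
    errors = pd.DataFrame(rows, columns=["trait", "taxon_id", "true", "imputed", "rank_used", "log10_ratio"])
    summaries = []
    for trait, grp in errors.groupby("trait"):
        e = grp["log10_ratio"].to_numpy()
        summaries.append(
            {
                "trait": trait,
                "n": len(e),
                "median": float(np.median(e)),
                "mad": float(np.median(np.abs(e - np.median(e)))),
                "rmse": float(np.sqrt(np.mean(e**2))),
            }
        )
    summary = pd.DataFrame(summaries, columns=["trait", "n", "median", "mad", "rmse"])
    return errors, summary
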