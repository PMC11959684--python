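"""Community and group mean traits.

Because Monod traits are distributed over orders of magnitude, community
mean traits are biomass-weighted *geometric* means: traits are
log-transformed, weighted by annual mean relative biovolumes and
exponentiated back,

    CMT_y = exp( Σ_i ln τ_i · b_iy ),

which is exactly the weighted geometric mean when the weights sum to one.
Taxon- or class-exclusion variants (e.g. dropping mixotrophic Dinophyceae,
whose Monod parameterisation is doubtful) renormalise the remaining weights
to one; the retained pre-renormalisation weight ("coverage") is reported per
year so the sensitivity of a series to its exclusion rule stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import AnnualComposition
from .io_tables import TRAITS, TraitTable


@dataclass(frozen=True)
class CMTSeries:
    """Per-year community (or group) mean traits under a named inclusion rule.

    ``values``: DataFrame year × trait; ``coverage``: per-year share of
    community biovolume retained before renormalisation; ``label``: name of
    the inclusion rule (e.g. ``"all"``, ``"no_Dinophyceae"``).
    """

    values: pd.DataFrame
    coverage: pd.Series
    label: str

    def __eq__(self, other):
        if not isinstance(other, CMTSeries):
            return NotImplemented
        return (
            self.label == other.label
            and self.values.equals(other.values)
            and self.coverage.equals(other.coverage)
        )


def community_mean_trait(tau, weights) -> float:
    """Weighted geometric mean of trait values ``tau`` with weights ``weights``.

    Weights may sum to less than one (after exclusions); they are
    renormalised, so with Σw = 1 this is the plain biomass-weighted
    geometric mean.
    """
    tau = np.asarray(tau, dtype=float)
    w = np.asarray(weights, dtype=float)
    if tau.shape != w.shape:
        raise ValueError("tau and weights must have the same shape")
    if (tau <= 0).any():
        raise ValueError("trait values must be strictly positive")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    if total > 1 + 1e-9:
        raise ValueError(f"weights sum to {total}, expected at most 1")
    return float(np.exp(np.log(tau) @ (w / total)))


def _weight_matrix(
    composition: AnnualComposition,
    exclude_taxa=(),
    exclude_classes=(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict b_iy to non-excluded taxa; return (weights, coverage)."""
    drop = set(exclude_taxa)
    if exclude_classes:
        classes = set(exclude_classes)
        drop |= {t for t, c in composition.taxon_class.items() if c in classes}
    keep = [t for t in composition.taxa if t not in drop]
    if not keep:
        raise ValueError("exclusions removed every taxon")
    w = composition.b[keep]
    coverage = w.sum(axis=1)
    if (coverage <= 0).any():
        bad = coverage.index[coverage <= 0].tolist()
        raise ValueError(f"exclusions remove all biomass in year(s) {bad}")
    coverage.name = "coverage"
    return w, coverage


def cmt_series(
    traits: TraitTable,
    composition: AnnualComposition,
    exclude_taxa=(),
    exclude_classes=(),
    label: str = "all",
    on_missing_traits: str = "error",
) -> CMTSeries:
    """Community mean trait series for all three Monod traits.

    Every taxon with positive weight must have a complete trait triple;
    with ``on_missing_traits="drop"`` trait-less taxa are instead removed
    from the weights (their mass shows up as reduced coverage).
    """
    if on_missing_traits not in ("error", "drop"):
        raise ValueError("on_missing_traits must be 'error' or 'drop'")
    w, _ = _weight_matrix(composition, exclude_taxa, exclude_classes)

    tt = traits.table.set_index("taxon_id")
    have = [
        t
        for t in w.columns
        if t in tt.index and not any(np.isnan(tt.at[t, tr]) for tr in TRAITS)
    ]
    lacking = [t for t in w.columns if t not in have and (w[t] > 0).any()]
    if lacking and on_missing_traits == "error":
        raise ValueError(f"taxa with positive biovolume but incomplete traits: {lacking[:10]}")
    w = w[[t for t in w.columns if t in have]]
    coverage = w.sum(axis=1)
    coverage.name = "coverage"
    if (coverage <= 0).any():
        bad = coverage.index[coverage <= 0].tolist()
        raise ValueError(f"no trait-bearing biomass left in year(s) {bad}")

    ln_tau = np.log(tt.loc[list(w.columns), list(TRAITS)].to_numpy())
    wn = w.to_numpy() / coverage.to_numpy()[:, None]
    values = pd.DataFrame(
        np.exp(wn @ ln_tau), index=w.index, columns=list(TRAITS)
    )
    values.index.name = "year"
    return CMTSeries(values=values, coverage=coverage, label=label)


def group_mean_traits(
    traits: TraitTable,
    composition: AnnualComposition,
    class_id: str,
) -> CMTSeries:
    """Within-class mean trait series (weights renormalised within the class).

    Years in which the class holds no biomass yield NaN rather than an error.
    """
    members = [t for t in composition.taxa if composition.taxon_class.get(t) == class_id]
    if not members:
        raise ValueError(f"no taxa in class {class_id!r}")
    tt = traits.table.set_index("taxon_id")
    missing = [
        t for t in members if t not in tt.index or any(np.isnan(tt.at[t, tr]) for tr in TRAITS)
    ]
    if missing:
        raise ValueError(f"class members with incomplete traits: {missing[:10]}")
    w = composition.b[members]
    coverage = w.sum(axis=1)
    coverage.name = "coverage"
    ln_tau = np.log(tt.loc[members, list(TRAITS)].to_numpy())
    out = np.full((len(w), len(TRAITS)), np.nan)
    present = coverage.to_numpy() > 0
    if present.any():
        wn = w.to_numpy()[present] / coverage.to_numpy()[present, None]
        out[present] = np.exp(wn @ ln_tau)
    values = pd.DataFrame(out, index=w.index, columns=list(TRAITS))
    values.index.name = "year"
    return CMTSeries(values=values, coverage=coverage, label=f"class:{class_id}")
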