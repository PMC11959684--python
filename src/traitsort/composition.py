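"""Annual community composition from dated biovolume records.

The long-term analysis works on *annual* quantities derived from roughly
biweekly samples: per-taxon biovolume records are linearly interpolated to a
daily series spanning the whole study period (constant extension before the
first and after the last sample), relative shares are formed per day, and
everything is averaged over the 365/366 days of each calendar year.  This
yields, per year *y*: total biovolume ``B_y``, per-taxon relative biovolumes
``b_iy`` (summing to one), per-class shares ``g_jy``, and the long-term
average share ``b̄_i`` of each taxon.

Small-celled taxa, which were inconsistently identified early in long
monitoring series, can be removed with :func:`filter_small_cells`; the
accompanying report quantifies what was discarded on the *pre-filter*
community so the cost of the filter is visible.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import ObservationTable, SchemaError

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ExclusionReport:
    """What a cell-volume filter removed, measured before removal."""

    threshold: float
    n_taxa: int
    n_excluded: int
    fraction_taxa_excluded: float
    mean_biovolume_share: float
    excluded_taxa: tuple[str, ...]
    per_year_share: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [self.threshold],
                "n_taxa": [self.n_taxa],
                "n_excluded": [self.n_excluded],
                "fraction_taxa_excluded": [self.fraction_taxa_excluded],
                "mean_biovolume_share": [self.mean_biovolume_share],
                "excluded_taxa": [";".join(self.excluded_taxa)],
            }
        )


@dataclass(frozen=True)
class AnnualComposition:
    """Annual (relative) biovolume composition.

    ``b``: DataFrame year × taxon of relative biovolumes ``b_iy``;
    ``totals``: Series of total biovolume ``B_y`` (μm³ L⁻¹);
    ``g``: DataFrame year × class of class shares ``g_jy``;
    ``b_bar``: Series of long-term average shares ``b̄_i``;
    ``taxon_class``: Series mapping taxon → class.
    """

    b: pd.DataFrame
    totals: pd.Series
    g: pd.DataFrame
    b_bar: pd.Series
    taxon_class: pd.Series

    def __post_init__(self):
        if (self.b.to_numpy() < -_SUM_TOL).any():
            raise SchemaError("composition: negative relative biovolume")
        row_sums = self.b.sum(axis=1).to_numpy()
        if not np.allclose(row_sums, 1.0, rtol=0, atol=1e-9):
            raise SchemaError("composition: per-year taxon shares do not sum to 1")
        g_sums = self.g.sum(axis=1).to_numpy()
        if not np.allclose(g_sums, 1.0, rtol=0, atol=1e-9):
            raise SchemaError("composition: per-year class shares do not sum to 1")

    @property
    def years(self) -> np.ndarray:
        return self.b.index.to_numpy()

    @property
    def taxa(self) -> list[str]:
        return list(self.b.columns)


def _day_numbers(dates) -> np.ndarray:
    """Calendar dates → integer day counts (days since epoch)."""
    return np.asarray(pd.DatetimeIndex(dates).values.astype("datetime64[D]").astype(np.int64))


def daily_series(dates, values, grid_dates) -> np.ndarray:
    """Linearly interpolate one taxon's observations onto a daily grid.

    Between adjacent sampling dates the value is linear; before the first and
    after the last sample it is held constant at the nearest observation.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    if len(dates) == 0:
        raise ValueError("daily_series: empty observation series")
    order = np.argsort(_day_numbers(dates))
    d = _day_numbers(dates)[order]
    v = values[order]
    return np.interp(_day_numbers(grid_dates), d, v)


def filter_small_cells(
    obs: ObservationTable, threshold: float = 30.0
) -> tuple[ObservationTable, ExclusionReport]:
    """Drop taxa with cell volume strictly below ``threshold`` μm³.

    The report's biovolume share is the excluded taxa's mean share of annual
    community biovolume computed on the unfiltered data.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    meta = obs.meta
    small = meta.loc[meta["cell_volume"] < threshold, "taxon_id"].tolist()
    n_taxa = len(meta)
    if small:
        comp_full = annual_compositions(obs)
        per_year = comp_full.b[small].sum(axis=1)
        mean_share = float(per_year.mean())
        filtered = obs.subset_taxa(set(obs.taxa) - set(small))
    else:
        years = sorted(obs.records["date"].dt.year.unique().tolist())
        per_year = pd.Series(0.0, index=pd.Index(years, name="year"))
        mean_share = 0.0
        filtered = obs
    report = ExclusionReport(
        threshold=threshold,
        n_taxa=n_taxa,
        n_excluded=len(small),
        fraction_taxa_excluded=len(small) / n_taxa if n_taxa else 0.0,
        mean_biovolume_share=mean_share,
        excluded_taxa=tuple(sorted(small)),
        per_year_share=per_year,
    )
    return filtered, report


def annual_compositions(
    obs: ObservationTable,
    years=None,
    share_mode: str = "daily",
) -> AnnualComposition:
    """Annual total, per-taxon and per-class relative biovolumes.

    Parameters
    ----------
    obs:
        Validated (and typically cell-volume filtered) observations.
    years:
        Optional (first, last) year pair; defaults to the span of the data.
    share_mode:
        ``"daily"`` (default) averages the per-day relative shares over each
        year; ``"annual_ratio"`` instead ratios the annual mean biovolumes.
        The two differ whenever composition and total biovolume co-vary
        within a year.
    """
    if share_mode not in ("daily", "annual_ratio"):
        raise ValueError(f"unknown share_mode {share_mode!r}")
    rec = obs.records
    if rec.empty:
        raise ValueError("annual_compositions: no observations")
    obs_years = rec["date"].dt.year
    if years is None:
        y0, y1 = int(obs_years.min()), int(obs_years.max())
    else:
        y0, y1 = map(int, years)
    year_list = np.arange(y0, y1 + 1)
    have = set(obs_years)
    gapped = [int(y) for y in year_list if not ({y - 1, y, y + 1} & have)]
    if gapped:
        raise ValueError(
            f"annual_compositions: no observations within ±1 year of year(s) {gapped}"
        )

    grid = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    taxa = obs.taxa
    mat = np.empty((len(grid), len(taxa)))
    for k, (taxon, group) in enumerate(rec.groupby("taxon_id", sort=True)):
        mat[:, taxa.index(taxon)] = daily_series(group["date"], group["biovolume"], grid)
    observed = set(rec["taxon_id"])
    for k, taxon in enumerate(taxa):
        if taxon not in observed:
            mat[:, k] = 0.0

    totals_day = mat.sum(axis=1)
    if (totals_day <= 0).any():
        bad_day = grid[int(np.argmax(totals_day <= 0))].date()
        raise ValueError(f"annual_compositions: zero community biovolume on {bad_day}")

    year_of_day = grid.year.to_numpy()
    # sanity: every calendar year must contribute its full 365/366 days
    counts = pd.Series(year_of_day).value_counts()
    for y in year_list:
        expect = 366 if calendar.isleap(int(y)) else 365
        if counts[y] != expect:
            raise AssertionError(f"year {y}: {counts[y]} grid days, expected {expect}")

    frame = pd.DataFrame(mat, index=year_of_day, columns=taxa)
    totals = frame.sum(axis=1).groupby(level=0).mean()
    totals.index.name = "year"
    if share_mode == "daily":
        shares = frame.div(frame.sum(axis=1), axis=0)
        b = shares.groupby(level=0).mean()
    else:
        annual_mean = frame.groupby(level=0).mean()
        b = annual_mean.div(annual_mean.sum(axis=1), axis=0)
    b.index.name = "year"
    b.columns.name = "taxon_id"

    taxon_class = obs.taxon_class()
    g = class_aggregate(b, taxon_class)
    b_bar = long_term_average(b)
    return AnnualComposition(b=b, totals=totals, g=g, b_bar=b_bar, taxon_class=taxon_class)


def class_aggregate(b: pd.DataFrame, taxon_class: pd.Series) -> pd.DataFrame:
    """Sum per-taxon shares ``b_iy`` into per-class shares ``g_jy``."""
    missing = [t for t in b.columns if t not in taxon_class.index or taxon_class[t] == ""]
    if missing:
        raise ValueError(f"class_aggregate: taxa without class: {missing}")
    g = b.T.groupby(taxon_class.loc[list(b.columns)]).sum().T
    g.columns.name = "class_id"
    return g


def long_term_average(b: pd.DataFrame) -> pd.Series:
    """Average share of each taxon across all study years (``b̄_i``)."""
    out = b.mean(axis=0)
    out.name = "b_bar"
    return out
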