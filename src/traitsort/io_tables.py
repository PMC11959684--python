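"""Reading, validation and writing of the study's tabular inputs and outputs.

Schema truth for the whole pipeline lives in this module.  Four input tables
are defined:

* :class:`ObservationTable` — dated per-taxon biovolumes (μm³ L⁻¹) with a
  companion metadata table carrying each taxon's cell volume and class.
* :class:`TraitTable` — per-taxon Monod resource-acquisition traits
  (phosphate affinity ``gamma``, light affinity ``alpha``, maximum growth
  rate ``mumax``) with a per-cell provenance flag.
* :class:`TaxonomyTable` — ranked taxonomy (genus → phylum) used for trait
  imputation.
* :class:`EnvironmentTable` — one row per study year with the winter-mixis
  total phosphorus concentration ``tp_mix`` (μmol L⁻¹).

All tables validate on construction and raise :class:`SchemaError` on any
invariant violation, so downstream modules may assume well-formed data.
Files are plain UTF-8 CSV with ISO-8601 dates, ``.`` decimals and empty
fields for missing values.  Because the column layout of external deposits
varies, every reader accepts a ``column_map`` renaming dict instead of
hard-coding source column names.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

RANKS = ("genus", "family", "order", "class", "phylum")
TRAITS = ("gamma", "alpha", "mumax")
PROVENANCE = ("measured", "imputed", "missing")


class SchemaError(ValueError):
    """An input table violates its schema or an invariant."""


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _apply_map(df: pd.DataFrame, column_map) -> pd.DataFrame:
    return df.rename(columns=dict(column_map)) if column_map else df


@dataclass(frozen=True)
class ObservationTable:
    """Dated biovolume records plus per-taxon metadata.

    ``records`` columns: ``date`` (datetime), ``taxon_id`` (str),
    ``biovolume`` (float ≥ 0, μm³ L⁻¹).  ``meta`` columns: ``taxon_id``,
    ``cell_volume`` (float > 0, μm³), ``class_id`` (str).
    """

    records: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        rec = self.records.copy()
        meta = self.meta.copy()
        _require_columns(rec, ("date", "taxon_id", "biovolume"), "observations")
        _require_columns(meta, ("taxon_id", "cell_volume", "class_id"), "observation metadata")

        try:
            rec["date"] = pd.to_datetime(rec["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"observations: unparseable date: {exc}") from None
        rec["taxon_id"] = rec["taxon_id"].astype(str)
        rec["biovolume"] = pd.to_numeric(rec["biovolume"], errors="raise").astype(float)

        if not np.isfinite(rec["biovolume"]).all():
            raise SchemaError("observations: non-finite biovolume")
        if (rec["biovolume"] < 0).any():
            bad = rec.loc[rec["biovolume"] < 0].iloc[0]
            raise SchemaError(
                f"observations: negative biovolume at ({bad['date'].date()}, {bad['taxon_id']})"
            )
        dup = rec.duplicated(subset=["date", "taxon_id"])
        if dup.any():
            bad = rec.loc[dup].iloc[0]
            raise SchemaError(
                f"observations: duplicate (date, taxon) pair ({bad['date'].date()}, {bad['taxon_id']})"
            )

        meta["taxon_id"] = meta["taxon_id"].astype(str)
        meta["class_id"] = meta["class_id"].astype(str)
        if meta["taxon_id"].duplicated().any():
            raise SchemaError("observation metadata: duplicate taxon_id")
        cv = pd.to_numeric(meta["cell_volume"], errors="raise").astype(float)
        bad_cv = meta.loc[~np.isfinite(cv) | (cv <= 0), "taxon_id"].tolist()
        if bad_cv:
            raise SchemaError(f"observation metadata: missing/non-positive cell_volume for taxa {bad_cv}")
        meta["cell_volume"] = cv

        known = set(meta["taxon_id"])
        unknown = sorted(set(rec["taxon_id"]) - known)
        if unknown:
            raise SchemaError(f"observations: taxa without metadata: {unknown}")

        rec = rec.sort_values(["date", "taxon_id"], kind="mergesort").reset_index(drop=True)
        meta = meta.sort_values("taxon_id", kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "records", rec[["date", "taxon_id", "biovolume"]])
        object.__setattr__(self, "meta", meta[["taxon_id", "cell_volume", "class_id"]])

    @property
    def taxa(self) -> list[str]:
        return self.meta["taxon_id"].tolist()

    def taxon_class(self) -> pd.Series:
        return self.meta.set_index("taxon_id")["class_id"]

    def subset_taxa(self, keep) -> "ObservationTable":
        keep = set(keep)
        return ObservationTable(
            self.records[self.records["taxon_id"].isin(keep)],
            self.meta[self.meta["taxon_id"].isin(keep)],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationTable):
            return NotImplemented
        return self.records.equals(other.records) and self.meta.equals(other.meta)


@dataclass(frozen=True)
class TraitTable:
    """Per-taxon Monod traits with per-cell provenance.

    Columns: ``taxon_id``; for each trait in :data:`TRAITS` a value column and
    a ``<trait>_status`` column with a flag from :data:`PROVENANCE`.  Missing
    values are NaN and must carry the ``missing`` flag; all non-missing values
    are strictly positive (the whole analysis is on log traits).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        _require_columns(df, ("taxon_id",) + TRAITS, "traits")
        df["taxon_id"] = df["taxon_id"].astype(str)
        if df["taxon_id"].duplicated().any():
            dup = df.loc[df["taxon_id"].duplicated(), "taxon_id"].iloc[0]
            raise SchemaError(f"traits: duplicate taxon_id {dup!r}")
        for t in TRAITS:
            df[t] = pd.to_numeric(df[t], errors="raise").astype(float)
            scol = f"{t}_status"
            if scol not in df.columns:
                df[scol] = np.where(df[t].isna(), "missing", "measured")
            df[scol] = df[scol].astype(str)
            bad = ~df[scol].isin(PROVENANCE)
            if bad.any():
                raise SchemaError(f"traits: invalid {scol} value {df.loc[bad, scol].iloc[0]!r}")
            if ((df[scol] == "missing") != df[t].isna()).any():
                raise SchemaError(f"traits: {t} missing-flag inconsistent with NaN values")
            nonpos = df[t].notna() & (df[t] <= 0)
            if nonpos.any():
                who = df.loc[nonpos, "taxon_id"].iloc[0]
                raise SchemaError(
                    f"traits: {t} must be positive for log-transform (taxon {who!r})"
                )
        cols = ["taxon_id"] + [c for t in TRAITS for c in (t, f"{t}_status")]
        df = df[cols].sort_values("taxon_id", kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @property
    def taxa(self) -> list[str]:
        return self.table["taxon_id"].tolist()

    @property
    def is_complete(self) -> bool:
        return not any(self.table[t].isna().any() for t in TRAITS)

    def values(self, trait: str) -> pd.Series:
        if trait not in TRAITS:
            raise KeyError(f"unknown trait {trait!r}")
        return self.table.set_index("taxon_id")[trait]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class TaxonomyTable:
    """Ranked taxonomy; empty string means the rank is unknown.

    Ranks must form a tree: a genus belongs to exactly one family, a family
    to one order, and so on up to phylum.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        _require_columns(df, ("taxon_id",) + RANKS, "taxonomy")
        df["taxon_id"] = df["taxon_id"].astype(str)
        if df["taxon_id"].duplicated().any():
            raise SchemaError("taxonomy: duplicate taxon_id")
        for r in RANKS:
            df[r] = df[r].fillna("").astype(str)
        for child, parent in zip(RANKS[:-1], RANKS[1:]):
            sub = df[(df[child] != "") & (df[parent] != "")]
            counts = sub.groupby(child)[parent].nunique()
            bad = counts[counts > 1]
            if len(bad):
                raise SchemaError(
                    f"taxonomy: {child} {bad.index[0]!r} maps to {bad.iloc[0]} distinct {parent} values"
                )
        df = df[["taxon_id", *RANKS]].sort_values("taxon_id", kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "table", df)

    def ranks_of(self, taxon_id: str) -> dict[str, str]:
        row = self.table.loc[self.table["taxon_id"] == taxon_id]
        if row.empty:
            raise KeyError(f"taxon {taxon_id!r} not in taxonomy")
        return {r: row.iloc[0][r] for r in RANKS}

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxonomyTable):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass(frozen=True)
class EnvironmentTable:
    """Yearly nutrient state: columns ``year`` (int) and ``tp_mix`` (> 0, μmol L⁻¹)."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        _require_columns(df, ("year", "tp_mix"), "environment")
        df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
        df["tp_mix"] = pd.to_numeric(df["tp_mix"], errors="raise").astype(float)
        if df["year"].duplicated().any():
            raise SchemaError("environment: duplicate year")
        if not (np.isfinite(df["tp_mix"]) & (df["tp_mix"] > 0)).all():
            raise SchemaError("environment: tp_mix must be finite and positive")
        df = df.sort_values("year", kind="mergesort").reset_index(drop=True)
        years = df["year"].to_numpy()
        if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise SchemaError("environment: years must be contiguous")
        object.__setattr__(self, "table", df[["year", "tp_mix"]])

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    def series(self) -> pd.Series:
        return self.table.set_index("year")["tp_mix"]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnvironmentTable):
            return NotImplemented
        return self.table.equals(other.table)


def check_class_consistency(obs: ObservationTable, taxonomy: TaxonomyTable) -> None:
    """Require the observation metadata class to match the taxonomy class rank."""
    tax = taxonomy.table.set_index("taxon_id")["class"]
    merged = obs.meta.set_index("taxon_id")["class_id"]
    common = merged.index.intersection(tax.index)
    mismatch = common[(tax.loc[common] != "") & (tax.loc[common] != merged.loc[common])]
    if len(mismatch):
        raise SchemaError(
            f"class_id mismatch between observations and taxonomy for taxa {sorted(mismatch)[:5]}"
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_observations(path, meta_path, column_map=None, meta_column_map=None) -> ObservationTable:
    rec = _apply_map(pd.read_csv(path, float_precision="round_trip"), column_map)
    meta = _apply_map(pd.read_csv(meta_path, float_precision="round_trip"), meta_column_map)
    return ObservationTable(rec, meta)


def write_observations(obs: ObservationTable, path, meta_path) -> None:
    rec = obs.records.copy()
    rec["date"] = rec["date"].dt.strftime("%Y-%m-%d")
    rec.to_csv(path, index=False, float_format="%.17g")
    obs.meta.to_csv(meta_path, index=False, float_format="%.17g")


def read_traits(path, column_map=None) -> TraitTable:
    return TraitTable(_apply_map(pd.read_csv(path, float_precision="round_trip"), column_map))


def write_traits(traits: TraitTable, path) -> None:
    traits.table.to_csv(path, index=False, float_format="%.17g")


def read_taxonomy(path, column_map=None) -> TaxonomyTable:
    df = _apply_map(pd.read_csv(path, keep_default_na=False), column_map)
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    taxonomy.table.to_csv(path, index=False)


def read_environment(path, column_map=None) -> EnvironmentTable:
    return EnvironmentTable(_apply_map(pd.read_csv(path, float_precision="round_trip"), column_map))


def write_environment(env: EnvironmentTable, path) -> None:
    env.table.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run manifest


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, entries: dict) -> None:
    """Write a key = value run manifest (config, seed, input hashes)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(entries):
            fh.write(f"{key} = {entries[key]}\n")


def read_manifest(path) -> dict:
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                out[k.strip()] = v.strip()
    return out
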