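import numpy as np
import pandas as pd
import pytest

import traitsort as ts


@pytest.fixture(scope="session")
def default_dataset() -> ts.SyntheticDataset:
    """One synthetic species-sorting dataset shared across the suite."""
    return ts.generate_dataset(ts.SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def default_composition(default_dataset):
    """Filtered observations + annual composition of the shared dataset."""
    obs_f, report = ts.filter_small_cells(default_dataset.observations)
    comp = ts.annual_compositions(obs_f)
    return obs_f, report, comp


def make_observations(rows, meta_rows) -> ts.ObservationTable:
    """Small helper: build an ObservationTable from (date, taxon, value) rows."""
    rec = pd.DataFrame(rows, columns=["date", "taxon_id", "biovolume"])
    meta = pd.DataFrame(meta_rows, columns=["taxon_id", "cell_volume", "class_id"])
    return ts.ObservationTable(rec, meta)


def make_traits(**per_taxon) -> ts.TraitTable:
    """Build a TraitTable from taxon_id -> (gamma, alpha, mumax); None = missing."""
    rows = []
    for taxon, (g, a, m) in per_taxon.items():
        rows.append({"taxon_id": taxon, "gamma": g, "alpha": a, "mumax": m})
    return ts.TraitTable(pd.DataFrame(rows).astype({"gamma": float, "alpha": float, "mumax": float}))


def make_taxonomy(rows) -> ts.TaxonomyTable:
    df = pd.DataFrame(rows, columns=["taxon_id", *ts.io_tables.RANKS])
    return ts.TaxonomyTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
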