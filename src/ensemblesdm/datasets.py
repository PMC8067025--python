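"""Packaged reference tables: the variable catalogue and the carcass records.

The variable catalogue mirrors the printed 27-factor table of candidate
environmental variables (the human-population-density row is unnumbered in
the printed table and is carried here the same way). The carcass table holds
the 20 printed carcass records from the 2010 snowfall event.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mortality import CarcassRecord, read_carcass_table


def _data_path(name: str):
    return resources.files("ensemblesdm.data") / name


def variable_catalogue() -> pd.DataFrame:
    """The candidate-variable catalogue (27 numbered factors)."""
    with resources.as_file(_data_path("table1_variables.csv")) as path:
        return pd.read_csv(path)


def n_candidate_variables(catalogue: pd.DataFrame | None = None) -> int:
    """Count of numbered candidate variables in the catalogue."""
    cat = catalogue if catalogue is not None else variable_catalogue()
    return int(cat["no"].notna().sum())


def carcass_records() -> list[CarcassRecord]:
    """The packaged carcass table as parsed records."""
    with resources.as_file(_data_path("table2_carcasses.csv")) as path:
        return read_carcass_table(path)
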