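"""Worked-example affinity tables for D2 receptor mutants.

Ships the measured binding affinities (pK with the corresponding K in nM) of
wild-type and mutant SNAP-tagged D2 receptors for spiperone, risperidone and
eticlopride, from two assay formats: [3H]spiperone radioligand binding
("radioligand") and TR-FRET binding with a fluorescent spiperone tracer
("trfret"). These serve as inputs for the pharmacology worked examples —
pK -> K conversion and mutant/WT fold-change computation — and as ground
truth for synthetic assay-data generation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import DataError
from .pharm import fold_change

__all__ = ["load_affinity_tables", "affinity", "affinity_fold"]


def load_affinity_tables() -> pd.DataFrame:
    """The affinity tables as a tidy DataFrame
    (table, construct, ligand, assay, pK, K_nM, n)."""
    with resources.files("gpcrdyn.data").joinpath("d2r_affinity_tables.csv").open() as fh:
        return pd.read_csv(fh)


def affinity(table: str, construct: str, ligand: str,
             df: pd.DataFrame | None = None) -> dict:
    """One affinity record; raises :class:`DataError` if absent."""
    df = load_affinity_tables() if df is None else df
    sub = df[(df.table == table) & (df.construct == construct) & (df.ligand == ligand)]
    if len(sub) != 1:
        raise DataError(f"no unique record for ({table}, {construct}, {ligand})")
    return sub.iloc[0].to_dict()


def affinity_fold(table: str, mutant: str, ligand: str,
                  wt: str = "WT", df: pd.DataFrame | None = None) -> float:
    """Mutant/WT affinity fold-change from the tabulated K values (nM)."""
    df = load_affinity_tables() if df is None else df
    k_mut = affinity(table, mutant, ligand, df)["K_nM"]
    k_wt = affinity(table, wt, ligand, df)["K_nM"]
    return fold_change(k_mut, k_wt)
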