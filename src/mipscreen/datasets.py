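"""Packaged reference tables from the doublet-microtubule proteomics study.

Two small curated tables ship with the package:

* ``axoneme_top35_stoichiometry`` — the 35 highest-stoichiometry proteins of
  salt-extracted *Chlamydomonas* doublets: molecular weight (kDa), averaged
  quantitative value over triplicate label-free runs, the published 2-decimal
  RSPA, homolog accessions in *T. thermophila* and human ("-" = no homolog),
  and the annotated localization.
* ``fap52ko_missing_proteins`` — the proteins with no peptide detected in the
  FAP52-knockout axoneme: molecular weight, the reported WT-vs-KO p-value and
  the triplicate WT exclusive unique peptide counts and normalized
  quantitative values.

``homolog_sizes_synthetic`` is a stand-in table of homolog sizes (the real
homolog lengths are not part of the curated tables); values are synthetic and
chosen so the FAP115 and FAP161 *Tetrahymena* homologs are disproportionately
large, as reported qualitatively.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core_io import Homolog, ProteinEntry
from .differential import DiffRecord

__all__ = [
    "load_doublet_stoichiometry",
    "doublet_stoichiometry_entries",
    "load_fap52ko_missing",
    "fap52ko_missing_diff_records",
    "load_synthetic_homolog_sizes",
    "TETRAHYMENA",
    "HUMAN",
]

TETRAHYMENA = "T. thermophila"
HUMAN = "H. sapiens"


def _read(name: str) -> pd.DataFrame:
    with resources.files("mipscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_doublet_stoichiometry() -> pd.DataFrame:
    """The top-35 doublet stoichiometry table as a DataFrame."""
    return _read("axoneme_top35_stoichiometry.tsv")


def doublet_stoichiometry_entries(
    with_synthetic_homolog_sizes: bool = False,
) -> list[ProteinEntry]:
    """The stoichiometry table as annotated :class:`ProteinEntry` objects.

    Homolog annotations carry presence/absence for *T. thermophila* and human;
    with ``with_synthetic_homolog_sizes`` the synthetic homolog-size stand-ins
    are attached to the *Tetrahymena* homologs that have one.
    """
    df = load_doublet_stoichiometry()
    sizes = {}
    if with_synthetic_homolog_sizes:
        hs = load_synthetic_homolog_sizes()
        sizes = {
            (r.protein_id, r.species): float(r.homolog_mw_kda)
            for r in hs.itertuples(index=False)
        }
    entries = []
    for row in df.itertuples(index=False):
        homologs = {
            TETRAHYMENA: Homolog(
                row.homolog_tetrahymena, sizes.get((row.name, TETRAHYMENA))
            ),
            HUMAN: Homolog(row.homolog_human),
        }
        entries.append(
            ProteinEntry(
                id=row.name,
                mw_kda=float(row.mw_kda),
                localization=row.localization,
                homologs=homologs,
            )
        )
    return entries


def load_fap52ko_missing() -> pd.DataFrame:
    """The FAP52-knockout completely-missing proteins as a DataFrame."""
    df = _read("fap52ko_missing_proteins.tsv")
    for col in ("wt_peptides", "wt_values"):
        df[col] = df[col].map(lambda s: tuple(int(v) for v in s.split(",")))
    return df


def fap52ko_missing_diff_records() -> list[DiffRecord]:
    """The missing set as :class:`DiffRecord` objects (all-zero KO replicates)."""
    records = []
    for row in load_fap52ko_missing().itertuples(index=False):
        wt = np.array(row.wt_values, dtype=float)
        records.append(
            DiffRecord(
                protein_id=row.name,
                wt_values=wt,
                ko_values=np.zeros_like(wt),
                fold_change=float("inf"),
                p_value=float(row.p_value),
                status="missing",
                wt_peptides=np.array(row.wt_peptides, dtype=float),
                ko_peptides=np.zeros_like(wt),
            )
        )
    return records


def load_synthetic_homolog_sizes() -> pd.DataFrame:
    """Synthetic stand-in homolog sizes (see module docstring)."""
    return _read("homolog_sizes_synthetic.tsv")
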