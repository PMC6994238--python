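"""Data model and readers/writers for proteomes, quant tables and expression matrices.

Every downstream module consumes only the types defined here. Tabular I/O is
TSV with a one-line header; CSV is accepted via ``sep=","``. The absent-homolog
marker in homolog columns is ``"-"`` and means "this species has no homolog",
which is distinct from the annotation simply being unknown (missing key).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights

__all__ = [
    "ABSENT_HOMOLOG",
    "Homolog",
    "ProteinEntry",
    "QuantTable",
    "ExpressionMatrix",
    "sequence_mw_kda",
    "parse_proteome",
    "write_proteome",
    "parse_quant_table",
    "read_homolog_map",
]

#: marker used in homolog columns for "no homolog exists in that species"
ABSENT_HOMOLOG = "-"

_WATER = 18.0153
# average residue masses: free amino-acid average weights minus one water
_RESIDUE_MASS = {aa: w - _WATER for aa, w in protein_weights.items()}
# unknown residue X contributes the unweighted mean residue mass
_RESIDUE_MASS["X"] = float(np.mean(list(_RESIDUE_MASS.values())))

_VALID_RESIDUES = frozenset(_RESIDUE_MASS)


def sequence_mw_kda(sequence: str) -> float:
    """Average molecular weight of a polypeptide in kDa.

    Sums standard average residue masses plus one water for the termini.
    ``X`` counts as the mean residue mass. Raises ``ValueError`` for an empty
    sequence (a 0-residue protein has no defined mass here) or for letters
    outside the 20 standard residues plus X.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    for pos, aa in enumerate(seq):
        if aa not in _VALID_RESIDUES:
            raise ValueError(f"non-amino-acid character {aa!r} at position {pos}")
    return (sum(_RESIDUE_MASS[aa] for aa in seq) + _WATER) / 1000.0


@dataclass(frozen=True)
class Homolog:
    """A homolog annotation for one species: id (or absent marker) and optional size."""

    homolog_id: str
    mw_kda: float | None = None

    @property
    def absent(self) -> bool:
        return self.homolog_id == ABSENT_HOMOLOG


@dataclass
class ProteinEntry:
    """One proteome sequence with identity, size and annotation metadata.

    ``mw_kda`` comes from an input table when given, else is computed from the
    sequence. ``homologs`` maps species name to a :class:`Homolog`; a missing
    species key means "unknown", while a :class:`Homolog` with the ``"-"``
    marker means "known to be absent".
    """

    id: str
    sequence: str = ""
    description: str = ""
    mw_kda: float | None = None
    localization: str | None = None
    homologs: dict[str, Homolog] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sequence and self.mw_kda is None:
            self.mw_kda = sequence_mw_kda(self.sequence)
        if self.mw_kda is not None and self.mw_kda <= 0:
            raise ValueError(f"{self.id}: mw_kda must be positive, got {self.mw_kda}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_proteome(fasta_source) -> list[ProteinEntry]:
    """Read a FASTA proteome into a list of :class:`ProteinEntry`, order preserved.

    ``fasta_source`` is a path or an open text handle. Sequences may be
    line-wrapped. Duplicate ids and non-amino-acid characters raise
    ``ValueError``.
    """
    if isinstance(fasta_source, (str, Path)):
        with open(fasta_source) as fh:
            return parse_proteome(fh)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(fasta_source, "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate protein id {record.id!r} in FASTA input")
        seen.add(record.id)
        seq = str(record.seq).upper()
        for pos, aa in enumerate(seq):
            if aa not in _VALID_RESIDUES:
                raise ValueError(
                    f"{record.id}: non-amino-acid character {aa!r} at position {pos}"
                )
        entries.append(
            ProteinEntry(id=record.id, sequence=seq, description=record.description)
        )
    return entries


def write_proteome(entries: Iterable[ProteinEntry], path, width: int = 60) -> None:
    """Write entries as FASTA, wrapping sequence lines at ``width`` residues."""
    with open(path, "w") as fh:
        for e in entries:
            header = e.description if e.description else e.id
            fh.write(f">{header}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


class QuantTable:
    """Per-protein replicate quantitative values for named conditions.

    ``values[condition]`` is a DataFrame (proteins x replicates) of
    non-negative label-free quantitative values; ``peptides[condition]``, when
    present, holds exclusive unique peptide counts with the same shape.
    Replicate counts are equal across proteins within a condition by
    construction (rectangular DataFrames).
    """

    def __init__(
        self,
        mw_kda: Mapping[str, float],
        values: Mapping[str, pd.DataFrame],
        peptides: Mapping[str, pd.DataFrame] | None = None,
    ) -> None:
        self.mw_kda = pd.Series(mw_kda, dtype=float)
        self.values = {c: df.astype(float) for c, df in values.items()}
        self.peptides = {c: df.astype(float) for c, df in (peptides or {}).items()}
        for cond, df in self.values.items():
            if df.shape[1] < 1:
                raise ValueError(f"condition {cond!r} has no replicate columns")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative quantitative value in condition {cond!r}")
        for cond, df in self.peptides.items():
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative peptide count in condition {cond!r}")

    @property
    def conditions(self) -> list[str]:
        return list(self.values)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values[next(iter(self.values))].index)

    def condition_values(self, condition: str) -> pd.DataFrame:
        if condition not in self.values:
            raise KeyError(f"condition not found: {condition!r}")
        return self.values[condition]

    def condition_peptides(self, condition: str) -> pd.DataFrame | None:
        return self.peptides.get(condition)

    def replicate_values(self, protein_id: str, condition: str) -> np.ndarray:
        return self.condition_values(condition).loc[protein_id].to_numpy()

    def aqv(self, condition: str) -> pd.Series:
        """Averaged quantitative value: arithmetic mean over replicates."""
        return self.condition_values(condition).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one wide DataFrame (protein_id, mw_kda, <cond>_<i>, ...)."""
        out = pd.DataFrame({"protein_id": self.protein_ids})
        out["mw_kda"] = self.mw_kda.reindex(out["protein_id"]).to_numpy()
        for cond, df in self.values.items():
            for i in range(df.shape[1]):
                out[f"{cond}_{i + 1}"] = df.iloc[:, i].to_numpy()
        for cond, df in self.peptides.items():
            for i in range(df.shape[1]):
                out[f"{cond}_pep_{i + 1}"] = df.iloc[:, i].to_numpy()
        return out

    def write_tsv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def parse_quant_table(
    tabular_source,
    condition_columns: Mapping[str, Sequence[str]],
    peptide_columns: Mapping[str, Sequence[str]] | None = None,
    *,
    id_column: str = "protein_id",
    mw_column: str = "mw_kda",
    sep: str = "\t",
    absent_as_zero: bool = False,
) -> QuantTable:
    """Read a wide TSV/CSV quant table into a :class:`QuantTable`.

    ``condition_columns`` maps each condition name to its ordered replicate
    column names. Missing cells are an error unless ``absent_as_zero`` is set,
    in which case they read as 0. Negative values and ragged replicate
    structures (NaN in some replicates of a row) raise ``ValueError``.
    """
    df = pd.read_csv(tabular_source, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    df = df.set_index(id_column)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate protein id {dup!r} in quant table")

    def _block(cols: Sequence[str], what: str, cond: str) -> pd.DataFrame:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KeyError(f"condition not found: {cond!r} ({what} columns {missing})")
        block = df[list(cols)].copy()
        if block.isna().any().any():
            if absent_as_zero:
                block = block.fillna(0.0)
            else:
                raise ValueError(
                    f"missing cells in {what} columns of condition {cond!r}; "
                    "pass absent_as_zero=True to read them as 0"
                )
        return block.astype(float)

    values = {c: _block(cols, "value", c) for c, cols in condition_columns.items()}
    peptides = {
        c: _block(cols, "peptide", c) for c, cols in (peptide_columns or {}).items()
    }
    if mw_column in df.columns:
        mw = df[mw_column].astype(float).to_dict()
    else:
        mw = {}
    return QuantTable(mw, values, peptides)


class ExpressionMatrix:
    """Consensus normalized expression, genes x tissues, unitless and >= 0."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.duplicated().any():
            raise ValueError("duplicate gene labels")
        if frame.columns.duplicated().any():
            raise ValueError("duplicate tissue labels")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    def expression(self, gene: str) -> pd.Series:
        if gene not in self.frame.index:
            raise KeyError(f"unknown gene: {gene!r}")
        return self.frame.loc[gene]

    @classmethod
    def read_tsv(cls, source, sep: str = "\t") -> "ExpressionMatrix":
        return cls(pd.read_csv(source, sep=sep, index_col=0))

    def write_tsv(self, path, sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index_label="gene")


def read_homolog_map(source, sep: str = "\t") -> pd.DataFrame:
    """Read a homolog map table (protein_id, species, homolog_id, homolog_mw_kda).

    ``homolog_id == "-"`` encodes a known-absent homolog. Returns a tidy
    DataFrame; use :func:`annotate_homologs` to fold it into ProteinEntry
    objects.
    """
    df = pd.read_csv(source, sep=sep)
    required = {"protein_id", "species", "homolog_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"homolog map missing columns: {sorted(missing)}")
    return df


def annotate_homologs(entries: Iterable[ProteinEntry], homolog_map: pd.DataFrame) -> None:
    """Attach homolog annotations from a tidy map to entries, in place."""
    by_id = {e.id: e for e in entries}
    has_mw = "homolog_mw_kda" in homolog_map.columns
    for row in homolog_map.itertuples(index=False):
        entry = by_id.get(row.protein_id)
        if entry is None:
            continue
        mw = getattr(row, "homolog_mw_kda", None) if has_mw else None
        mw = None if mw is None or pd.isna(mw) else float(mw)
        entry.homologs[row.species] = Homolog(str(row.homolog_id), mw)


def write_json_report(obj, path) -> None:
    """Serialize a report object to pretty JSON (stable key order)."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON serializable: {type(o)}")

    text = json.dumps(obj, indent=2, sort_keys=True, default=_default)
    if isinstance(path, (str, Path)):
        Path(path).write_text(text + "\n")
    else:
        path.write(text + "\n")
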