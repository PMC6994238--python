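"""Rough stoichiometric peptide abundance (RSPA) and copy-number ranking.

RSPA is a deliberately rough copy-number proxy for label-free proteomics of a
stoichiometric complex: the averaged quantitative value (AQV, mean over
replicates) of a protein scales with copy number times molecular weight, so

    RSPA = AQV / MW * 10

is proportional to copies per structural repeat. The factor 10 only sets a
convenient display scale; it cancels in every ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import QuantTable

__all__ = ["StoichRow", "compute_rspa", "rank_by_rspa", "top_n"]


@dataclass(frozen=True)
class StoichRow:
    """RSPA accounting for one protein: MW (kDa), AQV, RSPA and 1-based rank."""

    protein_id: str
    mw_kda: float
    aqv: float
    rspa: float
    rank: int


def compute_rspa(mw_kda: float, aqv: float) -> float:
    """RSPA = (AQV / MW) * 10, at full precision.

    Display rounding to two decimals is a formatting concern only. ``mw_kda``
    must be positive; ``aqv`` must be non-negative.
    """
    if mw_kda <= 0:
        raise ValueError(f"mw_kda must be positive, got {mw_kda}")
    if aqv < 0:
        raise ValueError(f"aqv must be non-negative, got {aqv}")
    return aqv / mw_kda * 10.0


def rank_by_rspa(
    table: QuantTable | Iterable[tuple[str, float, float]],
    condition: str | None = None,
) -> list[StoichRow]:
    """Rank proteins by descending RSPA.

    Accepts either a :class:`QuantTable` (with the condition whose replicates
    define AQV) or an iterable of ``(protein_id, mw_kda, aqv)`` triples. Ties
    in RSPA are broken by ascending protein id, so the ordering is total and
    deterministic. Returns one :class:`StoichRow` per protein; ranks are the
    permutation 1..N.
    """
    if isinstance(table, QuantTable):
        if condition is None:
            raise ValueError("condition is required when ranking a QuantTable")
        aqv = table.aqv(condition)
        triples = [
            (pid, float(table.mw_kda[pid]), float(aqv[pid])) for pid in table.protein_ids
        ]
    else:
        triples = [(str(i), float(m), float(a)) for i, m, a in table]

    scored = [(compute_rspa(mw, aqv), pid, mw, aqv) for pid, mw, aqv in triples]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        StoichRow(protein_id=pid, mw_kda=mw, aqv=aqv, rspa=rspa, rank=i + 1)
        for i, (rspa, pid, mw, aqv) in enumerate(scored)
    ]


def top_n(rows: Sequence[StoichRow], n: int) -> list[StoichRow]:
    """First ``n`` rows of an RSPA ranking (the high-stoichiometry set)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return list(rows[:n])
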