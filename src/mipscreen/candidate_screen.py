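"""Multi-criteria candidate screening for unassigned cryo-EM densities.

Given an RSPA ranking, per-protein annotations (molecular weight, homolog
presence and size per species, localization) and optionally a knockout
differential, the screen keeps proteins that satisfy every active criterion:

1. stoichiometry  — inside the top-N RSPA ranks ("high stoichiometry");
2. size           — molecular weight inside an inclusive kDa window from the
                    density trace;
3. conservation   — homolog required (or required absent) in listed species;
4. homolog size   — a required homolog must not be disproportionately larger
                    than the query (a "too big" homolog cannot fit the same
                    density);
5. localization / blacklist — proteins of known other localization, or
                    already-assigned proteins, are excluded;
6. knockout evidence — optionally require a differential status (missing or
                    reduced in the knockout).

Criteria are evaluated in that fixed order; the order affects only which
criterion is recorded as the first failure, never shortlist membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import ProteinEntry
from .differential import DiffRecord
from .stoichiometry import StoichRow

__all__ = [
    "ScreenCriteria",
    "CandidateVerdict",
    "CandidateReport",
    "apply_criteria",
    "identify_from_trace",
]

CRITERIA_ORDER = (
    "stoichiometry",
    "mw_window",
    "conservation",
    "homolog_size",
    "localization",
    "blacklist",
    "diff_status",
)


@dataclass
class ScreenCriteria:
    """Thresholds and requirements for one screen; the single source of truth.

    ``conservation_required`` lists species in which a homolog must exist;
    ``conservation_absent`` lists species in which no homolog may exist (used
    for species-specific candidates). ``homolog_size_max_ratio`` rejects a
    required homolog whose size exceeds that multiple of the query size.
    """

    require_top_n_stoichiometry: int = 35
    mw_window_kda: tuple[float, float] | None = None  # inclusive
    conservation_required: tuple[str, ...] = ()
    conservation_absent: tuple[str, ...] = ()
    homolog_size_max_ratio: float | None = None  # default off; 2.0 is typical
    excluded_localizations: frozenset[str] = frozenset()
    known_protein_blacklist: frozenset[str] = frozenset()
    required_diff_status: str | None = None  # "missing" or "reduced"

    def __post_init__(self) -> None:
        if self.require_top_n_stoichiometry < 1:
            raise ValueError("require_top_n_stoichiometry must be >= 1")
        if self.mw_window_kda is not None and self.mw_window_kda[0] > self.mw_window_kda[1]:
            raise ValueError("mw window min > max")
        self.excluded_localizations = frozenset(self.excluded_localizations)
        self.known_protein_blacklist = frozenset(self.known_protein_blacklist)


@dataclass
class CandidateVerdict:
    """Per-protein criterion flags and the final verdict."""

    protein_id: str
    stoich_rank: int
    flags: dict[str, bool] = field(default_factory=dict)
    shortlisted: bool = False
    first_failure: str | None = None


@dataclass
class CandidateReport:
    """Screen outcome: every evaluated protein plus the ordered shortlist."""

    verdicts: list[CandidateVerdict]
    shortlist: list[str]  # protein ids, sorted by stoichiometry rank

    def verdict(self, protein_id: str) -> CandidateVerdict:
        for v in self.verdicts:
            if v.protein_id == protein_id:
                return v
        raise KeyError(f"no verdict for {protein_id!r}")


def _evaluate(
    row: StoichRow,
    entry: ProteinEntry,
    criteria: ScreenCriteria,
    diff_status: str | None,
) -> CandidateVerdict:
    flags: dict[str, bool] = {}

    flags["stoichiometry"] = row.rank <= criteria.require_top_n_stoichiometry

    if criteria.mw_window_kda is None:
        flags["mw_window"] = True
    else:
        lo, hi = criteria.mw_window_kda
        mw = entry.mw_kda if entry.mw_kda is not None else row.mw_kda
        flags["mw_window"] = lo <= mw <= hi

    conserved = True
    for species in criteria.conservation_required:
        if species not in entry.homologs:
            raise ValueError(
                f"{entry.id}: homolog annotation for species {species!r} missing"
            )
        conserved &= not entry.homologs[species].absent
    for species in criteria.conservation_absent:
        if species not in entry.homologs:
            raise ValueError(
                f"{entry.id}: homolog annotation for species {species!r} missing"
            )
        conserved &= entry.homologs[species].absent
    flags["conservation"] = conserved

    size_ok = True
    if criteria.homolog_size_max_ratio is not None:
        query_mw = entry.mw_kda if entry.mw_kda is not None else row.mw_kda
        for species in criteria.conservation_required:
            hom = entry.homologs.get(species)
            if hom is None or hom.absent or hom.mw_kda is None:
                continue
            if hom.mw_kda / query_mw > criteria.homolog_size_max_ratio:
                size_ok = False
    flags["homolog_size"] = size_ok

    flags["localization"] = entry.localization not in criteria.excluded_localizations
    flags["blacklist"] = entry.id not in criteria.known_protein_blacklist

    if criteria.required_diff_status is None:
        flags["diff_status"] = True
    else:
        flags["diff_status"] = diff_status == criteria.required_diff_status

    first_failure = next((c for c in CRITERIA_ORDER if not flags[c]), None)
    return CandidateVerdict(
        protein_id=row.protein_id,
        stoich_rank=row.rank,
        flags=flags,
        shortlisted=first_failure is None,
        first_failure=first_failure,
    )


def apply_criteria(
    stoich_rows: Sequence[StoichRow],
    proteome: Iterable[ProteinEntry] | Mapping[str, ProteinEntry],
    criteria: ScreenCriteria,
    diff_records: Sequence[DiffRecord] | None = None,
) -> CandidateReport:
    """Evaluate every ranked protein against the screen criteria.

    ``proteome`` supplies annotations (MW, homologs, localization) and may be
    a mapping or an iterable of entries. Proteins in the ranking without an
    annotation entry get a minimal stand-in carrying only the ranking's MW —
    sufficient unless a conservation criterion is active, in which case the
    missing annotation raises. Shortlist is ordered by stoichiometry rank.
    """
    if not isinstance(proteome, Mapping):
        proteome = {e.id: e for e in proteome}
    status_by_id = {r.protein_id: r.status for r in (diff_records or [])}

    verdicts = []
    for row in sorted(stoich_rows, key=lambda r: r.rank):
        entry = proteome.get(row.protein_id)
        if entry is None:
            entry = ProteinEntry(id=row.protein_id, mw_kda=row.mw_kda)
        verdicts.append(_evaluate(row, entry, criteria, status_by_id.get(row.protein_id)))

    shortlist = [v.protein_id for v in verdicts if v.shortlisted]
    return CandidateReport(verdicts=verdicts, shortlist=shortlist)


def identify_from_trace(
    trace_length_aa: int,
    trace_mw_kda: float,
    diff_records: Sequence[DiffRecord],
    mw_by_id: Mapping[str, float],
    *,
    tolerance: float = 0.2,
    required_status: str = "missing",
) -> list[str]:
    """Match a short traced density to knockout-supported candidates by size.

    Keeps proteins whose molecular weight lies within ``tolerance`` (a
    fraction of the trace mass) of ``trace_mw_kda`` AND whose differential
    status equals ``required_status``; returns ids sorted by |MW - trace MW|,
    ties by id. An empty result is a valid outcome. ``trace_length_aa`` is
    recorded context from the backbone trace; the mass criterion is the
    operative filter since MW is what the quant table provides.
    """
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    if trace_mw_kda <= 0:
        raise ValueError("trace_mw_kda must be positive")

    window = trace_mw_kda * tolerance
    matches: list[tuple[float, str]] = []
    for rec in diff_records:
        if rec.status != required_status:
            continue
        mw = mw_by_id.get(rec.protein_id)
        if mw is None:
            continue
        if abs(mw - trace_mw_kda) <= window:
            matches.append((abs(mw - trace_mw_kda), rec.protein_id))
    matches.sort()
    return [pid for _, pid in matches]
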