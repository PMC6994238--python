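"""Density-signature pattern searches over a proteome.

A cryo-EM backbone trace exposes a "density signature": the spacing of bulky,
recognizable side chains along the chain. Such a signature is expressible as
a compact residue pattern, e.g. ``[FHY]xWxxKxx[FHY]`` — an aromatic, any
residue, a tryptophan, two wildcards, a lysine, two wildcards, an aromatic.
This module compiles those patterns into sequence searches with two
trace-specific constraints:

* a whole-protein length window, because the trace bounds the chain length;
* a search direction — the trace direction along the density is often
  unknown, so a signature may need to be matched **reversed** (the token list
  read back-to-front, i.e. looking from the C- instead of the N-terminus).
  Reversal is token reversal, never residue complementation.

The wildcard token is lowercase ``x`` exactly; an uppercase ``X`` in a
signature is a literal unknown-residue match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import ProteinEntry

__all__ = [
    "MotifQuery",
    "MotifHit",
    "parse_signature",
    "compile_signature",
    "search_sequence",
    "search_proteome",
]

_AA = "ACDEFGHIKLMNPQRSTVWYX"


def parse_signature(signature: str) -> list[str]:
    """Split a signature into tokens: residue letters, ``x`` wildcards, classes.

    Raises ``ValueError`` with the offending position for unbalanced brackets,
    empty classes and illegal characters.
    """
    tokens: list[str] = []
    i = 0
    while i < len(signature):
        ch = signature[i]
        if ch == "[":
            j = signature.find("]", i)
            if j == -1:
                raise ValueError(f"unbalanced bracket at position {i}")
            members = signature[i + 1 : j]
            if not members:
                raise ValueError(f"empty residue class at position {i}")
            for k, m in enumerate(members):
                if m.upper() not in _AA or not m.isupper():
                    raise ValueError(
                        f"illegal residue {m!r} in class at position {i + 1 + k}"
                    )
            tokens.append(f"[{members}]")
            i = j + 1
        elif ch == "x":
            tokens.append("x")
            i += 1
        elif ch.isupper() and ch in _AA:
            tokens.append(ch)
            i += 1
        else:
            raise ValueError(f"illegal character {ch!r} at position {i}")
    if not tokens:
        raise ValueError("signature is empty")
    return tokens


def reverse_tokens(tokens: Sequence[str]) -> list[str]:
    """Token-level reversal: ``WPxxxxxW`` becomes ``WxxxxxPW``."""
    return list(reversed(tokens))


def _tokens_to_regex(tokens: Sequence[str]) -> re.Pattern:
    parts = ["." if t == "x" else t for t in tokens]
    # lookahead wrapper so finditer reports overlapping matches
    return re.compile("(?=(" + "".join(parts) + "))")


def compile_signature(signature: str, direction: str = "forward") -> dict[str, re.Pattern]:
    """Compile a signature into regex matchers keyed by direction.

    ``direction`` is ``forward``, ``reverse`` or ``both``. Matching is done on
    upper-cased sequences; overlapping matches are found via a lookahead
    wrapper.
    """
    if direction not in ("forward", "reverse", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    tokens = parse_signature(signature)
    matchers: dict[str, re.Pattern] = {}
    if direction in ("forward", "both"):
        matchers["forward"] = _tokens_to_regex(tokens)
    if direction in ("reverse", "both"):
        matchers["reverse"] = _tokens_to_regex(reverse_tokens(tokens))
    return matchers


@dataclass(frozen=True)
class MotifQuery:
    """A density-signature pattern with protein-length window and direction."""

    signature: str
    length_window: tuple[int, int] | None = None  # inclusive (Lmin, Lmax)
    direction: str = "forward"

    def __post_init__(self) -> None:
        parse_signature(self.signature)  # validate eagerly
        if self.length_window is not None:
            lmin, lmax = self.length_window
            if lmin > lmax:
                raise ValueError(f"length window min {lmin} > max {lmax}")

    @property
    def n_tokens(self) -> int:
        return len(parse_signature(self.signature))


@dataclass(frozen=True)
class MotifHit:
    """One match span in 0-based half-open residue coordinates."""

    protein_id: str
    start: int
    end: int
    matched_seq: str
    direction: str

    def human_span(self) -> tuple[int, int]:
        """1-based inclusive coordinates for human-readable reports."""
        return self.start + 1, self.end


def search_sequence(
    protein_id: str, sequence: str, matchers: dict[str, re.Pattern]
) -> list[MotifHit]:
    """All (including overlapping) matches of the compiled matchers."""
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for direction, pattern in matchers.items():
        for m in pattern.finditer(seq):
            s, matched = m.start(), m.group(1)
            hits.append(MotifHit(protein_id, s, s + len(matched), matched, direction))
    hits.sort(key=lambda h: (h.start, h.direction))
    return hits


def search_proteome(
    proteome: Iterable[ProteinEntry],
    query: MotifQuery,
    *,
    apply_length_filter: bool = True,
) -> tuple[list[MotifHit], list[str]]:
    """Scan a proteome for a signature under the query's constraints.

    Only proteins inside the inclusive length window are scanned (disable via
    ``apply_length_filter`` to scan everything). Returns all hits sorted by
    protein id then start position, plus the distinct matched protein ids.
    """
    matchers = compile_signature(query.signature, query.direction)
    hits: list[MotifHit] = []
    for entry in proteome:
        if apply_length_filter and query.length_window is not None:
            lmin, lmax = query.length_window
            if not (lmin <= entry.length <= lmax):
                continue
        hits.extend(search_sequence(entry.id, entry.sequence, matchers))
    hits.sort(key=lambda h: (h.protein_id, h.start, h.direction))
    matched_proteins = sorted({h.protein_id for h in hits})
    return hits, matched_proteins
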