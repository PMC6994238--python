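"""Tissue co-expression of gene pairs over consensus normalized expression.

Functionally related ciliary genes tend to be co-expressed across ciliated
tissues. This module computes Pearson's r for listed gene pairs across the
tissue columns of an :class:`~mipscreen.core_io.ExpressionMatrix`, with an
exclusion list so the analysis can be repeated without tissues that dominate
the correlation (e.g. testis), probing whether the association survives.

Expression values are used untransformed by default; ``log1p=True`` applies
log(1+x) first. p-values come from the exact t transform of r with n-2
degrees of freedom (the standard normal-theory test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix

__all__ = ["CorrelationResult", "correlate_pair", "correlate_pairs"]


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    n_tissues: int
    r: float
    p_value: float
    excluded_tissues: tuple[str, ...] = ()


def correlate_pair(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    exclude_tissues: Sequence[str] = (),
    *,
    log1p: bool = False,
) -> CorrelationResult:
    """Pearson correlation of one gene pair over the retained tissues.

    Exclusion is by exact tissue-label match; an unknown gene or tissue label
    raises ``KeyError`` naming it. At least 3 tissues must remain, and a
    zero-variance vector raises rather than propagating NaN.
    """
    unknown = [t for t in exclude_tissues if t not in matrix.frame.columns]
    if unknown:
        raise KeyError(f"unknown tissue label(s): {unknown}")
    keep = [t for t in matrix.tissues if t not in set(exclude_tissues)]
    if len(keep) < 3:
        raise ValueError(f"only {len(keep)} tissues left after exclusion; need >= 3")

    a = matrix.expression(gene_a)[keep].to_numpy(dtype=float)
    b = matrix.expression(gene_b)[keep].to_numpy(dtype=float)
    if log1p:
        a, b = np.log1p(a), np.log1p(b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError(
            f"zero-variance expression for {gene_a if np.ptp(a) == 0 else gene_b!r}; "
            "r is undefined"
        )
    res = stats.pearsonr(a, b)
    return CorrelationResult(
        gene_a=gene_a,
        gene_b=gene_b,
        n_tissues=len(keep),
        r=float(res.statistic),
        p_value=float(res.pvalue),
        excluded_tissues=tuple(exclude_tissues),
    )


def correlate_pairs(
    matrix: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    exclude_tissues: Sequence[str] = (),
    *,
    log1p: bool = False,
) -> list[CorrelationResult]:
    """Correlate each listed pair; results are returned in input-pair order."""
    return [
        correlate_pair(matrix, a, b, exclude_tissues, log1p=log1p) for a, b in pairs
    ]
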