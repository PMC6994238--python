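"""Wild-type vs knockout differential classification of axonemal proteomics.

Each protein detected in either condition is classified as one of

* ``missing``   — no evidence at all in the knockout (every peptide count, or
  every quantitative value when counts are unavailable, is zero) while the
  wild type has signal;
* ``reduced``   — mean(WT)/mean(KO) at least the reduction threshold
  (default twofold);
* ``increased`` — the symmetric condition, mean(KO)/mean(WT) at least the
  threshold;
* ``unchanged`` — anything else.

A protein absent from both conditions has no defined status and raises.
The per-protein p-value is reported for reference only and never overrides
the category. Fold change of a missing protein is marked infinite rather
than being regularized with a pseudocount, which keeps "missing" and
"reduced" disjoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core_io import QuantTable

__all__ = ["DiffRecord", "classify_protein", "compare_conditions", "welch_t_test"]

STATUSES = ("missing", "reduced", "unchanged", "increased")


def welch_t_test(wt: np.ndarray, ko: np.ndarray) -> float:
    """Two-sided Welch two-sample t probability; NaN when degenerate."""
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # constant vectors (e.g. an all-zero knockout) are expected inputs
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(wt, ko, equal_var=False)
    return float(res.pvalue)


@dataclass
class DiffRecord:
    """One protein's WT-vs-KO comparison."""

    protein_id: str
    wt_values: np.ndarray
    ko_values: np.ndarray
    fold_change: float  # mean(WT)/mean(KO); math.inf when mean(KO) == 0
    p_value: float
    status: str
    wt_peptides: np.ndarray | None = None
    ko_peptides: np.ndarray | None = None


def classify_protein(
    wt: Sequence[float],
    ko: Sequence[float],
    reduction_threshold: float = 2.0,
    *,
    wt_peptides: Sequence[float] | None = None,
    ko_peptides: Sequence[float] | None = None,
    protein_id: str = "",
    replicate_test: Callable[[np.ndarray, np.ndarray], float] = welch_t_test,
) -> DiffRecord:
    """Classify one protein's change between wild type and knockout.

    "Missing" is keyed on peptide counts when provided (no peptide detected in
    the knockout), else on the quantitative values. The replicate test is
    pluggable; its p-value is reported, not used for the category.
    """
    wt_v = np.asarray(wt, dtype=float)
    ko_v = np.asarray(ko, dtype=float)
    if wt_v.size == 0 or ko_v.size == 0:
        raise ValueError("replicate vectors must be non-empty")
    if (wt_v < 0).any() or (ko_v < 0).any():
        raise ValueError("replicate values must be non-negative")
    if reduction_threshold < 1:
        raise ValueError("reduction_threshold must be >= 1")

    wt_p = None if wt_peptides is None else np.asarray(wt_peptides, dtype=float)
    ko_p = None if ko_peptides is None else np.asarray(ko_peptides, dtype=float)

    wt_mean = float(wt_v.mean())
    ko_mean = float(ko_v.mean())

    wt_detected = wt_mean > 0 or (wt_p is not None and wt_p.sum() > 0)
    ko_detected = ko_mean > 0 or (ko_p is not None and ko_p.sum() > 0)
    if not wt_detected and not ko_detected:
        raise ValueError(
            f"protein {protein_id or '?'} not detected in either condition; "
            "status undefined"
        )

    # detection evidence for "missing": peptide counts when available
    ko_evidence_zero = (ko_p.sum() == 0) if ko_p is not None else (ko_mean == 0)

    fold = math.inf if ko_mean == 0 else wt_mean / ko_mean

    if ko_evidence_zero and ko_mean == 0 and wt_detected:
        status = "missing"
    elif ko_mean == 0:
        # peptides present but values zero: treat as missing-by-values edge
        status = "missing"
    elif wt_mean == 0:
        status = "increased"
    elif fold >= reduction_threshold:
        status = "reduced"
    elif ko_mean / wt_mean >= reduction_threshold:
        status = "increased"
    else:
        status = "unchanged"

    return DiffRecord(
        protein_id=protein_id,
        wt_values=wt_v,
        ko_values=ko_v,
        fold_change=fold,
        p_value=replicate_test(wt_v, ko_v),
        status=status,
        wt_peptides=wt_p,
        ko_peptides=ko_p,
    )


def compare_conditions(
    table: QuantTable,
    wt_name: str,
    ko_name: str,
    reduction_threshold: float = 2.0,
    *,
    replicate_test: Callable[[np.ndarray, np.ndarray], float] = welch_t_test,
) -> tuple[list[DiffRecord], dict[str, int]]:
    """Classify every protein detected in either condition of ``table``.

    Returns the records ordered by descending fold change (infinite first)
    then protein id, plus a summary count per status. Proteins detected in
    neither condition are dropped rather than erroring, so an all-zero row in
    an otherwise valid table does not abort a run.
    """
    wt_df = table.condition_values(wt_name)
    ko_df = table.condition_values(ko_name)
    wt_pep = table.condition_peptides(wt_name)
    ko_pep = table.condition_peptides(ko_name)

    records: list[DiffRecord] = []
    for pid in table.protein_ids:
        wt_v = wt_df.loc[pid].to_numpy()
        ko_v = ko_df.loc[pid].to_numpy()
        has_pep_wt = wt_pep is not None and wt_pep.loc[pid].sum() > 0
        has_pep_ko = ko_pep is not None and ko_pep.loc[pid].sum() > 0
        if wt_v.sum() == 0 and ko_v.sum() == 0 and not has_pep_wt and not has_pep_ko:
            continue
        records.append(
            classify_protein(
                wt_v,
                ko_v,
                reduction_threshold,
                wt_peptides=None if wt_pep is None else wt_pep.loc[pid].to_numpy(),
                ko_peptides=None if ko_pep is None else ko_pep.loc[pid].to_numpy(),
                protein_id=pid,
                replicate_test=replicate_test,
            )
        )

    # infinite fold changes (missing proteins) sort before every finite one
    records.sort(
        key=lambda r: (
            0 if math.isinf(r.fold_change) else 1,
            -r.fold_change if math.isfinite(r.fold_change) else 0.0,
            r.protein_id,
        )
    )

    summary = {s: 0 for s in STATUSES}
    for r in records:
        summary[r.status] += 1
    return records, summary
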