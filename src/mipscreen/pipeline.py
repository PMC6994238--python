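"""End-to-end screening workflows and the consolidated run report.

Three workflows mirror how unassigned cryo-EM densities are matched to
proteins in practice:

* ``tether-screen``          — stoichiometry ranking, then the multi-criteria
  screen (size window, conservation required, homolog size, localization /
  blacklist exclusions), optionally narrowed by a density-signature motif
  search over a proteome;
* ``species-specific-screen`` — the same machinery with an absent-homolog
  conservation requirement, for densities seen in only one species;
* ``trace-match``            — a short traced density matched by mass against
  the knockout-missing set.

A run is fully described by one YAML config (all thresholds live there — no
hidden defaults in code paths) and emits a versioned JSON report, a
human-readable TSV shortlist projected from the JSON, and a manifest
capturing config and package version.
"""

from __future__ import annotations

import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .candidate_screen import ScreenCriteria, apply_criteria, identify_from_trace
from .core_io import (
    ExpressionMatrix,
    ProteinEntry,
    annotate_homologs,
    parse_proteome,
    parse_quant_table,
    read_homolog_map,
    write_json_report,
)
from .coexpression import correlate_pairs
from .differential import compare_conditions
from .motif_search import MotifQuery, search_proteome
from .stoichiometry import rank_by_rspa

__all__ = ["RunConfig", "run_screen_pipeline", "load_run_config"]

REPORT_SCHEMA_VERSION = 1

WORKFLOWS = ("tether-screen", "species-specific-screen", "trace-match")


@dataclass
class RunConfig:
    """One pipeline run; every referenced path must exist before execution."""

    workflow: str
    outdir: Path
    quant_path: Path
    replicate_columns: dict[str, list[str]]
    wt_condition: str = "WT"
    ko_condition: str | None = None
    peptide_columns: dict[str, list[str]] = field(default_factory=dict)
    fasta_path: Path | None = None
    annotations_path: Path | None = None
    homolog_map_path: Path | None = None
    expression_path: Path | None = None
    expression_pairs: list[tuple[str, str]] = field(default_factory=list)
    exclude_tissues: list[str] = field(default_factory=list)
    signature: str | None = None
    length_window: tuple[int, int] | None = None
    direction: str = "both"
    criteria: dict[str, Any] = field(default_factory=dict)
    trace: dict[str, float] = field(default_factory=dict)
    fold_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.workflow not in WORKFLOWS:
            raise ValueError(f"unknown workflow {self.workflow!r}; choose from {WORKFLOWS}")
        for p in (self.quant_path, self.fasta_path, self.annotations_path,
                  self.homolog_map_path, self.expression_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent

    def _path(key):
        return None if raw.get(key) is None else base / raw[key]

    return RunConfig(
        workflow=raw["workflow"],
        outdir=base / raw.get("outdir", "out"),
        quant_path=_path("quant"),
        replicate_columns={k: list(v) for k, v in raw["replicate_columns"].items()},
        wt_condition=raw.get("wt_condition", "WT"),
        ko_condition=raw.get("ko_condition"),
        peptide_columns={k: list(v) for k, v in raw.get("peptide_columns", {}).items()},
        fasta_path=_path("fasta"),
        annotations_path=_path("annotations"),
        homolog_map_path=_path("homolog_map"),
        expression_path=_path("expression"),
        expression_pairs=[tuple(p) for p in raw.get("expression_pairs", [])],
        exclude_tissues=list(raw.get("exclude_tissues", [])),
        signature=raw.get("signature"),
        length_window=tuple(raw["length_window"]) if raw.get("length_window") else None,
        direction=raw.get("direction", "both"),
        criteria=dict(raw.get("criteria", {})),
        trace=dict(raw.get("trace", {})),
        fold_threshold=float(raw.get("fold_threshold", 2.0)),
        seed=int(raw.get("seed", 0)),
    )


def _criteria_from_dict(d: dict[str, Any]) -> ScreenCriteria:
    return ScreenCriteria(
        require_top_n_stoichiometry=int(d.get("top_n", 35)),
        mw_window_kda=tuple(d["mw_window"]) if d.get("mw_window") else None,
        conservation_required=tuple(d.get("conservation_required", ())),
        conservation_absent=tuple(d.get("conservation_absent", ())),
        homolog_size_max_ratio=d.get("homolog_size_max_ratio"),
        excluded_localizations=frozenset(d.get("excluded_localizations", ())),
        known_protein_blacklist=frozenset(d.get("known_protein_blacklist", ())),
        required_diff_status=d.get("required_diff_status"),
    )


def _log(stage: str, t0: float) -> None:
    print(f"[mipscreen] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def run_screen_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow and write the consolidated report.

    Stages always compose the public single-stage functions, so the report's
    shortlist equals what running each stage by hand produces. Any stage
    failure aborts the run with the failing stage named; the report is only
    written after every stage succeeded.
    """
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "workflow": config.workflow,
        "stages": {},
    }
    stage = "setup"
    try:
        t0 = time.perf_counter()
        table = parse_quant_table(
            config.quant_path,
            config.replicate_columns,
            config.peptide_columns or None,
        )
        _log("setup", t0)

        stage = "rspa"
        t0 = time.perf_counter()
        rows = rank_by_rspa(table, config.wt_condition)
        report["stages"]["rspa"] = [
            {"protein_id": r.protein_id, "mw_kda": r.mw_kda, "aqv": r.aqv,
             "rspa": r.rspa, "rank": r.rank}
            for r in rows
        ]
        _log("rspa", t0)

        diff_records = None
        if config.ko_condition is not None:
            stage = "diff"
            t0 = time.perf_counter()
            diff_records, summary = compare_conditions(
                table, config.wt_condition, config.ko_condition, config.fold_threshold
            )
            report["stages"]["diff"] = {
                "summary": summary,
                "records": [
                    {"protein_id": r.protein_id, "status": r.status,
                     "fold_change": ("inf" if math.isinf(r.fold_change) else r.fold_change),
                     "p_value": (None if math.isnan(r.p_value) else r.p_value)}
                    for r in diff_records
                ],
            }
            _log("diff", t0)

        stage = "annotations"
        t0 = time.perf_counter()
        proteome: list = []
        if config.fasta_path is not None:
            proteome = parse_proteome(config.fasta_path)
        by_id = {e.id: e for e in proteome}
        if config.annotations_path is not None:
            ann = pd.read_csv(config.annotations_path, sep="\t")
            for row in ann.itertuples(index=False):
                entry = by_id.get(row.protein_id)
                if entry is None:
                    mw = getattr(row, "mw_kda", None)
                    entry = ProteinEntry(
                        id=row.protein_id,
                        mw_kda=None if mw is None or pd.isna(mw) else float(mw),
                    )
                    by_id[entry.id] = entry
                    proteome.append(entry)
                loc = getattr(row, "localization", None)
                if loc is not None and not pd.isna(loc):
                    entry.localization = str(loc)
        if config.homolog_map_path is not None:
            annotate_homologs(proteome, read_homolog_map(config.homolog_map_path))
        _log("annotations", t0)

        if config.workflow == "trace-match":
            stage = "trace-match"
            t0 = time.perf_counter()
            if diff_records is None:
                raise ValueError("trace-match requires a knockout condition")
            hits = identify_from_trace(
                int(config.trace.get("length_aa", 0)),
                float(config.trace["mw_kda"]),
                diff_records,
                table.mw_kda.to_dict(),
                tolerance=float(config.trace.get("tolerance", 0.2)),
                required_status=str(config.trace.get("required_status", "missing")),
            )
            report["shortlist"] = hits
            _log("trace-match", t0)
        else:
            stage = "screen"
            t0 = time.perf_counter()
            criteria = _criteria_from_dict(config.criteria)
            screen_report = apply_criteria(rows, by_id, criteria, diff_records)
            report["stages"]["screen"] = [
                {"protein_id": v.protein_id, "stoich_rank": v.stoich_rank,
                 "flags": v.flags, "shortlisted": v.shortlisted,
                 "first_failure": v.first_failure}
                for v in screen_report.verdicts
            ]
            shortlist = list(screen_report.shortlist)
            _log("screen", t0)

            if config.signature is not None and config.fasta_path is not None:
                stage = "motif-search"
                t0 = time.perf_counter()
                query = MotifQuery(
                    signature=config.signature,
                    length_window=config.length_window,
                    direction=config.direction,
                )
                hits, matched = search_proteome(proteome, query)
                report["stages"]["motif_search"] = {
                    "matched_proteins": matched,
                    "hits": [
                        {"protein_id": h.protein_id, "start": h.start, "end": h.end,
                         "matched_seq": h.matched_seq, "direction": h.direction}
                        for h in hits
                    ],
                }
                # motif evidence reorders the shortlist: matched proteins first
                shortlist = sorted(
                    shortlist, key=lambda pid: (pid not in set(matched))
                )
                _log("motif-search", t0)
            report["shortlist"] = shortlist

        if config.expression_path is not None and config.expression_pairs:
            stage = "coexpr"
            t0 = time.perf_counter()
            matrix = ExpressionMatrix.read_tsv(config.expression_path)
            results = correlate_pairs(
                matrix, config.expression_pairs, config.exclude_tissues
            )
            report["stages"]["coexpression"] = [
                {"gene_a": r.gene_a, "gene_b": r.gene_b, "n_tissues": r.n_tissues,
                 "r": r.r, "p_value": r.p_value,
                 "excluded_tissues": list(r.excluded_tissues)}
                for r in results
            ]
            _log("coexpr", t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json_report(report, outdir / "report.json")
    # human TSV is a pure projection of the JSON report
    with open(outdir / "shortlist.tsv", "w") as fh:
        fh.write("rank\tprotein_id\n")
        for i, pid in enumerate(report.get("shortlist", []), start=1):
            fh.write(f"{i}\t{pid}\n")
    manifest = {
        "package": "mipscreen",
        "version": __version__,
        "schema_version": REPORT_SCHEMA_VERSION,
        "workflow": config.workflow,
        "seed": config.seed,
        "criteria": config.criteria,
        "fold_threshold": config.fold_threshold,
    }
    write_json_report(manifest, outdir / "manifest.json")
    return report
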