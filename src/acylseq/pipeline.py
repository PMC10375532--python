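"""End-to-end screen pipeline: config validation, per-condition counting and
enrichment, logos, correlations and selectivity, with deterministic TSV/JSON
reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .enrichment import (EnrichmentTable, compute_enrichment, correlation_matrix,
                         position_matrix, selectivity_score)
from .variant_counting import LibraryDesign, VariantCountTable, count_fastq

logger = logging.getLogger("acylseq")

_ENRICHMENT_COLUMNS = ["count_sel", "count_blank", "freq_sel", "freq_blank",
                       "enrichment", "log2_enrichment", "rank_by_raw_count",
                       "percentile"]
_MATRIX_COLUMNS = ["A", "C", "G", "U", "IC_bits"]


@dataclass
class PipelineConfig:
    """Everything one screen run needs: design, per-condition FASTQ paths
    (exactly one labelled ``blank``), smoothing and ranking parameters."""

    design: LibraryDesign
    fastq_by_condition: dict[str, str]
    blank_label: str = "blank"
    pseudocount: float = 1.0
    top_fraction: float = 0.1
    max_flank_mismatch: int = 1
    seed: int = 0
    output_dir: str = "screen_output"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        design = LibraryDesign(upstream_flank=d["design"]["upstream_flank"],
                               k=int(d["design"]["k"]),
                               downstream_flank=d["design"]["downstream_flank"],
                               name=d["design"].get("name", "library"))
        return cls(design=design,
                   fastq_by_condition=dict(d["fastq_by_condition"]),
                   blank_label=d.get("blank_label", "blank"),
                   pseudocount=float(d.get("pseudocount", 1.0)),
                   top_fraction=float(d.get("top_fraction", 0.1)),
                   max_flank_mismatch=int(d.get("max_flank_mismatch", 1)),
                   seed=int(d.get("seed", 0)),
                   output_dir=d.get("output_dir", "screen_output"))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems (empty iff the config is runnable)."""
    problems: list[str] = []
    labels = list(config.fastq_by_condition)
    if config.blank_label not in labels:
        problems.append(f"fastq_by_condition: no blank condition "
                        f"{config.blank_label!r} among {labels}")
    n_blanks = sum(1 for l in labels if l == config.blank_label)
    if n_blanks > 1:
        problems.append("fastq_by_condition: more than one blank condition")
    if len(labels) < 2:
        problems.append("fastq_by_condition: need the blank plus at least one "
                        "selection condition")
    for label, path in config.fastq_by_condition.items():
        if not Path(path).exists():
            problems.append(f"fastq_by_condition[{label}]: file not found: {path}")
    if config.pseudocount <= 0:
        problems.append(f"pseudocount: must be > 0, got {config.pseudocount}")
    if not 0 < config.top_fraction <= 1:
        problems.append(f"top_fraction: must be in (0, 1], got {config.top_fraction}")
    if config.max_flank_mismatch < 0:
        problems.append("max_flank_mismatch: must be >= 0")
    return problems


def _check_schema(path: Path, required: list[str]) -> None:
    cols = list(pd.read_csv(path, sep="\t", nrows=0).columns)
    missing = [c for c in required if c not in cols]
    if missing:
        raise RuntimeError(f"{path} is missing columns {missing}")


def run_screen_pipeline(config: PipelineConfig) -> dict:
    """Count, enrich, summarize and write every report for one screen.

    Per selection condition this writes a count table, an enrichment table
    and a position matrix; globally a correlation matrix, a selectivity
    table (when >= 2 selection conditions) and a run log with versions,
    parameters and read accounting.  Every TSV is schema-checked before the
    run is reported successful.  Returns the report bundle in memory.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts: dict[str, VariantCountTable] = {}
    for label, path in sorted(config.fastq_by_condition.items()):
        tab = count_fastq(path, config.design,
                          max_flank_mismatch=config.max_flank_mismatch,
                          condition_label=label)
        logger.info("counted %s: %d matched, %d unmatched",
                    label, tab.matched, tab.unmatched)
        counts[label] = tab
        tab.to_tsv(outdir / f"counts_{label}.tsv")

    blank = counts[config.blank_label]
    selection_labels = [l for l in sorted(counts) if l != config.blank_label]
    enrichments: dict[str, EnrichmentTable] = {}
    for label in selection_labels:
        enr = compute_enrichment(counts[label], blank,
                                 pseudocount=config.pseudocount)
        enrichments[label] = enr
        enr.to_tsv(outdir / f"enrichment_{label}.tsv")
        pm = position_matrix(enr, fraction=config.top_fraction,
                             weighting="raw_reads")
        pm.to_tsv(outdir / f"logo_{label}.tsv")

    corr = correlation_matrix(counts)
    corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t",
                index_label="condition")

    scores = None
    if len(enrichments) >= 2:
        scores = selectivity_score(enrichments)
        scores.to_csv(outdir / "selectivity_scores.tsv", sep="\t",
                      index_label="variant")

    run_log = {
        "acylseq_version": __version__,
        "design": {"name": config.design.name,
                   "upstream_flank": config.design.upstream_flank,
                   "k": config.design.k,
                   "downstream_flank": config.design.downstream_flank},
        "parameters": {"pseudocount": config.pseudocount,
                       "top_fraction": config.top_fraction,
                       "max_flank_mismatch": config.max_flank_mismatch,
                       "seed": config.seed},
        "read_accounting": {l: counts[l].summary() for l in sorted(counts)},
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    for label in selection_labels:
        _check_schema(outdir / f"counts_{label}.tsv",
                      ["variant", "count", "frequency"])
        _check_schema(outdir / f"enrichment_{label}.tsv",
                      ["variant"] + _ENRICHMENT_COLUMNS)
        _check_schema(outdir / f"logo_{label}.tsv",
                      ["position"] + _MATRIX_COLUMNS)
    _check_schema(outdir / "correlation_matrix.tsv", ["condition"])
    if scores is not None:
        _check_schema(outdir / "selectivity_scores.tsv",
                      ["variant"] + selection_labels)

    return {"counts": counts, "enrichments": enrichments,
            "correlation": corr, "selectivity": scores, "run_log": run_log}
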