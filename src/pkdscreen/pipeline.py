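"""End-to-end orchestration of the two-screen workflow.

``run_screen`` takes one proteinGroups table from raw rows to classified
enrichment records (filter -> log matrix -> impute -> ratios -> fences);
``run_all`` runs both screens, scans the proteome for consensus motifs,
compares the screens and cross-references the shared motif sites against
the known-site table, writing per-stage TSVs and a JSON run summary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .compare import ComparisonReport, ScreenResult, build_report
from .enrichment import (
    FenceParams,
    IMPUTE_STREAM,
    SampleInfo,
    classify_enrichment,
    compute_log2_ratios,
    enrichment_table,
    filter_proteins,
    impute_missing,
    make_design,
    to_log_matrix,
)
from .io import (
    ColumnMap,
    KnownSiteTable,
    ProteinGroupTable,
    read_fasta,
    read_known_sites,
    read_protein_groups,
    write_results,
)
from .motifs import PATTERNS, proteome_motif_counts, scan_proteome

logger = logging.getLogger(__name__)


class ScreenConfig(BaseModel):
    """Input files and sample design for one screen."""

    label: str
    protein_groups: Path
    control: list[str]
    treatment: list[str]


class AnalysisParams(BaseModel):
    """All tunable analysis parameters with their standard defaults."""

    min_razor_unique: int = Field(default=2, ge=0)
    impute_quantile: float = Field(default=0.05, gt=0, lt=1)
    impute_sd: float = Field(default=0.1, gt=0)
    k_potential: float = Field(default=1.5, gt=0)
    k_extreme: float = Field(default=3.0, gt=0)
    ratio_mode: str = "paired-mean"
    quantile_method: str = "linear"
    motif_pattern: str = "full"

    def fences(self) -> FenceParams:
        return FenceParams(k_potential=self.k_potential, k_extreme=self.k_extreme,
                           quantile_method=self.quantile_method)


class RunConfig(BaseModel):
    """Full two-screen run configuration (JSON-loadable)."""

    screen_a: ScreenConfig
    screen_b: ScreenConfig
    fasta: Path
    known_sites: Path | None = None
    out_dir: Path
    params: AnalysisParams = AnalysisParams()
    seed: int | None = None


def analyze_screen(
    table: ProteinGroupTable,
    design: Sequence[SampleInfo],
    params: AnalysisParams = AnalysisParams(),
    seed: int | None = None,
    label: str = "screen",
    rng: np.random.Generator | None = None,
) -> ScreenResult:
    """One screen, in memory: filter, log-transform, impute, ratio, classify.

    The peptide-count filter runs before imputation so excluded rows cannot
    shift the imputation anchor quantile.
    """
    filtered = filter_proteins(table, params.min_razor_unique)
    matrix = to_log_matrix(filtered, design)
    matrix = impute_missing(matrix, quantile=params.impute_quantile,
                            sd=params.impute_sd, seed=seed, rng=rng)
    ratios = compute_log2_ratios(matrix, mode=params.ratio_mode)
    classes = classify_enrichment(ratios["log2_ratio"], params.fences())
    records = enrichment_table(filtered, ratios, classes)
    return ScreenResult.from_records(label, records)


def top_proteins(records: pd.DataFrame, n: int = 15) -> pd.DataFrame:
    """The n most enriched proteins, sorted by descending log2 ratio."""
    cols = ["accession", "gene_names", "razor_unique_peptides", "log2_ratio", "significance"]
    return records.sort_values("log2_ratio", ascending=False).head(n)[cols].reset_index(drop=True)


def _screen_rng(seed: int | None, index: int) -> np.random.Generator:
    # one imputation substream per screen, stable under pipeline changes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(IMPUTE_STREAM, index)))


def run_screen(
    config: RunConfig,
    which: str,
    column_map: ColumnMap | None = None,
    write: bool = True,
) -> ScreenResult:
    """Run one configured screen from its proteinGroups file; write its tables."""
    if which not in ("a", "b"):
        raise ValueError("which must be 'a' or 'b'")
    sc = config.screen_a if which == "a" else config.screen_b
    labels = list(sc.control) + list(sc.treatment)
    table = read_protein_groups(sc.protein_groups, sample_labels=labels, column_map=column_map)
    design = make_design(sc.control, sc.treatment)
    result = analyze_screen(table, design, config.params, label=sc.label,
                            rng=_screen_rng(config.seed, 0 if which == "a" else 1))
    if write:
        scatter = result.records[["accession", "mean_log10_intensity", "log2_ratio",
                                  "significance", "direction"]]
        write_results(
            {
                f"enrichment_{sc.label}": result.records,
                f"scatter_{sc.label}": scatter,
                f"top15_{sc.label}": top_proteins(result.records),
            },
            config.out_dir,
        )
    return result


def run_all(config: RunConfig) -> ComparisonReport:
    """The full two-screen workflow; returns the comparison report.

    Writes per-screen enrichment/scatter/top-15 tables, the motif-hit
    table, the known-site cross-reference, and ``summary.json`` with the
    headline counts, parameters and seed.
    """
    result_a = run_screen(config, "a")
    result_b = run_screen(config, "b")

    records = read_fasta(config.fasta)
    pattern = PATTERNS[config.params.motif_pattern]
    counts = proteome_motif_counts(records, pattern)
    hits = scan_proteome(records, pattern)
    known = read_known_sites(config.known_sites) if config.known_sites else KnownSiteTable()

    report = build_report(result_a, result_b, counts, hits, known)

    hits_df = pd.DataFrame(hits, columns=["accession", "acceptor_pos", "window",
                                          "kind", "acceptor_residue"])
    summary = {
        "version": __version__,
        "seed": config.seed,
        "params": config.params.model_dump(),
        "fasta": str(config.fasta),
        "n_proteins_screened": {
            config.screen_a.label: int(len(result_a.records)),
            config.screen_b.label: int(len(result_b.records)),
        },
        **report.to_summary(),
    }
    write_results(
        {"motif_hits": hits_df, "xref": report.xref_table()},
        config.out_dir,
        summary=summary,
    )
    logger.info("run complete: %s", report.to_summary())
    return report
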