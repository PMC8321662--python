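"""Quantification statistics for a motif-antibody IP screen.

The analysis chain implemented here is:

1. exclude protein groups identified by fewer than two razor+unique peptides,
2. log10-transform the LFQ intensities of a paired control/treatment design,
3. impute missing (left-censored) cells from a normal distribution centred
   on a low quantile of the pooled observed log10 intensities,
4. compute per-protein log2 treatment/control ratios, and
5. classify each ratio against Tukey-style IQR fences computed over all
   ratios of the screen: beyond ``Q3 + 3*IQR`` / ``Q1 - 3*IQR`` is class 2
   ("significantly enriched"/"extreme"), beyond the 1.5x fences is class 1
   ("potentially enriched"), otherwise class 0.

No distributional test is involved: the fence classification itself is the
enrichment criterion, and it is a pure function of the ratio vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StateError
from .io import ProteinGroupTable

logger = logging.getLogger(__name__)

LOG10_2 = np.log10(2.0)

#: spawn key of the RNG substream consumed by imputation, so that adding
#: other randomised stages to a pipeline never changes imputed values.
IMPUTE_STREAM = 101


def substream_rng(seed: int | None, stream: int) -> np.random.Generator:
    """A generator on a named substream of the pipeline-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# peptide-count filter
# ---------------------------------------------------------------------------

def filter_proteins(table: ProteinGroupTable, min_razor_unique: int = 2) -> ProteinGroupTable:
    """Retain protein groups with at least ``min_razor_unique`` razor+unique peptides.

    The default of 2 excludes single-peptide identifications.  Row order is
    preserved; an empty result is legal.
    """
    if min_razor_unique < 0:
        raise ConfigurationError("min_razor_unique must be >= 0")
    keep = table.meta["razor_unique_peptides"] >= min_razor_unique
    logger.info("peptide filter (>= %d): %d -> %d rows",
                min_razor_unique, len(table), int(keep.sum()))
    return ProteinGroupTable(
        meta=table.meta[keep].reset_index(drop=True),
        lfq=table.lfq[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# log-intensity matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    """One sample column: its label, condition role and replicate index."""

    label: str
    role: Literal["control", "treatment"]
    replicate: int


@dataclass(frozen=True)
class LogIntensityMatrix:
    """log10 LFQ intensities for a paired control/treatment design.

    ``values`` is proteins x samples; cells where ``observed`` is False are
    NaN until :func:`impute_missing` fills them (``imputed`` then flips to
    True).  Observed cells always hold exactly ``log10`` of the input LFQ.
    """

    proteins: tuple[str, ...]
    samples: tuple[SampleInfo, ...]
    values: np.ndarray
    observed: np.ndarray
    imputed: bool = False

    def __post_init__(self) -> None:
        n, m = len(self.proteins), len(self.samples)
        if self.values.shape != (n, m) or self.observed.shape != (n, m):
            raise ValueError("matrix dimensions inconsistent with proteins/samples")

    def columns(self, role: str) -> list[int]:
        idx = [i for i, s in enumerate(self.samples) if s.role == role]
        return sorted(idx, key=lambda i: self.samples[i].replicate)


def make_design(control: Sequence[str], treatment: Sequence[str]) -> list[SampleInfo]:
    """Build a paired design from ordered control and treatment labels.

    The r-th control label is paired with the r-th treatment label
    (replicates paired by donor animal).
    """
    if len(control) != len(treatment):
        raise ConfigurationError(
            f"unpaired design: {len(control)} control vs {len(treatment)} treatment samples")
    if not control:
        raise ConfigurationError("design must contain at least one replicate pair")
    design = [SampleInfo(lbl, "control", r + 1) for r, lbl in enumerate(control)]
    design += [SampleInfo(lbl, "treatment", r + 1) for r, lbl in enumerate(treatment)]
    return design


def to_log_matrix(table: ProteinGroupTable, design: Sequence[SampleInfo]) -> LogIntensityMatrix:
    """log10-transform the LFQ matrix; missing cells stay NaN (no imputation)."""
    labels = [s.label for s in design]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate sample labels in design")
    missing = [lbl for lbl in labels if lbl not in table.lfq.columns]
    if missing:
        raise ConfigurationError(f"design labels not in table: {missing}")
    n_control = sum(s.role == "control" for s in design)
    n_treatment = sum(s.role == "treatment" for s in design)
    if n_control != n_treatment:
        raise ConfigurationError(
            f"unpaired design: {n_control} control vs {n_treatment} treatment samples")
    for role in ("control", "treatment"):
        reps = sorted(s.replicate for s in design if s.role == role)
        if reps != list(range(1, len(reps) + 1)):
            raise ConfigurationError(f"{role} replicate indices must be 1..n, got {reps}")

    lin = table.lfq[labels].to_numpy(dtype=float)
    observed = np.isfinite(lin)
    values = np.full(lin.shape, np.nan)
    values[observed] = np.log10(lin[observed])
    return LogIntensityMatrix(
        proteins=tuple(table.leading_accessions),
        samples=tuple(design),
        values=values,
        observed=observed,
    )


def impute_missing(
    m: LogIntensityMatrix,
    quantile: float = 0.05,
    sd: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> LogIntensityMatrix:
    """Fill missing cells with draws from Normal(q, sd) in log10 space.

    ``q`` is the ``quantile``-quantile of all observed log10 intensities
    pooled across both conditions and all replicates — a low anchor chosen
    because LFQ missingness is left-censored (low-abundance proteins drop
    out first).  Observed cells are untouched.  With ``rng`` unset, draws
    come from a dedicated substream of ``seed``.
    """
    if not 0 < quantile < 1:
        raise ConfigurationError("impute quantile must be in (0, 1)")
    if sd <= 0:
        raise ConfigurationError("impute sd must be > 0")
    pool = m.values[m.observed]
    if pool.size == 0:
        raise StateError("cannot impute: no observed values to anchor the quantile")
    if not m.observed.all():
        q = float(np.quantile(pool, quantile))
        gen = rng if rng is not None else substream_rng(seed, IMPUTE_STREAM)
        values = m.values.copy()
        n_missing = int((~m.observed).sum())
        values[~m.observed] = gen.normal(loc=q, scale=sd, size=n_missing)
        logger.info("imputed %d/%d cells at Normal(%.4f, %.3f)",
                    n_missing, m.values.size, q, sd)
    else:
        values = m.values.copy()
    return replace(m, values=values, imputed=True)


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

def compute_log2_ratios(
    m: LogIntensityMatrix,
    mode: Literal["paired-mean", "ratio-of-means"] = "paired-mean",
) -> pd.DataFrame:
    """Per-protein log2 treatment/control ratio and mean log10 intensity.

    ``paired-mean`` (default): per replicate pair r, the log difference
    ``(log10 T_r - log10 C_r) / log10 2``, averaged over replicates — the
    pairing reflects replicates drawn from the same animal.
    ``ratio-of-means``: difference of the per-condition mean log10
    intensities, divided by log10 2.

    Returns a DataFrame indexed by accession with columns ``log2_ratio``
    and ``mean_log10_intensity`` (the mean of all the protein's log10
    values, the natural x-axis for an MA-style scatter).
    """
    if not m.imputed:
        raise StateError("compute_log2_ratios requires a fully imputed matrix")
    if mode not in ("paired-mean", "ratio-of-means"):
        raise ConfigurationError(f"unknown ratio mode {mode!r}")
    c_cols = m.columns("control")
    t_cols = m.columns("treatment")
    C = m.values[:, c_cols]
    T = m.values[:, t_cols]
    if mode == "paired-mean":
        log2_ratio = ((T - C) / LOG10_2).mean(axis=1)
    else:
        log2_ratio = (T.mean(axis=1) - C.mean(axis=1)) / LOG10_2
    return pd.DataFrame(
        {
            "log2_ratio": log2_ratio,
            "mean_log10_intensity": m.values.mean(axis=1),
        },
        index=pd.Index(m.proteins, name="accession"),
    )


# ---------------------------------------------------------------------------
# IQR-fence classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FenceParams:
    """Tukey fence multipliers: 1.5x IQR = potential (class 1), 3x = extreme (class 2)."""

    k_potential: float = 1.5
    k_extreme: float = 3.0
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if not 0 < self.k_potential < self.k_extreme:
            raise ConfigurationError("fences require k_extreme > k_potential > 0")


def classify_enrichment(
    ratios: Mapping[str, float] | pd.Series,
    fences: FenceParams = FenceParams(),
) -> pd.DataFrame:
    """Two-tier IQR-fence classification of log2 ratios.

    Quartiles are computed over *all* ratios of the screen (linear
    interpolation between order statistics by default).  A ratio strictly
    outside ``Q3 + k*IQR`` / ``Q1 - k*IQR`` is classified 2 for the extreme
    fence (k_extreme), else 1 for the potential fence (k_potential), else 0;
    ``direction`` is +1 above the upper fence, -1 below the lower fence,
    0 for unclassified ratios.  With IQR = 0 the fences collapse onto the
    quartiles and, inequalities being strict, fence ties stay class 0.
    """
    series = pd.Series(ratios, dtype=float)
    r = series.to_numpy()
    if r.size < 4:
        raise ConfigurationError(f"need >= 4 ratios for quartiles, got {r.size}")
    if not np.isfinite(r).all():
        raise ConfigurationError("non-finite ratio encountered")
    q1, q3 = np.quantile(r, [0.25, 0.75], method=fences.quantile_method)
    iqr = q3 - q1

    significance = np.zeros(r.size, dtype=int)
    direction = np.zeros(r.size, dtype=int)
    for sig, k in ((2, fences.k_extreme), (1, fences.k_potential)):
        lo, hi = q1 - k * iqr, q3 + k * iqr
        outside = (significance == 0) & ((r > hi) | (r < lo))
        significance[outside] = sig
        direction[outside & (r > hi)] = 1
        direction[outside & (r < lo)] = -1

    out = pd.DataFrame(
        {"log2_ratio": r, "significance": significance, "direction": direction},
        index=series.index.rename("accession"),
    )
    logger.info("fence classification: %d ratios, Q1=%.4f Q3=%.4f, class counts %s",
                r.size, q1, q3, np.bincount(significance, minlength=3).tolist())
    return out


def enrichment_table(
    table: ProteinGroupTable,
    ratios: pd.DataFrame,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-protein enrichment table (one row per protein).

    Columns: accession, gene_names, razor_unique_peptides,
    mean_log10_intensity, log2_ratio, significance, direction — the
    machine-readable twin of a top-protein figure table plus the scatter
    coordinates.
    """
    meta = table.meta.set_index("leading_accession")
    out = pd.DataFrame({
        "accession": ratios.index,
        "gene_names": [";".join(meta.loc[a, "gene_names"]) for a in ratios.index],
        "razor_unique_peptides": [int(meta.loc[a, "razor_unique_peptides"]) for a in ratios.index],
        "mean_log10_intensity": ratios["mean_log10_intensity"].to_numpy(),
        "log2_ratio": ratios["log2_ratio"].to_numpy(),
        "significance": classes["significance"].to_numpy(),
        "direction": classes["direction"].to_numpy(),
    })
    return out
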