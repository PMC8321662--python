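"""Synthetic data emulating a paired motif-antibody IP screen.

Three generators, each emitting a machine-readable ground-truth table so
recovery can be scored exactly:

* :func:`generate_lfq_experiment` — a paired control/treatment LFQ screen:
  log-normal protein abundances, replicate noise, a minority of proteins
  spiked with a large positive log2 fold change (the planted "substrates"),
  and intensity-dependent (left-censored, MNAR-like) missingness via a
  logistic in log10 intensity.
* :func:`generate_proteome` — protein sequences whose background residues
  exclude R, S and T, so consensus motifs exist exactly where planted.
* :func:`generate_known_sites` — a seeded random subset of the planted
  sites, standing in for a phosphosite-repository snapshot.

All generators are deterministic under (spec, seed), drawing from named
substreams of the pipeline seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .enrichment import LOG10_2, substream_rng
from .errors import ConfigurationError
from .io import KnownSiteTable, ProteinGroupTable, SequenceRecord

# named RNG substreams (see enrichment.IMPUTE_STREAM = 101)
LFQ_STREAM = 201
PROTEOME_STREAM = 202
KNOWN_SITES_STREAM = 203

#: residues drawn for sequence background and motif wildcards: the 20-letter
#: alphabet minus R, S and T, so no accidental motif can form.
BACKGROUND_ALPHABET = "ACDEFGHIKLMNPQVWY"


class LfqSimSpec(BaseModel):
    """Parameters of the simulated paired LFQ screen.

    Defaults mirror a typical hepatocyte LFQ experiment: three paired
    biological replicates per condition, latent log10 abundances around 7
    with SD 0.7, replicate noise SD 0.1 (log10), and logistic left-censored
    missingness centred at log10 intensity 6.
    """

    n_proteins: int = Field(ge=4)
    n_replicates: int = Field(default=3, ge=1)
    base_log10_mean: float = 7.0
    base_log10_sd: float = Field(default=0.7, gt=0)
    replicate_noise_sd: float = Field(default=0.1, gt=0)
    spike_fraction: float = Field(default=0.05, ge=0, le=1)
    spike_log2_fc: float = 5.0
    mnar_missingness: bool = True
    missing_logistic_midpoint: float = 6.0
    missing_logistic_slope: float = Field(default=2.0, gt=0)
    #: when set, spiked proteins' latent log10 abundance is clipped to at
    #: least this value — benchmark fixtures use it to keep designed
    #: substrates inside the reliably quantified intensity range.
    spike_latent_floor: float | None = None
    low_peptide_fraction: float = Field(default=0.1, ge=0, le=1)
    control_prefix: str = "EGFP"
    treatment_prefix: str = "PKD3ca"
    seed: int | None = None

    @model_validator(mode="after")
    def _check(self) -> "LfqSimSpec":
        if self.control_prefix == self.treatment_prefix:
            raise ValueError("control and treatment prefixes must differ")
        return self


class PlantedSite(NamedTuple):
    """One planted motif: 1-based acceptor position, pattern kind, acceptor residue."""

    acceptor_pos: int
    kind: Literal["full", "partial"]
    residue: str


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation run.

    ``proteins`` (accession, true_log2_fc, spiked) records the planted fold
    changes; ``planted_sites`` maps accession to its planted motif sites.
    """

    proteins: pd.DataFrame
    planted_sites: dict[str, list[PlantedSite]]

    @property
    def spiked_accessions(self) -> frozenset[str]:
        return frozenset(self.proteins.loc[self.proteins["spiked"], "accession"])

    def all_sites(self) -> list[tuple[str, PlantedSite]]:
        return [(acc, site)
                for acc in sorted(self.planted_sites)
                for site in self.planted_sites[acc]]


def _accession(i: int) -> str:
    return f"SYN{i + 1:05d}"


def generate_lfq_experiment(
    spec: LfqSimSpec,
    spiked_indices: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ProteinGroupTable, SyntheticTruth]:
    """Simulate a paired control/treatment LFQ screen with known truth.

    Per protein i: latent log10 abundance ``a_i ~ N(base_log10_mean,
    base_log10_sd)``; control replicate r measures ``a_i + eps``, treatment
    ``a_i + fc_i * log10(2) + eps`` with ``eps ~ N(0, replicate_noise_sd)``.
    Each cell goes missing independently with probability
    ``1 / (1 + exp(slope * (log10 value - midpoint)))`` — low-intensity
    cells drop out preferentially, emulating left-censored LFQ data.
    Razor+unique peptide counts are >= 1 with ``low_peptide_fraction`` of
    proteins below the standard filter threshold of 2.

    ``spiked_indices`` overrides the random choice of spiked proteins (used
    to construct screens with a designed overlap); ``rng`` overrides the
    default substream (used to draw several screens from one seed).
    """
    if rng is None:
        rng = substream_rng(spec.seed, LFQ_STREAM)
    n, k = spec.n_proteins, spec.n_replicates

    if spiked_indices is None:
        n_spiked = round(spec.spike_fraction * n)
        spiked_idx = rng.choice(n, size=n_spiked, replace=False) if n_spiked else np.array([], int)
    else:
        spiked_idx = np.asarray(sorted(set(spiked_indices)), dtype=int)
        if len(spiked_idx) and (spiked_idx[0] < 0 or spiked_idx[-1] >= n):
            raise ConfigurationError("spiked_indices out of range")
    spiked = np.zeros(n, dtype=bool)
    spiked[spiked_idx] = True
    true_fc = np.where(spiked, float(spec.spike_log2_fc), 0.0)

    latent = rng.normal(spec.base_log10_mean, spec.base_log10_sd, size=n)
    if spec.spike_latent_floor is not None:
        latent[spiked] = np.maximum(latent[spiked], spec.spike_latent_floor)
    eps_c = rng.normal(0.0, spec.replicate_noise_sd, size=(n, k))
    eps_t = rng.normal(0.0, spec.replicate_noise_sd, size=(n, k))
    log10_c = latent[:, None] + eps_c
    log10_t = latent[:, None] + true_fc[:, None] * LOG10_2 + eps_t
    log10_all = np.concatenate([log10_c, log10_t], axis=1)

    if spec.mnar_missingness:
        p_missing = 1.0 / (1.0 + np.exp(
            spec.missing_logistic_slope * (log10_all - spec.missing_logistic_midpoint)))
        missing = rng.random(log10_all.shape) < p_missing
    else:
        missing = np.zeros(log10_all.shape, dtype=bool)

    lin = 10.0 ** log10_all
    lin[missing] = np.nan

    low_pep = rng.random(n) < spec.low_peptide_fraction
    peptides = np.where(low_pep, 1, 2 + rng.poisson(6, size=n))

    accessions = [_accession(i) for i in range(n)]
    labels = ([f"{spec.control_prefix}_{r + 1}" for r in range(k)]
              + [f"{spec.treatment_prefix}_{r + 1}" for r in range(k)])
    meta = pd.DataFrame({
        "group_id": [str(i) for i in range(n)],
        "accessions": [[a] for a in accessions],
        "leading_accession": accessions,
        "gene_names": [[f"Gene{i + 1}"] for i in range(n)],
        "razor_unique_peptides": peptides,
        "reverse": False,
        "contaminant": False,
    })
    lfq = pd.DataFrame(lin, columns=labels)
    truth = SyntheticTruth(
        proteins=pd.DataFrame({
            "accession": accessions,
            "true_log2_fc": true_fc,
            "spiked": spiked,
        }),
        planted_sites={},
    )
    return ProteinGroupTable(meta=meta, lfq=lfq), truth


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (120, 400),
    plant_spec: Sequence[tuple[int, int, str]] = (),
    seed: int | None = None,
    accessions: Sequence[str] | None = None,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Random proteome with consensus motifs planted at recorded positions.

    ``plant_spec`` lists ``(protein_index, acceptor_pos, kind)`` triples
    (positions 1-based, kind "full" or "partial").  Background residues are
    drawn from :data:`BACKGROUND_ALPHABET` (no R/S/T), so the scanner finds
    exactly the planted sites: the mandatory arginine cannot occur by
    chance.  Planted windows must fit inside their sequence and must not
    overlap.  For partial plants the residue five positions upstream of the
    acceptor is kept out of {L, V, I} so a partial site never accidentally
    satisfies the full pattern.
    """
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ConfigurationError(f"invalid length_range {length_range}")
    rng = substream_rng(seed, PROTEOME_STREAM)
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    accs = list(accessions) if accessions is not None else \
        [_accession(i) for i in range(n_proteins)]
    if len(accs) != n_proteins or len(set(accs)) != n_proteins:
        raise ConfigurationError("accessions must be unique and match n_proteins")

    bg = np.array(list(BACKGROUND_ALPHABET))
    seqs = [rng.choice(bg, size=int(L)).tolist() for L in lengths]

    # validate plants: in-bounds, non-overlapping per protein
    spans: dict[int, list[tuple[int, int]]] = {}
    for idx, pos, kind in plant_spec:
        if kind not in ("full", "partial"):
            raise ConfigurationError(f"unknown motif kind {kind!r}")
        if not 0 <= idx < n_proteins:
            raise ConfigurationError(f"plant protein_index {idx} out of range")
        wlen = 6 if kind == "full" else 4
        start = pos - wlen  # 0-based inclusive start of the window
        if start < 0 or pos > lengths[idx]:
            raise ConfigurationError(
                f"planted {kind} window at acceptor {pos} does not fit protein {idx}")
        for s, e in spans.setdefault(idx, []):
            if start < e and s < pos:
                raise ConfigurationError(
                    f"overlapping planted windows in protein {idx} (acceptor {pos})")
        spans[idx].append((start, pos))

    planted: dict[str, list[PlantedSite]] = {}
    partial_guards: list[tuple[int, int]] = []
    for idx, pos, kind in plant_spec:
        seq = seqs[idx]
        p0 = pos - 1  # 0-based acceptor
        residue = str(rng.choice(["S", "T"]))
        seq[p0] = residue
        seq[p0 - 3] = "R"
        if kind == "full":
            seq[p0 - 5] = str(rng.choice(["L", "V", "I"]))
            wildcards = (p0 - 4, p0 - 2, p0 - 1)
        else:
            wildcards = (p0 - 2, p0 - 1)
            partial_guards.append((idx, p0 - 5))
        for w in wildcards:
            seq[w] = str(rng.choice(bg))
        planted.setdefault(accs[idx], []).append(PlantedSite(pos, kind, residue))

    # a partial plant must not pick up an accidental L/V/I at offset -5
    safe = np.array([c for c in BACKGROUND_ALPHABET if c not in "LVI"])
    for idx, g in partial_guards:
        if g >= 0 and seqs[idx][g] in "LVI":
            seqs[idx][g] = str(rng.choice(safe))

    records = [
        SequenceRecord(accession=acc, description=f"{acc} synthetic protein", sequence="".join(seq))
        for acc, seq in zip(accs, seqs)
    ]
    for sites in planted.values():
        sites.sort()
    truth = SyntheticTruth(
        proteins=pd.DataFrame({
            "accession": accs,
            "true_log2_fc": 0.0,
            "spiked": False,
        }),
        planted_sites=planted,
    )
    return records, truth


def generate_known_sites(
    truth: SyntheticTruth,
    fraction_reported: float,
    seed: int | None = None,
    annotation: str = "synthetic known site",
) -> KnownSiteTable:
    """A seeded random subset of the planted sites, as a known-site table.

    ``round(fraction_reported * n_sites)`` sites are sampled without
    replacement, so e.g. fraction 11/30 on a 30-site truth reports exactly
    11 sites.
    """
    if not 0 <= fraction_reported <= 1:
        raise ConfigurationError("fraction_reported must be in [0, 1]")
    sites = truth.all_sites()
    n_report = round(fraction_reported * len(sites))
    rng = substream_rng(seed, KNOWN_SITES_STREAM)
    chosen = sorted(rng.choice(len(sites), size=n_report, replace=False)) if n_report else []
    rows = [
        {
            "accession": acc,
            "position": site.acceptor_pos,
            "residue": site.residue,
            "annotation": annotation,
        }
        for acc, site in (sites[i] for i in chosen)
    ]
    df = pd.DataFrame(rows, columns=["accession", "position", "residue", "annotation"])
    return KnownSiteTable(df=df)


@dataclass
class TwoScreenStudy:
    """A complete synthetic two-antibody study with its designed truth.

    ``expected`` records the counts the comparison report must reproduce
    when every planted protein is recovered: planted enriched-set sizes,
    overlap, motif percentages, shared motif-bearing proteins, total shared
    sites and known-reported sites.
    """

    table_a: ProteinGroupTable
    table_b: ProteinGroupTable
    proteome: list[SequenceRecord]
    known: KnownSiteTable
    truth_a: SyntheticTruth
    truth_b: SyntheticTruth
    proteome_truth: SyntheticTruth
    control_labels: list[str]
    treatment_labels: list[str]
    expected: dict[str, int]


def generate_two_screen_study(
    seed: int | None = None,
    n_proteins: int = 1500,
    n_spiked_a: int = 84,
    n_spiked_b: int = 226,
    n_overlap: int = 24,
    n_shared_with_motif: int = 12,
    n_shared_motif_sites: int = 30,
    n_known_reported: int = 11,
    spike_log2_fc: float = 5.0,
) -> TwoScreenStudy:
    """A two-antibody benchmark study with a designed comparison chain.

    Defaults mirror the shape of a published PKD3 substrate screen: 84 and
    226 proteins spiked in screens A and B with 24 shared; 12 of the shared
    proteins carry consensus motifs (30 sites in total, 11 of them in the
    known-site table).  Only those 12 proteins carry motifs at all, so the
    shared-motif chain of the report is pinned to the designed truth: a
    false-positive enrichment elsewhere can inflate the enriched sets and
    their intersection, but never the motif-bearing shared set, its site
    total, or the known-reported count.  Peptide counts are kept above the
    standard filter so the designed proteins stay quantifiable; both
    screens share the accession namespace and are drawn from independent
    substreams of ``seed``.
    """
    if not (n_overlap <= min(n_spiked_a, n_spiked_b)
            and n_shared_with_motif <= n_overlap
            and n_shared_with_motif <= n_shared_motif_sites
            and n_known_reported <= n_shared_motif_sites
            and n_spiked_a + n_spiked_b - n_overlap <= n_proteins):
        raise ConfigurationError("inconsistent two-screen study design counts")

    # index layout: [0, n_overlap) shared; [n_overlap, n_spiked_a) A-only;
    # [n_spiked_a, n_spiked_a + n_spiked_b - n_overlap) B-only; rest null.
    shared = list(range(n_overlap))
    a_only = list(range(n_overlap, n_spiked_a))
    b_only = list(range(n_spiked_a, n_spiked_a + n_spiked_b - n_overlap))
    spiked_a = shared + a_only
    spiked_b = shared + b_only

    spec = LfqSimSpec(
        n_proteins=n_proteins,
        spike_log2_fc=spike_log2_fc,
        low_peptide_fraction=0.0,
        spike_latent_floor=6.5,
        seed=seed,
    )
    table_a, truth_a = generate_lfq_experiment(
        spec, spiked_indices=spiked_a,
        rng=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(LFQ_STREAM, 0))))
    table_b, truth_b = generate_lfq_experiment(
        spec, spiked_indices=spiked_b,
        rng=np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(LFQ_STREAM, 1))))

    # motif plants: the shared motif bearers carry sites summing to the
    # designed total, spaced widely enough that windows never overlap.
    base, extra = divmod(n_shared_motif_sites, n_shared_with_motif)
    shared_site_counts = [base + (1 if i < extra else 0) for i in range(n_shared_with_motif)]
    plant_spec: list[tuple[int, int, str]] = []
    for i, n_sites in zip(shared[:n_shared_with_motif], shared_site_counts):
        for s in range(n_sites):
            plant_spec.append((i, 20 + 20 * s, "full"))

    proteome, proteome_truth = generate_proteome(
        n_proteins, length_range=(150, 300), plant_spec=plant_spec, seed=seed)

    shared_accs = {_accession(i) for i in shared[:n_shared_with_motif]}
    shared_truth = SyntheticTruth(
        proteins=proteome_truth.proteins,
        planted_sites={acc: sites for acc, sites in proteome_truth.planted_sites.items()
                       if acc in shared_accs},
    )
    known = generate_known_sites(shared_truth, n_known_reported / n_shared_motif_sites, seed=seed)

    k = spec.n_replicates
    return TwoScreenStudy(
        table_a=table_a,
        table_b=table_b,
        proteome=proteome,
        known=known,
        truth_a=truth_a,
        truth_b=truth_b,
        proteome_truth=proteome_truth,
        control_labels=[f"{spec.control_prefix}_{r + 1}" for r in range(k)],
        treatment_labels=[f"{spec.treatment_prefix}_{r + 1}" for r in range(k)],
        expected={
            "n_spiked_a": n_spiked_a,
            "n_spiked_b": n_spiked_b,
            "n_spiked_overlap": n_overlap,
            "n_shared_with_motif": n_shared_with_motif,
            "n_total_motifs_shared": n_shared_motif_sites,
            "n_reported": n_known_reported,
        },
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground truth as a flat TSV (fold changes + planted sites)."""
    rows = truth.proteins.copy()
    rows["planted_sites"] = [
        ";".join(f"{s.acceptor_pos}:{s.kind}:{s.residue}"
                 for s in truth.planted_sites.get(acc, []))
        for acc in rows["accession"]
    ]
    rows.to_csv(path, sep="\t", index=False)
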