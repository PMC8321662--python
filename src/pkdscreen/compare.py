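"""Combining two motif-antibody screens.

A screen's "enriched" set is every protein with IQR-fence significance 1 or
2.  Two screens (e.g. a fully specific and a partially specific antibody)
are compared by set intersection; the shared proteins are summarised by
consensus-motif possession, and each motif site is cross-referenced against
a local known-phosphosite table to split previously reported from novel
sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .io import KnownSiteTable
from .motifs import MotifFraction, MotifHit, fraction_with_motif

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    """One screen's enrichment outcome.

    ``records`` is the full per-protein enrichment table (accession,
    gene_names, mean_log10_intensity, log2_ratio, significance, direction);
    ``enriched`` is the accession set with significance 1 or 2.
    """

    screen_label: str
    records: pd.DataFrame = field(hash=False)
    enriched: frozenset[str] = field(hash=False)

    @classmethod
    def from_records(cls, screen_label: str, records: pd.DataFrame) -> "ScreenResult":
        enriched = frozenset(records.loc[records["significance"] >= 1, "accession"])
        return cls(screen_label=screen_label, records=records, enriched=enriched)

    def __post_init__(self) -> None:
        accs = set(self.records["accession"])
        if not self.enriched <= accs:
            raise ValueError("enriched set contains accessions missing from records")


def intersect_enriched(a: ScreenResult, b: ScreenResult) -> frozenset[str]:
    """Proteins enriched in both screens (exact accession-set intersection)."""
    inter = a.enriched & b.enriched
    logger.info("enriched sets: %s=%d, %s=%d, intersection=%d",
                a.screen_label, len(a.enriched), b.screen_label, len(b.enriched), len(inter))
    return frozenset(inter)


def shared_motif_proteins(
    intersection: Iterable[str],
    counts: Mapping[str, int],
) -> tuple[frozenset[str], int]:
    """Intersection members carrying >= 1 motif, plus their total site count.

    Members without a count (no sequence available) are treated as
    motif-free and logged.
    """
    members = sorted(set(intersection))
    missing = [a for a in members if a not in counts]
    if missing:
        logger.warning("no motif counts for %d shared proteins (treated as 0): %s ...",
                       len(missing), missing[:5])
    with_motif = frozenset(a for a in members if counts.get(a, 0) >= 1)
    total = sum(counts[a] for a in with_motif)
    return with_motif, total


class XrefEntry(NamedTuple):
    """One motif hit annotated against the known-site table."""

    hit: MotifHit
    previously_reported: bool
    conflict: bool  # same (accession, position) but a different residue
    annotation: str


def xref_known_sites(
    hits: Sequence[MotifHit],
    known: KnownSiteTable,
    position_tolerance: int = 0,
) -> list[XrefEntry]:
    """Flag each motif hit as previously reported or novel.

    The join key is the exact (accession, 1-based acceptor position) pair;
    a site at the right position but with a mismatching residue is flagged
    as a conflict, not a match.  ``position_tolerance`` widens the join to
    +/- that many residues (off by default).
    """
    out: list[XrefEntry] = []
    for hit in hits:
        entry = XrefEntry(hit, False, False, "")
        for offset in range(-position_tolerance, position_tolerance + 1):
            found = known.lookup(hit.accession, hit.acceptor_pos + offset)
            if found is None:
                continue
            residue, annotation = found
            if residue == hit.acceptor_residue:
                entry = XrefEntry(hit, True, False, annotation)
                break
            entry = XrefEntry(hit, False, True, annotation)
        out.append(entry)
    n_rep = sum(e.previously_reported for e in out)
    logger.info("known-site xref: %d hits, %d previously reported, %d novel",
                len(out), n_rep, len(out) - n_rep)
    return out


@dataclass(frozen=True)
class ComparisonReport:
    """Assembled two-screen comparison: intersection, motif summary, xref."""

    screen_a: str
    screen_b: str
    n_enriched_a: int
    n_enriched_b: int
    intersection: frozenset[str] = field(hash=False)
    motif_fraction_a: MotifFraction = field(hash=False)
    motif_fraction_b: MotifFraction = field(hash=False)
    shared_with_motif: frozenset[str] = field(hash=False)
    total_motifs_in_shared: int = 0
    xref: tuple[XrefEntry, ...] = field(default=(), hash=False)

    @property
    def n_reported(self) -> int:
        return sum(e.previously_reported for e in self.xref)

    @property
    def n_novel(self) -> int:
        return len(self.xref) - self.n_reported

    def to_summary(self) -> dict[str, object]:
        """Flat JSON-serialisable headline counts."""
        return {
            "screen_a": self.screen_a,
            "screen_b": self.screen_b,
            "n_enriched_a": self.n_enriched_a,
            "n_enriched_b": self.n_enriched_b,
            "n_intersection": len(self.intersection),
            "pct_motif_a": self.motif_fraction_a.percent,
            "pct_motif_b": self.motif_fraction_b.percent,
            "n_shared_with_motif": len(self.shared_with_motif),
            "n_total_motifs_shared": self.total_motifs_in_shared,
            "n_reported": self.n_reported,
            "n_novel": self.n_novel,
        }

    def xref_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": e.hit.accession,
                    "acceptor_pos": e.hit.acceptor_pos,
                    "acceptor_residue": e.hit.acceptor_residue,
                    "window": e.hit.window,
                    "kind": e.hit.kind,
                    "previously_reported": e.previously_reported,
                    "conflict": e.conflict,
                    "annotation": e.annotation,
                }
                for e in self.xref
            ],
            columns=["accession", "acceptor_pos", "acceptor_residue", "window",
                     "kind", "previously_reported", "conflict", "annotation"],
        )


def build_report(
    a: ScreenResult,
    b: ScreenResult,
    counts: Mapping[str, int],
    hits: Sequence[MotifHit],
    known: KnownSiteTable | None = None,
) -> ComparisonReport:
    """Assemble the full two-screen comparison.

    ``counts`` are per-protein motif counts over the scanned proteome;
    ``hits`` are the individual motif occurrences (the xref is restricted to
    hits on the shared motif-bearing proteins, the sites the comparison
    nominates).  A missing known-site table means every site is novel.
    """
    intersection = intersect_enriched(a, b)
    frac_a = fraction_with_motif(a.enriched, counts) if a.enriched else \
        MotifFraction(0.0, 0, 0, 0)
    frac_b = fraction_with_motif(b.enriched, counts) if b.enriched else \
        MotifFraction(0.0, 0, 0, 0)
    shared, total = shared_motif_proteins(intersection, counts)
    shared_hits = [h for h in hits if h.accession in shared]
    xref = xref_known_sites(shared_hits, known if known is not None else KnownSiteTable())
    return ComparisonReport(
        screen_a=a.screen_label,
        screen_b=b.screen_label,
        n_enriched_a=len(a.enriched),
        n_enriched_b=len(b.enriched),
        intersection=intersection,
        motif_fraction_a=frac_a,
        motif_fraction_b=frac_b,
        shared_with_motif=shared,
        total_motifs_in_shared=total,
        xref=tuple(xref),
    )
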