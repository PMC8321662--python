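"""Consensus-motif scanning for protein kinase D substrate sites.

PKD kinases phosphorylate serine/threonine residues in the context
``[L/V/I]xRxx[S/T]``: the acceptor S/T at offset 0, a mandatory arginine at
-3, and a hydrophobic leucine/valine/isoleucine at -5 (``x`` = any residue).
The relaxed form ``Rxx[S/T]`` drops the -5 constraint.  The scanner reports
every acceptor position (1-based, overlapping hits included), in the style
of a ScanProsite pattern search.

Ambiguity codes (X, B, Z, U) match wildcard offsets but never a constrained
offset: an unknown residue cannot be asserted to be L/V/I, R, S or T.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import ConfigurationError
from .io import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifPattern:
    """A positional-constraint motif ending at the phospho-acceptor.

    ``constraints`` maps offsets (relative to the acceptor at 0, all <= 0)
    to the allowed residue set; unconstrained offsets within the window are
    wildcards.  The acceptor constraint is always {S, T}.
    """

    kind: str
    window_length: int
    constraints: Mapping[int, frozenset[str]] = field(hash=False)

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ConfigurationError("window_length must be >= 1")
        if set(self.constraints.get(0, frozenset())) != {"S", "T"}:
            raise ConfigurationError("acceptor constraint (offset 0) must be {S, T}")
        for off in self.constraints:
            if not -self.window_length < off <= 0:
                raise ConfigurationError(
                    f"offset {off} outside window of length {self.window_length}")

    def regex(self) -> re.Pattern[str]:
        """Overlap-tolerant lookahead regex equivalent to the constraint table."""
        parts = []
        for off in range(-(self.window_length - 1), 1):
            allowed = self.constraints.get(off)
            # wildcards match any residue incl. ambiguity codes
            parts.append("[" + "".join(sorted(allowed)) + "]" if allowed else ".")
        return re.compile("(?=(" + "".join(parts) + "))")


FULL_MOTIF = MotifPattern(
    kind="full",
    window_length=6,
    constraints={-5: frozenset("LVI"), -3: frozenset("R"), 0: frozenset("ST")},
)
PARTIAL_MOTIF = MotifPattern(
    kind="partial",
    window_length=4,
    constraints={-3: frozenset("R"), 0: frozenset("ST")},
)

PATTERNS: dict[str, MotifPattern] = {"full": FULL_MOTIF, "partial": PARTIAL_MOTIF}


class MotifHit(NamedTuple):
    """One motif occurrence; ``acceptor_pos`` is 1-based."""

    accession: str
    acceptor_pos: int
    window: str
    kind: str
    acceptor_residue: str


def scan_motifs(record: SequenceRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All motif occurrences in one sequence, ascending by acceptor position.

    Overlapping occurrences are all reported (two acceptors sharing an
    arginine are two hits); hits are unique per (acceptor position, kind).
    Sequences shorter than the window return an empty list.
    """
    seq = record.sequence
    hits: list[MotifHit] = []
    for m in pattern.regex().finditer(seq):
        window = m.group(1)
        acceptor_pos = m.start() + pattern.window_length  # 1-based
        hits.append(MotifHit(
            accession=record.accession,
            acceptor_pos=acceptor_pos,
            window=window,
            kind=pattern.kind,
            acceptor_residue=window[-1],
        ))
    return hits


def scan_proteome(records: Iterable[SequenceRecord], pattern: MotifPattern) -> list[MotifHit]:
    """Concatenated hits over a proteome, per-record order preserved."""
    hits: list[MotifHit] = []
    for rec in records:
        hits.extend(scan_motifs(rec, pattern))
    return hits


def proteome_motif_counts(
    records: Sequence[SequenceRecord],
    pattern: MotifPattern,
) -> dict[str, int]:
    """Number of motif occurrences per protein (0 allowed, all proteins listed)."""
    accs = [rec.accession for rec in records]
    if len(set(accs)) != len(accs):
        dup = next(a for a in accs if accs.count(a) > 1)
        raise ConfigurationError(f"duplicate accession {dup!r} in proteome")
    return {rec.accession: len(scan_motifs(rec, pattern)) for rec in records}


class MotifFraction(NamedTuple):
    fraction: float
    percent: int  # rounded to the nearest integer
    n_with_motif: int
    n_total: int


def fraction_with_motif(accessions: Iterable[str], counts: Mapping[str, int]) -> MotifFraction:
    """Fraction of a protein set possessing at least one motif.

    Proteins absent from ``counts`` (no sequence available) count as
    motif-free and are logged.  Reported both as a fraction and as a
    percentage rounded to the nearest integer.
    """
    accs = sorted(set(accessions))
    if not accs:
        raise ConfigurationError("fraction_with_motif: empty accession set")
    missing = [a for a in accs if a not in counts]
    if missing:
        logger.warning("%d accessions lack sequences; counted as motif-free: %s ...",
                       len(missing), missing[:5])
    n_with = sum(1 for a in accs if counts.get(a, 0) >= 1)
    frac = n_with / len(accs)
    return MotifFraction(fraction=frac, percent=round(frac * 100),
                         n_with_motif=n_with, n_total=len(accs))
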