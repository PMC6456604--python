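"""UMI-aware deduplication, sequencing-error removal and read filtering.

CLIP libraries carry 4+4 nt randomized adapter ends that act as unique
molecular identifiers (UMIs).  The processing chain, applied in this fixed
order, is

1. :func:`collapse_duplicates`      - merge reads identical in sequence+UMI
2. :func:`remove_sequencing_errors` - within a (coordinates, UMI) group,
   drop low-copy reads whose mismatches are a strict superset of the
   dominant read's mismatches (classic PCR/sequencing-error shadows)
3. :func:`filter_end_mismatches`    - drop reads with events in the first
   or last two read positions
4. :func:`resolve_multimappers`     - keep the best alignment only when the
   runner-up has more than one extra mismatch

Every stage is idempotent; the error-removal stage never removes the
highest-copy read of a group.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: named diagnostic-event classes used throughout the pipeline
DE_CLASSES: dict[str, tuple[str, ...]] = {
    "TtoC": ("T-to-C",),
    "Tdel": ("T-del",),
    "TtoV": ("T-to-A", "T-to-C", "T-to-G"),
    "TtoV+Tdel": ("T-to-A", "T-to-C", "T-to-G", "T-del"),
}


def de_types_for(name: str) -> tuple[str, ...]:
    """Expand a DE class name (or a single event token) to event types."""
    if name in DE_CLASSES:
        return DE_CLASSES[name]
    return (name,)


@dataclass(frozen=True)
class AlignedRead:
    """One aligned CLIP read in transcript coordinates.

    ``blocks`` are the gapless aligned sub-intervals (split only at splice
    gaps; deletions stay inside a block).  Mismatch and deletion base
    identities are in transcript-sense orientation.
    """

    name: str
    umi: str | None
    reference: str
    start: int
    end: int
    strand: str
    blocks: tuple[tuple[int, int], ...]
    sequence: str | None = None
    mismatches: tuple[tuple[int, str, str], ...] = ()
    deletions: tuple[tuple[int, str], ...] = ()
    copy_number: int = 1

    @property
    def read_length(self) -> int:
        return sum(e - s for s, e in self.blocks) - len(self.deletions)

    def events(self) -> tuple[tuple[int, str, str], ...]:
        """All diagnostic events as (position, ref base, observed)."""
        return self.mismatches + tuple(
            (p, b, "del") for p, b in self.deletions
        )

    def event_types(self) -> set[str]:
        out = set()
        for _, ref, obs in self.events():
            out.add(f"{ref}-del" if obs == "del" else f"{ref}-to-{obs}")
        return out

    def event_signature(self) -> frozenset:
        """Position+outcome fingerprint used by the error-removal rule."""
        return frozenset(
            [(p, o) for p, _, o in self.mismatches]
            + [(p, "del") for p, _ in self.deletions]
        )


def collapse_duplicates(
    reads: Iterable[AlignedRead], umi_length: int = 8
) -> list[AlignedRead]:
    """Merge reads with identical sequence and UMI into one record.

    The merged record keeps the first read's alignment and accumulates the
    copy number.  Reads without a full-length UMI are rejected (counted).
    """
    merged: dict[tuple, AlignedRead] = {}
    n_rejected = 0
    for read in reads:
        if not read.umi or len(read.umi) < umi_length:
            n_rejected += 1
            continue
        if read.sequence is None:
            raise ConfigurationError(
                f"read {read.name} lacks a sequence; collapsing needs it"
            )
        key = (read.sequence, read.umi)
        prev = merged.get(key)
        if prev is None:
            merged[key] = read
        else:
            merged[key] = replace(
                prev, copy_number=prev.copy_number + read.copy_number
            )
    if n_rejected:
        logger.warning("collapse_duplicates: rejected %d reads without UMI",
                       n_rejected)
    return list(merged.values())


def remove_sequencing_errors(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Drop PCR/sequencing-error shadows within (coordinates, UMI) groups.

    Reads sharing reference, start, end, strand and UMI derive from one
    crosslinked molecule.  Within such a group the highest-copy read is the
    local reference; any lower-copy read whose event fingerprint strictly
    contains the reference read's fingerprint carries extra mismatches on
    fewer copies and is removed.  Equal copy numbers are never removed
    (ties destroy no evidence), and singleton groups pass unchanged.
    """
    groups: dict[tuple, list[AlignedRead]] = defaultdict(list)
    order: list[AlignedRead] = []
    for read in reads:
        groups[(read.reference, read.start, read.end, read.strand, read.umi)
               ].append(read)
        order.append(read)
    removed: set[int] = set()
    for group in groups.values():
        if len(group) < 2:
            continue
        ref = min(
            group,
            key=lambda r: (-r.copy_number, len(r.event_signature()), r.name),
        )
        ref_sig = ref.event_signature()
        for r in group:
            if r is ref:
                continue
            if r.copy_number < ref.copy_number and r.event_signature() > ref_sig:
                removed.add(id(r))
    return [r for r in order if id(r) not in removed]


def _event_read_positions(read: AlignedRead) -> tuple[list[int], int]:
    """1-based read-space positions of all events, in read orientation.

    A deletion is placed at the position the deleted base would have
    occupied (the position of the following read base, clamped to [1, L]).
    """
    del_pos = {p for p, _ in read.deletions}
    mm_pos = {p for p, _, _ in read.mismatches}
    mapping: dict[int, int] = {}
    idx = 0
    for bs, be in read.blocks:
        for p in range(bs, be):
            if p in del_pos:
                mapping[p] = idx + 1
            elif p in mm_pos:
                idx += 1
                mapping[p] = idx
            else:
                idx += 1
    length = idx
    positions = []
    for p in sorted(del_pos | mm_pos):
        q = min(max(mapping[p], 1), length)
        if read.strand == "-":
            q = length + 1 - q
        positions.append(q)
    return positions, length


def filter_end_mismatches(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Drop reads with any event in read positions {1,2} or {L-1,L}.

    Positions are 1-based in read orientation (minus-strand reads are
    counted from their own 5' end), so genuine crosslink events in the read
    interior survive while end-biased artefacts are removed.
    """
    kept = []
    for read in reads:
        positions, length = _event_read_positions(read)
        if any(q <= 2 or q >= length - 1 for q in positions):
            continue
        kept.append(read)
    return kept


def filter_read_length(
    reads: Iterable[AlignedRead], min_length: int = 16
) -> list[AlignedRead]:
    """Drop reads shorter than ``min_length`` aligned nucleotides."""
    return [r for r in reads if r.read_length >= min_length]


def resolve_multimappers(
    candidate_groups: Sequence[Sequence[tuple[AlignedRead, int]]],
) -> list[AlignedRead]:
    """One or zero alignments per read from (alignment, n_mismatch) lists.

    A read with a single candidate is kept; otherwise the best alignment is
    kept only if the second-best has more than one mismatch more.
    """
    out = []
    for group in candidate_groups:
        if not group:
            continue
        ranked = sorted(group, key=lambda t: t[1])
        if len(ranked) == 1 or ranked[1][1] - ranked[0][1] > 1:
            out.append(ranked[0][0])
    return out


def count_de_read_fractions(
    reads: Sequence[AlignedRead],
    types: Sequence[str] = ("T-to-C", "T-del"),
) -> dict[str, float]:
    """Fraction of reads carrying at least one event of each type.

    ``types`` may mix single event tokens ("T-to-C") and named composite
    classes ("TtoV+Tdel"); a read with several events of one type counts
    once for that type.
    """
    reads = list(reads)
    if not reads:
        raise ConfigurationError("DE read fractions are undefined on no reads")
    counts = {t: 0 for t in types}
    for read in reads:
        present = read.event_types()
        for t in types:
            if present & set(de_types_for(t)):
                counts[t] += 1
    n = len(reads)
    return {t: counts[t] / n for t in types}


def process_reads(
    reads: Iterable[AlignedRead],
    min_read_length: int = 16,
    umi_length: int = 8,
) -> list[AlignedRead]:
    """The full processing chain on uniquely aligned reads."""
    out = collapse_duplicates(reads, umi_length=umi_length)
    out = remove_sequencing_errors(out)
    out = filter_end_mismatches(out)
    out = filter_read_length(out, min_read_length)
    return out
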