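"""miRNA seed-match detection and crosslink-anchored miRNA assignment.

A miRNA silences a target through Watson-Crick pairing of its seed region
(positions 2-7, counted 1-based from the miRNA 5' end) to the target 3'UTR.
Canonical site types follow the TargetScan nomenclature:

=========  ===========================================================
type       target requirement (target written 5'->3', DNA alphabet)
=========  ===========================================================
6mer       perfect complement of miRNA positions 2-7
7mer-A1    6mer plus an adenosine opposite miRNA position 1
7mer-m8    perfect complement of miRNA positions 2-8
8mer-A1    7mer-m8 plus the A1 adenosine
bulge      pairing to positions 2-8 with one extra target nucleotide
           bulged out between the bases pairing positions 5 and 6
=========  ===========================================================

Because the duplex is antiparallel, the target site reads as the reverse
complement of the seed, so the 5'-most target nucleotide of a 7mer-m8 pairs
miRNA position 8.  Crosslink-induced diagnostic events concentrate a few
nucleotides 5' of the site start; :class:`OffsetModel` captures that offset
distribution and :func:`assign_mirna` scores candidate sites against the
kernel-smoothed diagnostic-event profile of a cluster.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

CANONICAL_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer-A1")

_DNA = set("ACGT")
_RNA = set("ACGU")

# miRNA (RNA) base -> complementary target (DNA) base
_RNA_TO_DNA_COMP = {"A": "T", "U": "A", "G": "C", "C": "G"}
_DNA_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def _check_target(target: str) -> None:
    if not set(target) <= _DNA:
        raise ConfigurationError(
            f"target sequence contains non-DNA characters: "
            f"{sorted(set(target) - _DNA)}"
        )


def _check_mirna(mirna: str) -> None:
    if not set(mirna) <= _RNA:
        raise ConfigurationError(
            f"miRNA sequence contains non-RNA characters: "
            f"{sorted(set(mirna) - _RNA)}"
        )


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return "".join(_DNA_COMP[b] for b in reversed(seq))


def seed_site_core(mirna: str) -> str:
    """Target-side (DNA) complement of miRNA positions 2-7, written 5'->3'.

    This hexamer is the anchor shared by all canonical site types.
    """
    _check_mirna(mirna)
    return "".join(_RNA_TO_DNA_COMP[b] for b in reversed(mirna[1:7]))


@dataclass(frozen=True)
class SeedMatch:
    """One miRNA seed match on a target sequence (transcript sense)."""

    start: int
    end: int
    mirna_id: str
    seed_type: str

    def __post_init__(self) -> None:
        if self.seed_type == "bulge":
            expected = 8
        else:
            expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer-A1": 8}[
                self.seed_type
            ]
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.seed_type} interval must span {expected} nt, "
                f"got [{self.start},{self.end})"
            )


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def classify_core_occurrence(
    target: str, p: int, mirna: str
) -> tuple[str, int, int]:
    """Classify the canonical site whose 2-7 core starts at ``p``.

    Returns ``(seed_type, start, end)`` for the most specific type supported
    by the flanking nucleotides (8mer-A1 > 7mer-m8 / 7mer-A1 > 6mer).
    """
    m8_comp = _RNA_TO_DNA_COMP[mirna[7]] if len(mirna) >= 8 else None
    has_m8 = m8_comp is not None and p > 0 and target[p - 1] == m8_comp
    has_a1 = p + 6 < len(target) and target[p + 6] == "A"
    if has_m8 and has_a1:
        return "8mer-A1", p - 1, p + 7
    if has_m8:
        return "7mer-m8", p - 1, p + 6
    if has_a1:
        return "7mer-A1", p, p + 7
    return "6mer", p, p + 6


def find_seed_matches(
    target: str,
    mirna: str,
    mirna_id: str = "miRNA",
    allowed_types: Sequence[str] = CANONICAL_TYPES,
) -> list[SeedMatch]:
    """All canonical seed matches of one miRNA on a target sequence.

    Each occurrence of the 2-7 core is reported once, with the most specific
    canonical type its flanks support; types outside ``allowed_types`` are
    then dropped.
    """
    _check_target(target)
    _check_mirna(mirna)
    if len(mirna) < 8:
        raise ConfigurationError("miRNA must be at least 8 nt for seed matching")
    core = seed_site_core(mirna)
    out = []
    for p in _find_all(target, core):
        seed_type, s, e = classify_core_occurrence(target, p, mirna)
        if seed_type in allowed_types:
            out.append(SeedMatch(s, e, mirna_id, seed_type))
    return out


def find_bulge_sites(
    target: str,
    mirna: str,
    mirna_id: str = "miRNA",
    require_pivot_pairing: bool = True,
) -> list[SeedMatch]:
    """Nucleation-bulge sites: pairing to miRNA 2-8 with one extra target
    nucleotide between the bases pairing positions 5 and 6.

    With ``require_pivot_pairing`` the bulged nucleotide must itself be able
    to pair the pivot (miRNA position 6), the transitional-nucleation
    constraint of the original single-bulge site definition.
    """
    _check_target(target)
    _check_mirna(mirna)
    if len(mirna) < 8:
        raise ConfigurationError("miRNA must be at least 8 nt for seed matching")
    # target layout 5'->3': c(m8) c(m7) c(m6) X c(m5) c(m4) c(m3) c(m2)
    comp = [_RNA_TO_DNA_COMP[b] for b in mirna[:8]]
    pre = comp[7] + comp[6] + comp[5]
    suf = comp[4] + comp[3] + comp[2] + comp[1]
    pivot = comp[5]
    out = []
    for p in range(0, len(target) - 7):
        if target[p : p + 3] == pre and target[p + 4 : p + 8] == suf:
            if require_pivot_pairing and target[p + 3] != pivot:
                continue
            out.append(SeedMatch(p, p + 8, mirna_id, "bulge"))
    return out


# ---------------------------------------------------------------------------
# fast candidate search over many sequences (used by assignment and nulls)
# ---------------------------------------------------------------------------


class SeedIndex:
    """Hexamer lookup index over a set of target windows.

    Maps every hexamer in every window to its occurrence positions so that
    seed matches of an arbitrary miRNA (or shuffled decoy) are found with a
    single dictionary lookup instead of a scan.  Used heavily by the decoy
    repetitions, where thousands of shuffled miRNAs are queried against the
    same windows.
    """

    def __init__(self, sequences: Mapping[object, str]):
        self.sequences = dict(sequences)
        self._index: dict[str, list[tuple[object, int]]] = {}
        for key, seq in self.sequences.items():
            for p in range(len(seq) - 5):
                self._index.setdefault(seq[p : p + 6], []).append((key, p))

    def matches(
        self, mirna: str, mirna_id: str = "miRNA",
        allowed_types: Sequence[str] = CANONICAL_TYPES,
    ) -> dict[object, list[SeedMatch]]:
        """Canonical matches of one miRNA, grouped by window key."""
        core = seed_site_core(mirna)
        out: dict[object, list[SeedMatch]] = {}
        for key, p in self._index.get(core, ()):
            seed_type, s, e = classify_core_occurrence(
                self.sequences[key], p, mirna
            )
            if seed_type in allowed_types:
                out.setdefault(key, []).append(SeedMatch(s, e, mirna_id, seed_type))
        return out


# ---------------------------------------------------------------------------
# crosslink-offset model and assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffsetModel:
    """Empirical model of (crosslink position - seed-match start).

    ``variance`` is floored at 0.25 so that a perfectly concentrated training
    set cannot collapse the assignment kernel to a delta function.
    """

    mean: float
    variance: float
    n_training: int
    anchor: str = "crosslink"
    is_fallback: bool = False
    histogram: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("offset-model variance must be positive")


DEFAULT_FALLBACK_MODEL = OffsetModel(
    mean=-1.0, variance=4.0, n_training=0, is_fallback=True
)

VARIANCE_FLOOR = 0.25


@dataclass(frozen=True)
class SeedPrediction:
    """An assigned miRNA-site pair for one cluster."""

    cluster_id: object
    mirna_id: str
    match: SeedMatch
    score: float
    variance: float
    is_decoy: bool = False

    @property
    def transcript_id(self):  # cluster ids are (reference, ordinal) tuples
        return self.cluster_id


def learn_offset_model(
    clusters: Sequence,
    sequences: Mapping[str, str],
    mirnas: Sequence,
    min_clusters: int = 30,
    extend: int = 5,
    anchor: str = "crosslink",
    allowed_types: Sequence[str] = ("7mer-A1", "7mer-m8", "8mer-A1"),
) -> OffsetModel:
    """Learn the crosslink-to-seed offset from unambiguous clusters.

    Only clusters with exactly one 7mer/8mer match of the supplied miRNA set
    (within the interval extended by ``extend`` nt) contribute; with fewer
    than ``min_clusters`` such clusters the conservative default model
    (mean -1, variance 4) is returned with a warning.
    """
    offsets = []
    for cluster in clusters:
        seq = sequences[cluster.reference]
        lo = max(0, cluster.start - extend)
        hi = min(len(seq), cluster.end + extend)
        window = seq[lo:hi]
        found = []
        for m in mirnas:
            for match in find_seed_matches(
                window, m.sequence, m.id, allowed_types
            ):
                found.append(match)
        if len(found) != 1:
            continue
        anchor_pos = (
            cluster.crosslink if anchor == "crosslink" else cluster.coverage_summit
        )
        offsets.append(anchor_pos - (lo + found[0].start))
    if len(offsets) < min_clusters:
        warnings.warn(
            f"only {len(offsets)} unambiguous clusters "
            f"(<{min_clusters}); falling back to the default offset model",
            stacklevel=2,
        )
        return OffsetModel(
            mean=-1.0, variance=4.0, n_training=len(offsets),
            anchor=anchor, is_fallback=True,
        )
    arr = np.asarray(offsets, dtype=float)
    hist: dict[int, int] = {}
    for o in sorted(offsets):
        hist[int(o)] = hist.get(int(o), 0) + 1
    return OffsetModel(
        mean=float(arr.mean()),
        variance=float(max(arr.var(), VARIANCE_FLOOR)),
        n_training=len(offsets),
        anchor=anchor,
        histogram=hist,
    )


DEFAULT_MIN_CONCORDANCE = 0.05


def score_candidate(
    profile_positions: np.ndarray,
    profile_weights: np.ndarray,
    site_start: int,
    model: OffsetModel,
    variance: float,
) -> float:
    """Gaussian-kernel concordance between a smoothed DE profile and a site.

    score = sum_p w(p) * exp(-(p - start - mu)^2 / (2 v)), i.e. the fraction
    of the (unit-mass) smoothed diagnostic-event signal that falls inside a
    Gaussian window of width sqrt(v) centred at the expected crosslink
    position.  The score is non-decreasing in v, so a fixed acceptance
    threshold makes smaller variance strictly more stringent.
    """
    d = profile_positions - site_start - model.mean
    return float(np.sum(profile_weights * np.exp(-(d * d) / (2.0 * variance))))


def assign_mirna(
    cluster,
    mirnas: Sequence,
    sequences: Mapping[str, str],
    model: OffsetModel,
    variance: float = 0.5,
    anchor: str = "crosslink",
    extend: int = 5,
    min_concordance: float = DEFAULT_MIN_CONCORDANCE,
    allowed_types: Sequence[str] = CANONICAL_TYPES,
) -> SeedPrediction | None:
    """Assign the most plausible miRNA to one cluster (one or no prediction).

    Every canonical seed match of the candidate miRNAs inside the cluster
    interval (extended by ``extend`` nt) is scored against the smoothed
    diagnostic-event profile (or, in ``anchor='summit'`` mode, against a unit
    mass at the coverage summit); the best-scoring candidate is returned if
    its concordance reaches ``min_concordance``, otherwise ``None``.
    """
    seq = sequences[cluster.reference]
    lo = max(0, cluster.start - extend)
    hi = min(len(seq), cluster.end + extend)
    window = seq[lo:hi]
    if anchor == "crosslink":
        positions = np.arange(cluster.start, cluster.end, dtype=float)
        weights = cluster.smoothed
    elif anchor == "summit":
        positions = np.array([cluster.coverage_summit], dtype=float)
        weights = np.array([1.0])
    else:
        raise ConfigurationError(f"unknown anchor mode {anchor!r}")
    best: SeedPrediction | None = None
    for m in mirnas:
        for match in find_seed_matches(window, m.sequence, m.id, allowed_types):
            shifted = SeedMatch(
                match.start + lo, match.end + lo, m.id, match.seed_type
            )
            s = score_candidate(positions, weights, shifted.start, model, variance)
            if s < min_concordance:
                continue
            key = (-s, shifted.start, m.id)
            if best is None or key < (-best.score, best.match.start, best.mirna_id):
                best = SeedPrediction(
                    cluster_id=cluster.id,
                    mirna_id=m.id,
                    match=shifted,
                    score=s,
                    variance=variance,
                    is_decoy=getattr(m, "is_decoy", False),
                )
    return best


def assign_all(
    clusters: Sequence,
    mirnas: Sequence,
    sequences: Mapping[str, str],
    model: OffsetModel,
    variance: float = 0.5,
    **kwargs,
) -> list[SeedPrediction]:
    """Run :func:`assign_mirna` over a cluster list, dropping ``None``s."""
    out = []
    for cluster in clusters:
        pred = assign_mirna(cluster, mirnas, sequences, model, variance, **kwargs)
        if pred is not None:
            out.append(pred)
    return out


# ---------------------------------------------------------------------------
# collapsing and reproducibility
# ---------------------------------------------------------------------------


def seed_family(mirnas: Sequence) -> dict[str, str]:
    """Map miRNA id -> family representative id.

    A family is the set of miRNAs sharing positions 2-8; the representative
    is the lexicographically smallest member id.
    """
    groups: dict[str, list[str]] = {}
    for m in mirnas:
        groups.setdefault(m.sequence[1:8], []).append(m.id)
    rep = {}
    for members in groups.values():
        r = min(members)
        for mid in members:
            rep[mid] = r
    return rep


def _genomic_key(pred: SeedPrediction, isoform_map):
    tx = pred.cluster_id[0] if isinstance(pred.cluster_id, tuple) else pred.cluster_id
    if isoform_map is not None:
        tx = isoform_map.get(tx, tx)
    return (tx, pred.match.start, pred.match.end)


def collapse_predictions(
    predictions: Sequence[SeedPrediction],
    mirnas: Sequence,
    isoform_map: Mapping[str, str] | None = None,
) -> list[SeedPrediction]:
    """Collapse predictions sharing coordinates and miRNA seed family.

    Predictions on several isoforms of one gene (``isoform_map``: transcript
    id -> gene id; identity when ``None``) or from seed-family members merge
    to one record represented by the family's lexicographically smallest
    member; the best score is retained.
    """
    family = seed_family(mirnas)
    merged: dict[tuple, SeedPrediction] = {}
    for pred in predictions:
        key = (_genomic_key(pred, isoform_map), family.get(pred.mirna_id, pred.mirna_id))
        prev = merged.get(key)
        if prev is None or pred.score > prev.score:
            rep = family.get(pred.mirna_id, pred.mirna_id)
            merged[key] = SeedPrediction(
                cluster_id=pred.cluster_id,
                mirna_id=rep,
                match=pred.match,
                score=pred.score,
                variance=pred.variance,
                is_decoy=pred.is_decoy,
            )
    return [merged[k] for k in sorted(merged, key=repr)]


def reproducible_predictions(
    preds_a: Sequence[SeedPrediction],
    preds_b: Sequence[SeedPrediction],
    mirnas: Sequence,
    isoform_map: Mapping[str, str] | None = None,
) -> list[SeedPrediction]:
    """Keep collapsed predictions present in both replicate runs."""
    a = collapse_predictions(preds_a, mirnas, isoform_map)
    b = collapse_predictions(preds_b, mirnas, isoform_map)
    family = seed_family(mirnas)

    def key(p):
        return (_genomic_key(p, isoform_map), family.get(p.mirna_id, p.mirna_id))

    keys_b = {key(p) for p in b}
    return [p for p in a if key(p) in keys_b]
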