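"""Binding-site peak calling on read midpoints.

AGO footprints are called from the midpoints of processed reads: midpoint
counts are binned (default 20 nt) per reference and strand, a
zero-truncated negative binomial (ZTNB) background is fit by maximum
likelihood to the lowest 95% of non-zero bin counts, and bins whose
Benjamini-Hochberg-adjusted upper-tail probability falls below the
threshold become peaks (adjacent significant bins merge).  Replicate
reproducibility is scored by a rank-consistency proxy: peaks pairing across
replicates with >= 10% reciprocal-of-smaller overlap are ranked by the
geometric mean of their within-replicate read-count ranks and the top n
are kept (named presets carry the study-scale cut-offs, HITS n=8971 and
PAR n=11667).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, EstimationError
from .process import AlignedRead

logger = logging.getLogger(__name__)

TOP_N_PRESETS = {"hits": 8971, "par": 11667}

REGION_PRIORITY = ("3'UTR", "CDS", "5'UTR")


@dataclass(frozen=True)
class Peak:
    reference: str
    start: int
    end: int
    strand: str
    read_count: int
    p_value: float
    rank: int = 0
    region: str = "none"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_midpoint(read: AlignedRead) -> int:
    """Reference position of the read midpoint.

    For unspliced reads this is floor((start+end)/2); for spliced reads the
    read-space midpoint is projected through the block structure, so it
    lands in the block holding the middle of the read (the part with the
    more extensive exon overlap for two-block reads).
    """
    if len(read.blocks) == 1:
        return (read.start + read.end) // 2
    total = sum(e - s for s, e in read.blocks)
    offset = total // 2
    for s, e in read.blocks:
        if offset < e - s:
            return s + offset
        offset -= e - s
    return read.blocks[-1][1] - 1  # pragma: no cover


def read_midpoints(
    reads: Iterable[AlignedRead],
) -> dict[tuple[str, str], dict[int, int]]:
    """Midpoint counts per (reference, strand)."""
    out: dict[tuple[str, str], dict[int, int]] = {}
    for read in reads:
        key = (read.reference, read.strand)
        pos = read_midpoint(read)
        bucket = out.setdefault(key, {})
        bucket[pos] = bucket.get(pos, 0) + 1
    return out


# ---------------------------------------------------------------------------
# zero-truncated negative binomial background
# ---------------------------------------------------------------------------


def _ztnb_logpmf(x: np.ndarray, r: float, mu: float) -> np.ndarray:
    p = r / (r + mu)
    base = stats.nbinom.logpmf(x, r, p)
    denom = np.log1p(-stats.nbinom.pmf(0, r, p))
    return base - denom


def fit_ztnb(counts: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (size, mean) of a zero-truncated NB.

    Method-of-moments start, Nelder-Mead refinement on (log size, log mean).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 10:
        raise EstimationError("too few bins for a background fit")
    if np.ptp(counts) == 0:
        raise EstimationError("all bin counts identical; background fit "
                              "is degenerate")
    m, v = counts.mean(), counts.var()
    r0 = m * m / (v - m) if v > m else 10.0
    r0 = min(max(r0, 1e-2), 1e3)

    def nll(theta):
        r, mu = np.exp(theta)
        return -np.sum(_ztnb_logpmf(counts, r, mu))

    # r bounded away from 0: the r->0 ridge is a degenerate log-series fit
    res = optimize.minimize(
        nll, x0=np.log([min(max(r0, 0.06), 9e3), max(m, 0.5)]),
        method="L-BFGS-B",
        bounds=[(np.log(0.05), np.log(1e4)), (np.log(1e-3), np.log(1e9))],
    )
    if not res.success:
        raise EstimationError(f"ZTNB fit did not converge: {res.message}")
    r, mu = np.exp(res.x)
    return float(r), float(mu)


def ztnb_sf(x: np.ndarray, r: float, mu: float) -> np.ndarray:
    """P(X >= x | X >= 1) under NB(size=r, mean=mu)."""
    p = r / (r + mu)
    upper = stats.nbinom.sf(np.asarray(x) - 1, r, p)
    return upper / stats.nbinom.sf(0, r, p)


def call_peaks(
    midpoints: Mapping[tuple[str, str], Mapping[int, int]],
    bin_size: int = 20,
    fit_fraction: float = 0.95,
    alpha: float = 0.01,
    min_bins: int = 50,
    reference_lengths: Mapping[str, int] | None = None,
) -> list[Peak]:
    """ZTNB peak calling on binned midpoint counts.

    The background is fit to the lowest ``fit_fraction`` of the bin
    counts: when ``reference_lengths`` is given the cutoff quantile is
    taken over all bins of the binned input space (zero bins included,
    which is what keeps the background estimate clean when bound sites are
    a sizeable share of the occupied bins); otherwise over the non-zero
    bins only.  The ZTNB is always fit to the non-zero counts at or below
    the cutoff.  Bins significant after Benjamini-Hochberg adjustment at
    ``alpha`` become peaks, adjacent significant bins merge, and peaks are
    ranked by read count (dense, unique; ties broken by coordinates).
    Calling is strand-separated and never spans references.
    """
    bins: list[tuple[tuple[str, str], int, int]] = []  # (key, bin index, count)
    for key in sorted(midpoints):
        agg: dict[int, int] = {}
        for pos, c in midpoints[key].items():
            b = pos // bin_size
            agg[b] = agg.get(b, 0) + c
        for b in sorted(agg):
            bins.append((key, b, agg[b]))
    if not bins:
        raise ConfigurationError("no midpoint counts to call peaks on")
    counts = np.array([c for _, _, c in bins], dtype=float)
    if counts.size < min_bins:
        raise EstimationError(
            f"only {counts.size} non-zero bins (<{min_bins}); background "
            f"fit would be unstable"
        )
    if reference_lengths is not None:
        n_total = sum(
            -(-reference_lengths[ref] // bin_size)
            for ref in {k[0] for k in midpoints}
        ) * len({k[1] for k in midpoints})
        n_zero = max(n_total - counts.size, 0)
        cutoff = np.quantile(
            np.concatenate([np.zeros(n_zero), counts]), fit_fraction)
        cutoff = max(cutoff, 2.0)  # keep at least two count levels to fit
    else:
        cutoff = np.quantile(counts, fit_fraction)
    r, mu = fit_ztnb(counts[counts <= cutoff])
    pvals = ztnb_sf(counts, r, mu)
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    peaks: list[Peak] = []
    current = None  # (key, bstart, bend, count, min_p)
    for (key, b, c), sig, q in zip(bins, reject, p_adj):
        if not sig:
            continue
        if current is not None and current[0] == key and b == current[2]:
            current = (key, current[1], b + 1, current[3] + c,
                       min(current[4], q))
        else:
            if current is not None:
                peaks.append(_mk_peak(current, bin_size))
            current = (key, b, b + 1, c, q)
    if current is not None:
        peaks.append(_mk_peak(current, bin_size))
    peaks.sort(key=lambda p: (-p.read_count, p.reference, p.start, p.strand))
    return [replace(p, rank=i + 1) for i, p in enumerate(peaks)]


def _mk_peak(current, bin_size) -> Peak:
    (ref, strand), b0, b1, count, q = current
    return Peak(ref, b0 * bin_size, b1 * bin_size, strand, int(count),
                float(q))


def tile_windows(
    reference_lengths: Mapping[str, int],
    width: int = 40,
    strand: str = "+",
) -> list[Peak]:
    """Fixed-width tiling pseudo-peaks over whole references.

    Signal-free calibration runs (null SNR, positional nulls) need windows
    even though the background caller correctly reports no enrichment;
    these tiles stand in for peaks there.  Ranks are assigned after
    counting reads via :func:`count_reads_in_peaks`.
    """
    out = []
    for ref in sorted(reference_lengths):
        L = reference_lengths[ref]
        for s in range(0, L - width + 1, width):
            out.append(Peak(ref, s, s + width, strand, 0, 1.0))
    return out


def count_reads_in_peaks(
    peaks: Sequence[Peak], reads: Iterable[AlignedRead]
) -> list[Peak]:
    """Re-count reads (by midpoint) in given peaks and re-rank by count."""
    mids = read_midpoints(reads)
    out = []
    for p in peaks:
        bucket = mids.get((p.reference, p.strand), {})
        c = sum(v for pos, v in bucket.items() if p.start <= pos < p.end)
        out.append(replace(p, read_count=c))
    out.sort(key=lambda p: (-p.read_count, p.reference, p.start, p.strand))
    return [replace(p, rank=i + 1) for i, p in enumerate(out)]


# ---------------------------------------------------------------------------
# replicate reproducibility (rank-consistency proxy) and annotation
# ---------------------------------------------------------------------------


def select_reproducible(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    overlap_ratio: float = 0.1,
    n_top: int | str | None = None,
) -> list[Peak]:
    """Pooled peaks supported by both replicates.

    Peaks pair when their intersection covers at least ``overlap_ratio`` of
    the smaller peak; pairs are scored by the geometric mean of their
    within-replicate read-count ranks (rank 1 = most reads) and the best
    ``n_top`` pairs are pooled as union intervals.  Symmetric in replicate
    order.  ``n_top`` may be a preset name from :data:`TOP_N_PRESETS`.
    """
    if isinstance(n_top, str):
        n_top = TOP_N_PRESETS[n_top]
    by_key: dict[tuple[str, str], list[Peak]] = {}
    for p in peaks_b:
        by_key.setdefault((p.reference, p.strand), []).append(p)
    pairs = []
    used: set[int] = set()
    candidates = []
    for pa in peaks_a:
        for pb in by_key.get((pa.reference, pa.strand), []):
            inter = min(pa.end, pb.end) - max(pa.start, pb.start)
            smaller = min(pa.end - pa.start, pb.end - pb.start)
            if inter >= overlap_ratio * smaller and inter > 0:
                # symmetric greedy matching: best overlap first, ties by
                # order-free coordinates
                key = (-inter, min(pa.start, pb.start),
                       max(pa.start, pb.start), pa.reference)
                candidates.append((key, pa, pb))
    for _, pa, pb in sorted(candidates, key=lambda t: t[0]):
        if id(pa) in used or id(pb) in used:
            continue
        used.add(id(pa))
        used.add(id(pb))
        pairs.append((pa, pb))
    scored = sorted(
        pairs,
        key=lambda ab: (math.sqrt(ab[0].rank * ab[1].rank),
                        ab[0].reference, min(ab[0].start, ab[1].start)),
    )
    if n_top is not None and n_top < len(scored):
        scored = scored[:n_top]
    elif n_top is not None and n_top > len(scored):
        logger.warning("select_reproducible: requested top %d but only %d "
                       "paired peaks", n_top, len(scored))
    pooled = [
        Peak(a.reference, min(a.start, b.start), max(a.end, b.end), a.strand,
             a.read_count + b.read_count, min(a.p_value, b.p_value))
        for a, b in scored
    ]
    pooled.sort(key=lambda p: (-p.read_count, p.reference, p.start))
    return [replace(p, rank=i + 1) for i, p in enumerate(pooled)]


def annotate_peaks(
    peaks: Sequence[Peak],
    regions: Mapping[str, Sequence[tuple[int, int, str]]],
) -> list[Peak]:
    """Label peaks by the region containing their midpoint.

    Boundary ties resolve by priority 3'UTR > CDS > 5'UTR; peaks on
    references absent from the annotation get "none" with a warning.
    """
    missing = set()
    out = []
    for p in peaks:
        if p.reference not in regions:
            missing.add(p.reference)
            out.append(replace(p, region="none"))
            continue
        mid = p.midpoint
        hits = [lab for s, e, lab in regions[p.reference] if s <= mid < e]
        label = "none"
        for cand in REGION_PRIORITY:
            if cand in hits:
                label = cand
                break
        out.append(replace(p, region=label))
    if missing:
        logger.warning("annotate_peaks: references missing from annotation: "
                       "%s", sorted(missing))
    return out
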