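"""Synthetic AGO-CLIP study generator with planted ground truth.

Every input the pipeline consumes can be produced here with a known answer
key: a transcriptome with 5'UTR/CDS/3'UTR structure, a miRNA pool with
bimodal log-expression, 3'UTRs carrying planted canonical seed matches, and
CLIP reads whose crosslink-induced diagnostic events sit a few nucleotides
5' of the planted sites.  Protocol presets encode the two library types:

* PAR  - photoactivatable-ribonucleoside protocol; most reads carry a
  T-to-C conversion at the crosslinked uridine (per-read default 0.80).
* HITS - conventional UV crosslinking; conversions are rare
  (T-to-C 0.016) and T-deletions rarer still (0.0083).

Reads receive 4+4 nt UMIs, geometric PCR duplication and independent
per-base sequencing errors, so the downstream UMI-aware error removal has
realistic work to do.  A truth table and per-read provenance are emitted
for end-to-end verification.

All randomness flows from one integer seed; each stage derives its own
sub-stream so stages are independently reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError, PlantingError
from .process import AlignedRead
from .seeds import CANONICAL_TYPES, find_seed_matches, revcomp_dna

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_RNA_BASES = np.array(list("ACGU"))
_RNA_TO_DNA_COMP = {"A": "T", "U": "A", "G": "C", "C": "G"}

# stage tags for sub-seed derivation
_STAGE_REFERENCE = 1
_STAGE_MIRNA = 2
_STAGE_PLANT = 3
_STAGE_CLIP = 4
_STAGE_SMRNA = 5
_STAGE_KNOCKDOWN = 6


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent generator for one pipeline stage of one study seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]
    expression: float = 1.0

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1), (c0, c1) = self.utr5, self.cds, self.utr3
        if not (a0 == 0 and a1 == b0 and b1 == c0 and c1 == len(self.sequence)):
            raise ValueError(f"{self.id}: regions must tile [0, length)")


@dataclass(frozen=True)
class SyntheticReference:
    transcripts: tuple[Transcript, ...]

    def sequences(self) -> dict[str, str]:
        return {t.id: t.sequence for t in self.transcripts}

    def lengths(self) -> dict[str, int]:
        return {t.id: len(t.sequence) for t in self.transcripts}

    def get(self, tx_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == tx_id:
                return t
        raise KeyError(tx_id)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; position 1 is the 5' nucleotide, seed = 2-8."""

    id: str
    sequence: str
    expression_rpm: float = 0.0
    clip_enriched: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not 19 <= len(self.sequence) <= 25:
            raise ValueError(f"{self.id}: mature miRNA length must be 19-25 nt")


#: per-site crosslink offset relative to the seed-match start (5'-most
#: target nucleotide); negative = 5' of the site, matching the observed
#: concentration of diagnostic events just upstream of seed matches.
DEFAULT_OFFSET_DIST: dict[int, float] = {
    -5: 0.05, -4: 0.10, -3: 0.15, -2: 0.30, -1: 0.35, 0: 0.05,
}

DEFAULT_TYPE_PROPORTIONS: dict[str, float] = {
    "8mer-A1": 0.25, "7mer-m8": 0.35, "7mer-A1": 0.30, "6mer": 0.10,
}

#: additive per-site de-repression (log2FC upon AGO depletion), ordered
#: 8mer >= 7mer >= 6mer
DEFAULT_KNOCKDOWN_EFFECTS: dict[str, float] = {
    "8mer-A1": 0.35, "7mer-m8": 0.25, "7mer-A1": 0.20, "6mer": 0.10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable knobs of the read simulator (see module docstring)."""

    seed: int = 0
    protocol: str = "PAR"
    p_t2c: float = 0.80
    p_tdel: float = 0.005
    seq_error_rate: float = 0.001
    pcr_mean_copies: float = 1.7
    umi_length: int = 8
    read_length: tuple[int, int] = (26, 36)
    reads_per_site: float = 30.0
    background_fraction: float = 0.30
    n_background: int | None = None
    ligation_sigma: float = 1.5
    knockdown_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KNOCKDOWN_EFFECTS)
    )
    dispersion: float = 0.1
    replicates: int = 2
    offset_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_DIST)
    )

    def __post_init__(self) -> None:
        for name in ("p_t2c", "p_tdel", "seq_error_rate", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.p_t2c + self.p_tdel > 1.0:
            raise ConfigurationError("p_t2c + p_tdel must not exceed 1")
        if self.read_length[0] < 16:
            raise ConfigurationError("minimum read length is 16 nt")
        if self.pcr_mean_copies < 1.0:
            raise ConfigurationError("pcr_mean_copies must be >= 1")
        if abs(sum(self.offset_dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("offset distribution must sum to 1")


def par_config(seed: int = 0, **overrides) -> SimulationConfig:
    """PAR protocol preset: most reads T-to-C converted."""
    kw = dict(protocol="PAR", p_t2c=0.80, p_tdel=0.005)
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


def hits_config(seed: int = 0, **overrides) -> SimulationConfig:
    """HITS protocol preset: rare T-to-C, rarer T-deletions."""
    kw = dict(protocol="HITS", p_t2c=0.016, p_tdel=0.0083)
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


def config_for(protocol: str, seed: int = 0, **overrides) -> SimulationConfig:
    if protocol.upper() == "PAR":
        return par_config(seed, **overrides)
    if protocol.upper() == "HITS":
        return hits_config(seed, **overrides)
    raise ConfigurationError(f"unknown protocol {protocol!r}")


# ---------------------------------------------------------------------------
# reference and miRNA pool
# ---------------------------------------------------------------------------


def _composition_probs(comp: Mapping[str, float]) -> np.ndarray:
    p = np.array([comp.get(b, 0.0) for b in "ACGT"], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"base composition must be non-negative and sum to 1, got {comp}"
        )
    return p


def generate_reference(
    n_transcripts: int,
    seed: int = 0,
    utr5_length: tuple[int, int] = (60, 150),
    cds_length: tuple[int, int] = (300, 900),
    utr3_length: tuple[int, int] = (240, 600),
    utr3_au_fraction: float = 0.6,
    body_composition: Mapping[str, float] | None = None,
    utr3_composition: Mapping[str, float] | None = None,
) -> SyntheticReference:
    """A toy transcriptome in transcript coordinates.

    Each transcript is 5'UTR + CDS + 3'UTR with lengths drawn uniformly
    from the given ranges; the 3'UTR is AU-rich by default (fraction 0.6).
    Transcript expression weights (used for background read placement) are
    log-normal.
    """
    if n_transcripts < 1:
        raise ConfigurationError("n_transcripts must be >= 1")
    if utr3_length[0] < 60:
        raise ConfigurationError("3'UTR length must be >= 60 nt")
    body = _composition_probs(body_composition or
                              {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
    if utr3_composition is None:
        au = utr3_au_fraction
        utr3_composition = {"A": au / 2, "T": au / 2,
                           "G": (1 - au) / 2, "C": (1 - au) / 2}
    utr3 = _composition_probs(utr3_composition)
    rng = stage_rng(seed, _STAGE_REFERENCE)
    width = len(str(n_transcripts))
    transcripts = []
    for i in range(n_transcripts):
        l5 = int(rng.integers(utr5_length[0], utr5_length[1] + 1))
        lc = int(rng.integers(cds_length[0], cds_length[1] + 1))
        l3 = int(rng.integers(utr3_length[0], utr3_length[1] + 1))
        seq = "".join(
            np.concatenate([
                rng.choice(_BASES, size=l5 + lc, p=body),
                rng.choice(_BASES, size=l3, p=utr3),
            ])
        )
        transcripts.append(
            Transcript(
                id=f"tx{i:0{width}d}",
                sequence=seq,
                utr5=(0, l5),
                cds=(l5, l5 + lc),
                utr3=(l5 + lc, l5 + lc + l3),
                expression=float(rng.lognormal(math.log(100.0), 1.0)),
            )
        )
    return SyntheticReference(tuple(transcripts))


def generate_mirna_pool(
    n: int,
    seed: int = 0,
    length: int = 22,
    log10_means: tuple[float, float] = (0.5, 3.0),
    log10_sds: tuple[float, float] = (0.5, 0.5),
    weight_high: float = 0.5,
    max_retries: int = 10000,
) -> list[MiRNA]:
    """Random miRNA pool with two-component log10-normal expression.

    The upper mixture component models the CLIP-enriched miRNAs; no two
    pool members share positions 2-8 (distinct seed families).
    """
    if n < 2:
        raise ConfigurationError("pool size must be >= 2")
    rng = stage_rng(seed, _STAGE_MIRNA)
    seeds_seen: set[str] = set()
    out = []
    width = len(str(n))
    for i in range(n):
        for _ in range(max_retries):
            seq = "".join(rng.choice(_RNA_BASES, size=length))
            if seq[1:8] not in seeds_seen:
                seeds_seen.add(seq[1:8])
                break
        else:
            raise GenerationError(
                f"could not draw {n} distinct seed heptamers"
            )
        hi = rng.random() < weight_high
        mu, sd = (log10_means[1], log10_sds[1]) if hi else (
            log10_means[0], log10_sds[0])
        out.append(
            MiRNA(
                id=f"mir-sim-{i:0{width}d}",
                sequence=seq,
                expression_rpm=float(10.0 ** rng.normal(mu, sd)),
                clip_enriched=bool(hi),
            )
        )
    return out


# ---------------------------------------------------------------------------
# target-site planting
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "site_id", "transcript_id", "start", "end",
    "mirna_id", "seed_type", "offset", "crosslink",
]

_SITE_MARGIN_3P = 40  # room for reads downstream of the site
_SITE_MARGIN_5P = 6   # room for the upstream crosslink and flank edits


def _site_bases(mirna_seq: str, seed_type: str) -> str:
    comp = [_RNA_TO_DNA_COMP[b] for b in mirna_seq[:8]]
    core = "".join(reversed(comp[1:7]))  # complements positions 2-7
    if seed_type == "6mer":
        return core
    if seed_type == "7mer-A1":
        return core + "A"
    if seed_type == "7mer-m8":
        return comp[7] + core
    if seed_type == "8mer-A1":
        return comp[7] + core + "A"
    raise ConfigurationError(f"unknown seed type {seed_type!r}")


def plant_target_sites(
    reference: SyntheticReference,
    mirnas: Sequence[MiRNA],
    n_sites: int | None = None,
    density_per_kb: float | None = None,
    type_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    offset_dist: Mapping[int, float] | None = None,
    max_site_retries: int = 300,
) -> tuple[SyntheticReference, pd.DataFrame]:
    """Write canonical seed matches into 3'UTRs and record the answer key.

    Sites are placed uniformly within 3'UTRs (with margins so that reads
    fit around them), never within 25 nt of another planted site, and are
    resampled whenever the edit would create a seed match of any *other*
    pool miRNA within +/-25 nt.  Each site also receives a crosslinkable T
    at a drawn offset 5' of (or inside) the site; flanking bases are
    adjusted so the planted type is exactly what the seed matcher reports.
    """
    type_props = dict(type_proportions or DEFAULT_TYPE_PROPORTIONS)
    if abs(sum(type_props.values()) - 1.0) > 1e-9:
        raise ConfigurationError("seed-type proportions must sum to 1")
    offsets = dict(offset_dist or DEFAULT_OFFSET_DIST)
    total_kb = sum(
        (t.utr3[1] - t.utr3[0]) for t in reference.transcripts) / 1000.0
    if n_sites is None:
        if density_per_kb is None:
            raise ConfigurationError("give n_sites or density_per_kb")
        n_sites = int(round(density_per_kb * total_kb))
    if n_sites == 0:
        return reference, pd.DataFrame(columns=TRUTH_COLUMNS)

    rng = stage_rng(seed, _STAGE_PLANT)
    seqs = {t.id: list(t.sequence) for t in reference.transcripts}
    occupied: dict[str, list[tuple[int, int]]] = {t.id: [] for t in
                                                  reference.transcripts}
    eligible = []
    weights = []
    for t in reference.transcripts:
        span = (t.utr3[1] - _SITE_MARGIN_3P - 8) - (t.utr3[0] + _SITE_MARGIN_5P)
        if span > 0:
            eligible.append(t)
            weights.append(span)
    if not eligible:
        raise PlantingError(
            f"no 3'UTR is long enough to carry a site (first transcript: "
            f"{reference.transcripts[0].id})"
        )
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    types = sorted(type_props)
    type_p = np.array([type_props[t] for t in types])
    off_keys = sorted(offsets)
    off_p = np.array([offsets[k] for k in off_keys], dtype=float)

    records = []
    for site_id in range(n_sites):
        planted = False
        for _ in range(max_site_retries):
            t = eligible[int(rng.choice(len(eligible), p=weights))]
            seed_type = types[int(rng.choice(len(types), p=type_p))]
            m = mirnas[int(rng.integers(len(mirnas)))]
            site = _site_bases(m.sequence, seed_type)
            lo = t.utr3[0] + _SITE_MARGIN_5P
            hi = t.utr3[1] - _SITE_MARGIN_3P - len(site)
            if hi <= lo:
                continue
            p = int(rng.integers(lo, hi))
            if any(p - 25 < e and s < p + len(site) + 25
                   for s, e in occupied[t.id]):
                continue
            seq = seqs[t.id]
            backup = seq[p - 6 : p + len(site) + 1]
            seq[p : p + len(site)] = list(site)
            # flank edits preventing an unintended type upgrade
            m8c = _RNA_TO_DNA_COMP[m.sequence[7]]
            if seed_type in ("6mer", "7mer-A1") and seq[p - 1] == m8c:
                seq[p - 1] = _other_base(rng, forbid={m8c})
            if seed_type in ("6mer",) and seq[p + 6] == "A":
                seq[p + 6] = _other_base(rng, forbid={"A"})
            if seed_type == "7mer-m8" and seq[p + 7] == "A":
                seq[p + 7] = _other_base(rng, forbid={"A"})
            # crosslinkable T at a drawn offset from the site start
            feasible = []
            for o in off_keys:
                q = p + o
                if o < 0:
                    if q <= t.utr3[0]:
                        continue
                    if o == -1 and seed_type in ("6mer", "7mer-A1") and m8c == "T":
                        continue  # a T here would complete the m8 pairing
                    feasible.append(o)
                elif site[o] == "T":
                    feasible.append(o)
            if not feasible:
                seq[p - 6 : p + len(site) + 1] = backup
                continue
            fp = np.array([offsets[o] for o in feasible], dtype=float)
            fp /= fp.sum()
            o = int(feasible[int(rng.choice(len(feasible), p=fp))])
            if o < 0:
                seq[p + o] = "T"
            # reject if another pool miRNA now matches within +/-25 nt
            wlo, whi = max(0, p - 25), min(len(seq), p + len(site) + 25)
            window = "".join(seq[wlo:whi])
            collision = False
            for other in mirnas:
                if other.id == m.id:
                    continue
                if find_seed_matches(window, other.sequence, other.id):
                    collision = True
                    break
            if collision:
                seq[p - 6 : p + len(site) + 1] = backup
                continue
            # consistency: the matcher must report exactly the planted type
            own = [
                x for x in find_seed_matches(window, m.sequence, m.id)
                if wlo + x.start == p
            ]
            if len(own) != 1 or own[0].seed_type != seed_type:
                seq[p - 6 : p + len(site) + 1] = backup
                continue
            occupied[t.id].append((p, p + len(site)))
            records.append({
                "site_id": site_id,
                "transcript_id": t.id,
                "start": p,
                "end": p + len(site),
                "mirna_id": m.id,
                "seed_type": seed_type,
                "offset": o,
                "crosslink": p + o,
            })
            planted = True
            break
        if not planted:
            raise PlantingError(
                f"could not place site {site_id} after {max_site_retries} "
                f"attempts (3'UTRs too short/crowded for the requested "
                f"density; e.g. transcript {eligible[0].id})"
            )
    new_transcripts = tuple(
        replace(t, sequence="".join(seqs[t.id])) for t in reference.transcripts
    )
    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)
    return SyntheticReference(new_transcripts), truth


def _other_base(rng: np.random.Generator, forbid: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in forbid]
    return choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# CLIP read simulation
# ---------------------------------------------------------------------------


def simulate_clip_reads(
    reference: SyntheticReference,
    truth: pd.DataFrame,
    config: SimulationConfig,
    replicate: int = 0,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate raw (pre-deduplication) CLIP reads with provenance.

    Signal molecules sample read windows around each planted crosslink;
    background molecules land uniformly on expression-weighted transcripts
    and crosslink at a random interior T.  Per-molecule conversion/deletion
    events use the protocol probabilities; every molecule gets an 8-nt UMI,
    a geometric PCR copy number and independent per-base sequencing errors.
    ``replicate`` shifts the sub-seed so biological replicates differ.

    Returns the raw read list and a provenance frame
    (read name -> molecule, origin, site_id).
    """
    if truth.empty and config.n_background is None:
        raise ConfigurationError(
            "empty truth table: set n_background for background-only mode"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STAGE_CLIP, int(replicate)])
    )
    seqs = reference.sequences()
    tx_ids = [t.id for t in reference.transcripts]
    tx_w = np.array(
        [t.expression * len(t.sequence) for t in reference.transcripts]
    )
    tx_w = tx_w / tx_w.sum()
    lmin, lmax = config.read_length
    p_conv, p_del = config.p_t2c, config.p_tdel

    jobs: list[tuple[str, int, int]] = []  # (transcript, crosslink|-1, site)
    for row in truth.itertuples(index=False):
        n_mol = int(rng.poisson(config.reads_per_site))
        jobs.extend([(row.transcript_id, int(row.crosslink), int(row.site_id))]
                    * n_mol)
    n_signal = len(jobs)
    if config.n_background is not None:
        n_bg = int(config.n_background)
    else:
        f = config.background_fraction
        n_bg = int(round(n_signal * f / (1.0 - f))) if f > 0 else 0
    for _ in range(n_bg):
        tx = tx_ids[int(rng.choice(len(tx_ids), p=tx_w))]
        jobs.append((tx, -1, -1))

    reads: list[AlignedRead] = []
    prov_rows = []
    n_skipped = 0
    base_list = "ACGT"
    for mol, (tx, x, site_id) in enumerate(jobs):
        seq = seqs[tx]
        tlen = len(seq)
        L = int(rng.integers(lmin, lmax + 1))
        if tlen <= L:
            n_skipped += 1
            continue
        if x >= 0:  # signal: the crosslink must sit in the read interior
            ok = False
            for _ in range(8):
                s = x - int(rng.integers(3, L - 3))
                s = min(max(s, 0), tlen - L)
                if 2 < x - s < L - 3:
                    ok = True
                    break
            if not ok:
                n_skipped += 1
                continue
        else:
            s = int(rng.integers(0, tlen - L + 1))
        u = rng.random()
        event = "conv" if u < p_conv else ("del" if u < p_conv + p_del else None)
        epos = -1
        if event is not None:
            if x >= 0:
                if seq[x] == "T":
                    epos = x
                else:  # planted crosslink lost (should not happen)
                    n_skipped += 1
                    event = None
            else:
                ts = [i for i in range(s + 3, s + L - 3) if seq[i] == "T"]
                if ts:
                    epos = ts[int(rng.integers(len(ts)))]
                else:
                    event = None
        template = list(seq[s : s + L])
        deletions: tuple[tuple[int, str], ...] = ()
        if event == "conv":
            template[epos - s] = "C"
        elif event == "del":
            del template[epos - s]
            deletions = ((epos, "T"),)
        umi = "".join(base_list[i] for i in rng.integers(0, 4, config.umi_length))
        n_copies = int(rng.geometric(1.0 / config.pcr_mean_copies))
        for copy in range(n_copies):
            obs = template
            if config.seq_error_rate > 0:
                n_err = int(rng.binomial(len(template), config.seq_error_rate))
                if n_err:
                    obs = list(template)
                    for i in rng.choice(len(template), n_err, replace=False):
                        cur = obs[i]
                        obs[i] = base_list[
                            (base_list.index(cur) + 1 + int(rng.integers(3))) % 4
                        ]
            mismatches = _call_mismatches(seq, s, L, obs, deletions)
            name = f"m{mol}.{copy}"
            reads.append(
                AlignedRead(
                    name=name,
                    umi=umi,
                    reference=tx,
                    start=s,
                    end=s + L,
                    strand="+",
                    blocks=((s, s + L),),
                    sequence="".join(obs),
                    mismatches=mismatches,
                    deletions=deletions,
                )
            )
            prov_rows.append({
                "read": name,
                "molecule": mol,
                "origin": "signal" if x >= 0 else "background",
                "site_id": site_id,
                "has_error": int(obs is not template),
            })
    if n_skipped:
        logger.warning("simulate_clip_reads: skipped %d molecules "
                       "(boundary or missing crosslink T)", n_skipped)
    order = {t: i for i, t in enumerate(tx_ids)}
    idx = sorted(range(len(reads)),
                 key=lambda i: (order[reads[i].reference], reads[i].start,
                                reads[i].name))
    reads = [reads[i] for i in idx]
    prov = pd.DataFrame([prov_rows[i] for i in idx],
                        columns=["read", "molecule", "origin", "site_id",
                                 "has_error"])
    return reads, prov


def _call_mismatches(ref_seq, s, L, obs, deletions):
    delset = {p for p, _ in deletions}
    out = []
    i = 0
    for p in range(s, s + L):
        if p in delset:
            continue
        r = ref_seq[p]
        if obs[i] != r:
            out.append((p, r, obs[i]))
        i += 1
    return tuple(out)


# ---------------------------------------------------------------------------
# small-RNA sequencing and knockdown response
# ---------------------------------------------------------------------------


def simulate_smrnaseq(
    mirnas: Sequence[MiRNA],
    bias: str = "none",
    sigma: float = 1.5,
    library_size: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """A miRNA count table from multinomial sampling of the pool.

    ``bias='ligation'`` multiplies each miRNA's sampling weight by a
    log-normal(0, sigma^2) capture efficiency, emulating fixed-adapter
    ligation bias; ``sigma=0`` reduces exactly to the unbiased model.
    """
    if library_size < 1000:
        raise ConfigurationError("library_size must be >= 1000")
    if bias not in ("none", "ligation"):
        raise ConfigurationError(f"unknown bias model {bias!r}")
    rng = stage_rng(seed, _STAGE_SMRNA)
    w = np.array([m.expression_rpm for m in mirnas], dtype=float)
    if bias == "ligation" and sigma > 0:
        w = w * rng.lognormal(0.0, sigma, size=len(w))
    p = w / w.sum()
    counts = rng.multinomial(int(library_size), p)
    return pd.DataFrame({
        "mirna_id": [m.id for m in mirnas],
        "count": counts.astype(int),
    })


def expected_log2fc(
    truth: pd.DataFrame, effects: Mapping[str, float]
) -> pd.Series:
    """Additive expected RNA log2 fold change per transcript."""
    if truth.empty:
        return pd.Series(dtype=float)
    eff = truth["seed_type"].map(lambda t: effects[t])
    return eff.groupby(truth["transcript_id"]).sum()


def simulate_knockdown(
    genes: Sequence[str] | SyntheticReference,
    truth: pd.DataFrame,
    effects: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    replicates: int = 2,
    seed: int = 0,
    base_mean: float = 200.0,
    te_fraction: float = 0.1,
    te_effect: float = 0.25,
) -> tuple[dict[str, dict[str, pd.DataFrame]], pd.DataFrame]:
    """Negative-binomial count tables for an AGO-depletion experiment.

    The expected RNA log2FC (depleted vs control) of a gene is the sum of
    its planted sites' per-type effects; ribosome-footprint counts inherit
    the RNA effect plus an extra translational component for a random
    ``te_fraction`` of genes.  Returns
    ``({"rna"|"ribo"}{"control"|"depleted"} -> genes x replicates counts,
    expected-effect table)``.
    """
    if replicates < 2:
        raise ConfigurationError("fold changes need >= 2 replicates")
    if isinstance(genes, SyntheticReference):
        genes = [t.id for t in genes.transcripts]
    genes = list(genes)
    effects = dict(effects or DEFAULT_KNOCKDOWN_EFFECTS)
    rng = stage_rng(seed, _STAGE_KNOCKDOWN)
    lfc_rna = expected_log2fc(truth, effects).reindex(genes).fillna(0.0)
    n = len(genes)
    te_genes = set()
    if te_fraction > 0:
        k = int(round(te_fraction * n))
        te_genes = set(np.array(genes)[rng.choice(n, size=k, replace=False)])
    lfc_ribo = lfc_rna + pd.Series(
        [te_effect if g in te_genes else 0.0 for g in genes], index=genes)

    mu_rna = rng.lognormal(math.log(base_mean), 1.0, size=n)
    mu_ribo = mu_rna * rng.lognormal(0.0, 0.3, size=n)
    r = 1.0 / dispersion

    def draw(mu):
        cols = {}
        for j in range(replicates):
            pnb = r / (r + mu)
            cols[f"rep{j + 1}"] = rng.negative_binomial(r, pnb, size=n)
        return pd.DataFrame(cols, index=genes)

    tables = {
        "rna": {
            "control": draw(mu_rna),
            "depleted": draw(mu_rna * 2.0 ** lfc_rna.to_numpy()),
        },
        "ribo": {
            "control": draw(mu_ribo),
            "depleted": draw(mu_ribo * 2.0 ** lfc_ribo.to_numpy()),
        },
    }
    expected = pd.DataFrame({
        "expected_rna_log2fc": lfc_rna,
        "expected_ribo_log2fc": lfc_ribo,
    })
    expected.index.name = "gene"
    return tables, expected
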