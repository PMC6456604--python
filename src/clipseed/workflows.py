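"""End-to-end study workflows: simulate -> process -> peaks -> clusters ->
assignment, plus the calibration experiments built on them.

These functions wire the individual modules into the standard analyses:
the planted-signal recovery study, the signal-free null benchmark, the
diagnostic-event rate round trip and the positional-preference null.  The
command-line interface exposes the same steps file-by-file; these are the
in-memory equivalents used by scripted analyses.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import simulate as sim
from .de import DETrack, form_clusters, positional_preference_stats
from .decoys import sweep
from .peaks import call_peaks, count_reads_in_peaks, read_midpoints, tile_windows
from .process import process_reads
from .seeds import assign_all, learn_offset_model
from .simulate import TRUTH_COLUMNS

logger = logging.getLogger(__name__)


def run_planted_study(
    seed: int,
    n_transcripts: int = 300,
    n_mirnas: int = 30,
    n_sites: int = 500,
    protocol: str = "PAR",
    variance: float = 0.5,
    type_proportions: Mapping[str, float] | None = None,
    **config_overrides,
) -> dict:
    """The full planted-signal pipeline; returns all intermediates."""
    reference = sim.generate_reference(n_transcripts, seed=seed)
    mirnas = sim.generate_mirna_pool(n_mirnas, seed=seed)
    reference, truth = sim.plant_target_sites(
        reference, mirnas, n_sites=n_sites, seed=seed,
        type_proportions=type_proportions,
        offset_dist=config_overrides.get("offset_dist"))
    config = sim.config_for(protocol, seed=seed, **config_overrides)
    raw_reads, provenance = sim.simulate_clip_reads(reference, truth, config)
    processed = process_reads(raw_reads)
    peaks = call_peaks(read_midpoints(processed),
                       reference_lengths=reference.lengths())
    track = DETrack.from_reads(processed, reference.lengths())
    clusters = form_clusters(peaks, track)
    sequences = reference.sequences()
    model = learn_offset_model(clusters, sequences, mirnas)
    predictions = assign_all(clusters, mirnas, sequences, model,
                             variance=variance)
    return {
        "seed": seed,
        "reference": reference,
        "mirnas": mirnas,
        "truth": truth,
        "config": config,
        "raw_reads": raw_reads,
        "provenance": provenance,
        "processed": processed,
        "peaks": peaks,
        "track": track,
        "clusters": clusters,
        "sequences": sequences,
        "model": model,
        "predictions": predictions,
    }


def planted_recovery(study: Mapping) -> tuple[int, int]:
    """(sites covered by a cluster, covered sites assigned correctly).

    A planted site counts as recovered when an overlapping cluster carries
    a prediction for the planted miRNA whose site interval overlaps the
    planted interval.
    """
    clusters_by_tx: dict[str, list] = {}
    for c in study["clusters"]:
        clusters_by_tx.setdefault(c.reference, []).append(c)
    preds = {p.cluster_id: p for p in study["predictions"]}
    covered = recovered = 0
    for row in study["truth"].itertuples():
        hits = [c for c in clusters_by_tx.get(row.transcript_id, [])
                if c.start < row.end + 5 and row.start - 5 < c.end]
        if not hits:
            continue
        covered += 1
        for c in hits:
            p = preds.get(c.id)
            if (p is not None and p.mirna_id == row.mirna_id
                    and p.match.start < row.end
                    and row.start < p.match.end):
                recovered += 1
                break
    return covered, recovered


def run_null_study(
    seed: int,
    n_transcripts: int = 40,
    n_background: int = 30000,
    tile_width: int = 40,
    protocol: str = "PAR",
) -> dict:
    """Signal-free background study with tiling pseudo-clusters.

    Without planted signal the background peak caller correctly reports
    (close to) nothing, so fixed-width tiling windows stand in for peaks;
    clusters are then formed, trimmed and smoothed exactly as usual.
    """
    reference = sim.generate_reference(n_transcripts, seed=seed)
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    config = sim.config_for(protocol, seed=seed, n_background=n_background)
    raw_reads, _ = sim.simulate_clip_reads(reference, truth, config)
    processed = process_reads(raw_reads)
    tiles = count_reads_in_peaks(
        tile_windows(reference.lengths(), width=tile_width), processed)
    track = DETrack.from_reads(processed, reference.lengths())
    clusters = form_clusters(tiles, track)
    return {
        "seed": seed,
        "reference": reference,
        "sequences": reference.sequences(),
        "processed": processed,
        "track": track,
        "clusters": clusters,
    }


def null_snr(
    null_study: Mapping,
    seed: int,
    n_pools: int = 4,
    reps_per_pool: int = 25,
    pool_size: int = 30,
    variance: float = 0.5,
) -> dict:
    """Mean null SNR over independent query pools x shuffle repetitions.

    Averaging over several independent random query pools (not just
    shuffle repetitions of one pool) removes the finite-pool draw from the
    type-I anchor estimate.
    """
    clusters = null_study["clusters"]
    sequences = null_study["sequences"]
    snrs, senss, specs = [], [], []
    for i in range(n_pools):
        mirnas = sim.generate_mirna_pool(pool_size, seed=seed + 1000 * (i + 1))
        model = learn_offset_model(clusters, sequences, mirnas)
        df = sweep(clusters, sequences, mirnas, model,
                   variance_levels=(variance,), repetitions=reps_per_pool,
                   seed=seed + i, include_baseline=False)
        row = df.iloc[0]
        snrs.append(row.snr_mean)
        senss.append(row.sensitivity_mean)
        specs.append(row.specificity_mean)
    return {
        "snr_mean": float(np.mean(snrs)),
        "sensitivity_mean": float(np.mean(senss)),
        "specificity_mean": float(np.mean(specs)),
        "repetitions": n_pools * reps_per_pool,
        "n_clusters": len(clusters),
    }


def de_rate_roundtrip(
    protocol: str,
    seed: int,
    n_molecules: int = 100000,
    n_transcripts: int = 60,
) -> dict:
    """Protocol DE rates in, measured read fractions out.

    Background-only simulation at the protocol's conversion/deletion
    probabilities with the sequencing-error channel off, so the measured
    fractions isolate the protocol-event machinery; returns the measured
    fractions, the configured probabilities and the unique-read count.
    """
    from .process import count_de_read_fractions

    reference = sim.generate_reference(n_transcripts, seed=seed)
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    config = sim.config_for(protocol, seed=seed, n_background=n_molecules,
                            seq_error_rate=0.0)
    raw_reads, _ = sim.simulate_clip_reads(reference, truth, config)
    processed = process_reads(raw_reads)
    fractions = count_de_read_fractions(processed, ["T-to-C", "T-del"])
    return {
        "fractions": fractions,
        "configured": {"T-to-C": config.p_t2c, "T-del": config.p_tdel},
        "n_reads": len(processed),
    }


def positional_null_pvalues(
    n_runs: int,
    seed: int,
    n_shuffles: int = 200,
    n_transcripts: int = 25,
    n_background: int = 12000,
    query_size: int = 20,
) -> pd.DataFrame:
    """Empirical positional p-values under offset-free null simulations.

    Each run simulates fresh signal-free data and a fresh query pool, so
    the query's chance seed matches are exchangeable with the decoys';
    the returned p-values should be uniform and effect sizes near 1.
    """
    rows = []
    for i in range(n_runs):
        run_seed = seed + 37 * (i + 1)
        ns = run_null_study(run_seed, n_transcripts=n_transcripts,
                            n_background=n_background, tile_width=50)
        mirnas = sim.generate_mirna_pool(query_size, seed=run_seed + 7)
        tiles = tile_windows(ns["reference"].lengths(), width=50)
        stats = positional_preference_stats(
            tiles, ns["sequences"], ns["track"], mirnas,
            n_shuffles=n_shuffles, seed=run_seed, min_windows=30)
        s = stats["T-to-C"]
        rows.append({"run": i, "p_distance": s.p_distance,
                     "effect_size": s.effect_size,
                     "n_windows": s.n_windows})
    return pd.DataFrame(rows)
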