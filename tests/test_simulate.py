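"""Synthetic-data generator: determinism, planted truth, protocol rates."""

import os

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import clipseed as cs
from clipseed import samio
from clipseed.errors import ConfigurationError, PlantingError
from clipseed.simulate import TRUTH_COLUMNS


class TestGenerateReference:
    def test_fixed_seed_is_deterministic(self):
        a = cs.generate_reference(10, seed=1)
        b = cs.generate_reference(10, seed=1)
        assert a.sequences() == b.sequences()
        assert [t.expression for t in a.transcripts] == \
            [t.expression for t in b.transcripts]

    def test_regions_tile_the_transcript(self):
        ref = cs.generate_reference(5, seed=2)
        for t in ref.transcripts:
            assert t.utr5[0] == 0
            assert t.utr5[1] == t.cds[0]
            assert t.cds[1] == t.utr3[0]
            assert t.utr3[1] == len(t.sequence)
            assert t.utr3[1] - t.utr3[0] >= 60

    def test_degenerate_composition_all_A(self):
        ref = cs.generate_reference(
            3, seed=1, utr3_composition={"A": 1.0})
        for t in ref.transcripts:
            s, e = t.utr3
            assert set(t.sequence[s:e]) == {"A"}

    def test_au_fraction_default(self):
        ref = cs.generate_reference(20, seed=3)
        utr3 = "".join(t.sequence[t.utr3[0]:t.utr3[1]]
                       for t in ref.transcripts)
        au = sum(b in "AT" for b in utr3) / len(utr3)
        assert au == pytest.approx(0.6, abs=0.02)

    def test_zero_transcripts_is_an_error(self):
        with pytest.raises(ConfigurationError):
            cs.generate_reference(0)

    def test_bad_composition_is_an_error(self):
        with pytest.raises(ConfigurationError):
            cs.generate_reference(2, utr3_composition={"A": 0.5, "C": 0.2})


class TestMiRNAPool:
    def test_distinct_seed_heptamers_and_determinism(self):
        a = cs.generate_mirna_pool(30, seed=1)
        b = cs.generate_mirna_pool(30, seed=1)
        assert [m.sequence for m in a] == [m.sequence for m in b]
        assert len({m.sequence[1:8] for m in a}) == 30

    def test_equal_means_degenerate_mixture_is_fine(self):
        pool = cs.generate_mirna_pool(20, seed=2, log10_means=(1.0, 1.0))
        x = np.log10([m.expression_rpm for m in pool])
        assert x.std() < 1.0  # unimodal spread

    def test_too_small_pool_is_an_error(self):
        with pytest.raises(ConfigurationError):
            cs.generate_mirna_pool(1)


class TestPlantTargetSites:
    def test_density_zero_leaves_reference_unchanged(self):
        ref = cs.generate_reference(5, seed=1)
        mirnas = cs.generate_mirna_pool(5, seed=1)
        out, truth = cs.plant_target_sites(ref, mirnas, density_per_kb=0.0)
        assert truth.empty
        assert out.sequences() == ref.sequences()

    def test_requested_count_is_planted(self):
        ref = cs.generate_reference(50, seed=1)
        mirnas = cs.generate_mirna_pool(10, seed=1)
        _, truth = cs.plant_target_sites(ref, mirnas, n_sites=120, seed=1)
        assert len(truth) == 120
        assert list(truth.columns) == TRUTH_COLUMNS

    def test_every_record_validates_against_the_seed_matcher(self, study):
        """Planted sites are re-detected with their recorded type, and the
        site interval lies inside the 3'UTR."""
        seqs = study["sequences"]
        mirnas = {m.id: m for m in study["mirnas"]}
        for row in study["truth"].itertuples():
            tx = study["reference"].get(row.transcript_id)
            assert tx.utr3[0] <= row.start < row.end <= tx.utr3[1]
            matches = [
                m for m in cs.find_seed_matches(
                    seqs[row.transcript_id], mirnas[row.mirna_id].sequence,
                    row.mirna_id)
                if m.start == row.start
            ]
            assert len(matches) == 1
            assert matches[0].seed_type == row.seed_type
            assert matches[0].end == row.end
            # the planted crosslink is a T
            assert seqs[row.transcript_id][row.crosslink] == "T"

    def test_overcrowded_utrs_raise_planting_error(self):
        ref = cs.generate_reference(2, seed=1, utr3_length=(90, 95))
        mirnas = cs.generate_mirna_pool(5, seed=1)
        with pytest.raises(PlantingError):
            cs.plant_target_sites(ref, mirnas, n_sites=60, seed=1)


class TestSimulateClipReads:
    def test_same_seed_gives_identical_sam_bytes(self, tmp_path):
        ref = cs.generate_reference(10, seed=4)
        mirnas = cs.generate_mirna_pool(5, seed=4)
        ref, truth = cs.plant_target_sites(ref, mirnas, n_sites=20, seed=4)
        paths = []
        for i in (1, 2):
            reads, _ = cs.simulate_clip_reads(ref, truth,
                                              cs.par_config(seed=4))
            p = tmp_path / f"r{i}.sam"
            samio.write_sam(reads, ref.lengths(), str(p))
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_par_conversion_fraction_in_reported_range(self):
        """Most filtered unique PAR reads carry a T-to-C conversion."""
        ref = cs.generate_reference(30, seed=5)
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        cfg = cs.par_config(seed=5, n_background=10000)
        reads, _ = cs.simulate_clip_reads(ref, truth, cfg)
        fr = cs.count_de_read_fractions(cs.process_reads(reads), ["T-to-C"])
        assert 0.75 <= fr["T-to-C"] <= 0.90

    def test_hits_rates_at_moderate_depth(self):
        ref = cs.generate_reference(30, seed=6)
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
        cfg = cs.hits_config(seed=6, n_background=20000, seq_error_rate=0.0)
        reads, _ = cs.simulate_clip_reads(ref, truth, cfg)
        fr = cs.count_de_read_fractions(cs.process_reads(reads),
                                        ["T-to-C", "T-del"])
        assert fr["T-to-C"] == pytest.approx(0.016, rel=0.30)
        assert fr["T-del"] == pytest.approx(0.0083, rel=0.30)

    def test_background_only_without_count_is_an_error(self):
        ref = cs.generate_reference(3, seed=1)
        with pytest.raises(ConfigurationError):
            cs.simulate_clip_reads(ref, pd.DataFrame(columns=TRUTH_COLUMNS),
                                   cs.par_config(seed=1))

    def test_sam_round_trip_is_lossless(self, study, tmp_path):
        subset = study["raw_reads"][:800]
        p = tmp_path / "x.sam"
        samio.write_sam(subset, study["reference"].lengths(), str(p))
        back = samio.read_sam(str(p))
        assert len(back) == len(subset)
        for a, b in zip(subset, back):
            for f in ("name", "umi", "reference", "start", "end", "strand",
                      "blocks", "sequence", "mismatches", "deletions",
                      "copy_number"):
                assert getattr(a, f) == getattr(b, f), f

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            cs.SimulationConfig(p_t2c=1.5)
        with pytest.raises(ConfigurationError):
            cs.SimulationConfig(read_length=(10, 30))
        with pytest.raises(ConfigurationError):
            cs.SimulationConfig(offset_dist={-1: 0.5})


class TestSmallRNASeq:
    def _pool(self, ratios):
        seq = "UGAGGUAGUAGGUUGUAUAG"
        bases = "ACGU"
        out = []
        for i, r in enumerate(ratios):
            s = seq[:-1] + bases[i % 4]
            out.append(cs.MiRNA(f"m{i}", s, expression_rpm=r))
        return out

    def test_unbiased_counts_follow_expression(self):
        pool = self._pool([3.0, 1.0])
        counts = cs.simulate_smrnaseq(pool, library_size=10 ** 6, seed=1)
        ratio = counts["count"][0] / counts["count"][1]
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_ligation_bias_degrades_rank_agreement(self):
        pool = cs.generate_mirna_pool(40, seed=7)
        expr = np.array([m.expression_rpm for m in pool])
        none = cs.simulate_smrnaseq(pool, bias="none", seed=3)
        biased = cs.simulate_smrnaseq(pool, bias="ligation", sigma=1.5,
                                      seed=3)
        rho_none = stats.spearmanr(expr, none["count"]).statistic
        rho_bias = stats.spearmanr(expr, biased["count"]).statistic
        assert rho_bias < rho_none

    def test_sigma_zero_equals_unbiased(self):
        pool = self._pool([5.0, 2.0, 1.0])
        a = cs.simulate_smrnaseq(pool, bias="none", seed=2)
        b = cs.simulate_smrnaseq(pool, bias="ligation", sigma=0.0, seed=2)
        assert a.equals(b)

    def test_small_library_is_an_error(self):
        with pytest.raises(ConfigurationError):
            cs.simulate_smrnaseq(self._pool([1, 1]), library_size=10)


class TestKnockdown:
    TRUTH = pd.DataFrame({
        "site_id": [0, 1, 2],
        "transcript_id": ["g1", "g1", "g2"],
        "start": [0, 40, 0], "end": [8, 48, 8],
        "mirna_id": ["m", "m", "m"],
        "seed_type": ["8mer-A1", "8mer-A1", "6mer"],
        "offset": [-1, -1, -1], "crosslink": [0, 39, 0],
    })

    def test_additive_expected_effects(self):
        eff = {"8mer-A1": 0.3, "7mer-m8": 0.2, "7mer-A1": 0.15, "6mer": 0.1}
        _, expected = cs.simulate_knockdown(
            ["g1", "g2", "g3"], self.TRUTH, effects=eff, seed=1)
        assert expected.loc["g1", "expected_rna_log2fc"] == \
            pytest.approx(0.6)
        assert expected.loc["g2", "expected_rna_log2fc"] == \
            pytest.approx(0.1)
        assert expected.loc["g3", "expected_rna_log2fc"] == 0.0

    def test_tables_have_requested_shape(self):
        tables, _ = cs.simulate_knockdown(["g1", "g2"], self.TRUTH,
                                          replicates=3, seed=1)
        for mod in ("rna", "ribo"):
            for cond in ("control", "depleted"):
                assert tables[mod][cond].shape == (2, 3)

    def test_single_replicate_is_an_error(self):
        with pytest.raises(ConfigurationError):
            cs.simulate_knockdown(["g1"], self.TRUTH, replicates=1)

    def test_realised_fold_change_tracks_expectation(self):
        genes = [f"g{i}" for i in range(300)]
        rows = []
        for i in range(100):  # g0..g99 carry two strong sites each
            for j in range(2):
                rows.append({"site_id": 2 * i + j,
                             "transcript_id": f"g{i}",
                             "start": 50 * j, "end": 50 * j + 8,
                             "mirna_id": "m", "seed_type": "8mer-A1",
                             "offset": -1, "crosslink": 50 * j})
        truth = pd.DataFrame(rows)
        tables, expected = cs.simulate_knockdown(
            genes, truth, replicates=4, dispersion=0.05, seed=2,
            te_fraction=0.0)
        fc = cs.log2_fold_changes(
            tables["rna"]["control"], tables["rna"]["depleted"],
            tables["ribo"]["control"], tables["ribo"]["depleted"])
        target = fc.loc[[f"g{i}" for i in range(100)], "rna_log2fc"].mean()
        rest = fc.loc[[f"g{i}" for i in range(100, 300)],
                      "rna_log2fc"].mean()
        assert target - rest == pytest.approx(0.7, abs=0.15)
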