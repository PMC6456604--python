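"""Seed matching, bulge sites, offset model and miRNA assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import clipseed as cs
from clipseed.de import Cluster, smooth_de_signal
from clipseed.errors import ConfigurationError
from clipseed.seeds import (
    CANONICAL_TYPES,
    OffsetModel,
    SeedMatch,
    seed_family,
    seed_site_core,
)

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"

_PAIRS = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}


def _pairs(mirna_base: str, target_base: str) -> bool:
    return (mirna_base, target_base) in _PAIRS


def brute_force_matches(target: str, mirna: str) -> list[tuple[int, str]]:
    """Independent sliding-window complementarity scan (oracle).

    Checks the canonical definitions literally at every target position:
    positions 2..k of the miRNA pair the target antiparallel, plus the A1
    anchor where required; reports the most specific type per core locus.
    """
    out = []
    for p in range(len(target) - 5):
        # core: miRNA position k (2..7) pairs target[p + 7 - k], i.e. the
        # core occupies [p, p+6) with the duplex antiparallel
        core_ok = all(
            _pairs(mirna[k - 1], target[p + 7 - k]) for k in range(2, 8)
        )
        if not core_ok:
            continue
        m8 = p > 0 and _pairs(mirna[7], target[p - 1])
        a1 = p + 6 < len(target) and target[p + 6] == "A"
        if m8 and a1:
            out.append((p - 1, "8mer-A1"))
        elif m8:
            out.append((p - 1, "7mer-m8"))
        elif a1:
            out.append((p, "7mer-A1"))
        else:
            out.append((p, "6mer"))
    return out


class TestFindSeedMatches:
    @pytest.mark.parametrize(
        "target, expected_type, expected_span",
        [
            ("GGCTACCTCAGG", "8mer-A1", (2, 10)),
            ("GGCTACCTCGGG", "7mer-m8", (2, 9)),
            ("GGTACCTCAGGG", "7mer-A1", (2, 9)),
            ("GGTACCTCGGGG", "6mer", (2, 8)),
        ],
    )
    def test_let7_canonical_types(self, target, expected_type, expected_span):
        matches = cs.find_seed_matches(target, LET7, "let-7")
        assert len(matches) == 1
        m = matches[0]
        assert (m.seed_type, (m.start, m.end)) == (expected_type, expected_span)

    def test_no_complementarity(self):
        assert cs.find_seed_matches("G" * 40, LET7) == []

    def test_allowed_types_filters_after_classification(self):
        # an 8mer locus is not reported as a weaker type
        assert cs.find_seed_matches(
            "GGCTACCTCAGG", LET7, allowed_types=("7mer-m8",)) == []

    def test_invalid_alphabet(self):
        with pytest.raises(ConfigurationError):
            cs.find_seed_matches("ACGU", LET7)
        with pytest.raises(ConfigurationError):
            cs.find_seed_matches("ACGT", "ACGTACGTACGTACGTACGTAC")

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(300):
            target = "".join(rng.choice(list("ACGT"), size=60))
            mirna = "".join(rng.choice(list("ACGU"), size=22))
            got = sorted((m.start, m.seed_type)
                         for m in cs.find_seed_matches(target, mirna))
            assert got == sorted(brute_force_matches(target, mirna))


class TestBulgeSites:
    def test_constructed_bulge_from_canonical(self):
        # 7mer-m8 site CTACCTC; insert the pivot-pairing base between the
        # positions pairing miRNA 5 and 6 (pivot = position 6 -> 'A')
        target = "GG" + "CTA" + "A" + "CCTC" + "GG"
        matches = cs.find_bulge_sites(target, LET7, "let-7")
        assert [(m.start, m.end, m.seed_type) for m in matches] == \
            [(2, 10, "bulge")]

    def test_canonical_site_is_not_a_bulge(self):
        assert cs.find_bulge_sites("GGCTACCTCAGG", LET7) == []

    def test_empty_sequence(self):
        assert cs.find_bulge_sites("", LET7) == []

    def test_pivot_constraint_toggle(self):
        target = "GG" + "CTA" + "G" + "CCTC" + "GG"  # bulged G cannot pair pivot
        assert cs.find_bulge_sites(target, LET7) == []
        relaxed = cs.find_bulge_sites(target, LET7,
                                      require_pivot_pairing=False)
        assert len(relaxed) == 1


def _toy_cluster(de_positions, start=100, end=140, coverage_value=10):
    n = end - start
    de = np.zeros(n)
    for p, w in de_positions.items():
        de[p - start] = w
    c = Cluster(
        id=("tx", "+", start, end), reference="tx", strand="+",
        start=start, end=end, rank=1, read_count=coverage_value,
        de_counts=de, coverage=np.full(n, coverage_value),
    )
    return smooth_de_signal(c)


class TestOffsetModel:
    def _clusters_and_seq(self, offsets, mirna):
        # one cluster per offset, each with exactly one 7mer-m8 site
        core = seed_site_core(mirna.sequence)
        m8_flank = {"A": "T", "U": "A", "G": "C", "C": "G"}[mirna.sequence[7]]
        site = m8_flank + core
        s = list("G" * (120 * len(offsets)))
        clusters = []
        for i, o in enumerate(offsets):
            site_start = 120 * i + 60
            s[site_start : site_start + len(site)] = list(site)
            clusters.append(
                _toy_cluster({site_start + o: 5}, start=site_start - 20,
                             end=site_start + 20)
            )
        return clusters, {"tx": "".join(s)}

    def test_concentrated_offsets_floor_variance(self):
        m = cs.MiRNA("m1", "UGAGGUAGUAGGUUGUAUAGUU")
        clusters, seqs = self._clusters_and_seq([-1] * 35, m)
        model = cs.learn_offset_model(clusters, seqs, [m], min_clusters=30)
        assert model.mean == pytest.approx(-1.0)
        assert model.variance == pytest.approx(0.25)  # floored
        assert not model.is_fallback

    def test_symmetric_offsets_mean(self):
        m = cs.MiRNA("m1", "UGAGGUAGUAGGUUGUAUAGUU")
        clusters, seqs = self._clusters_and_seq([-2, -1, 0] * 12, m)
        model = cs.learn_offset_model(clusters, seqs, [m], min_clusters=30)
        assert model.mean == pytest.approx(-1.0)

    def test_fallback_below_minimum(self):
        m = cs.MiRNA("m1", "UGAGGUAGUAGGUUGUAUAGUU")
        clusters, seqs = self._clusters_and_seq([-1] * 10, m)
        with pytest.warns(UserWarning, match="falling back"):
            model = cs.learn_offset_model(clusters, seqs, [m],
                                          min_clusters=30)
        assert model.is_fallback
        assert (model.mean, model.variance) == (-1.0, 4.0)


class TestAssignment:
    MIRNA = cs.MiRNA("m1", "UGAGGUAGUAGGUUGUAUAGUU")
    OTHER = cs.MiRNA("m2", "UAUCACAGCCAGCUUUGAUGAGC")
    MODEL = OffsetModel(mean=-1.0, variance=1.0, n_training=100)

    def _seq_with_site(self, site_start, site, length=400):
        s = list("G" * length)
        s[site_start:site_start + len(site)] = list(site)
        return "".join(s)

    def test_unique_candidate_assigned(self):
        site = seed_site_core(self.MIRNA.sequence)
        seqs = {"tx": self._seq_with_site(200, site)}
        cluster = _toy_cluster({199: 5}, start=180, end=220)
        pred = cs.assign_mirna(cluster, [self.MIRNA, self.OTHER], seqs,
                               self.MODEL, variance=0.5)
        assert pred is not None and pred.mirna_id == "m1"
        assert pred.match.start == 200

    def test_nearer_of_two_candidates_wins(self):
        site = seed_site_core(self.MIRNA.sequence)
        other_site = seed_site_core(self.OTHER.sequence)
        seq = list("G" * 400)
        seq[200:206] = site
        seq[215:221] = other_site  # 15 nt away from the DE mass
        seqs = {"tx": "".join(seq)}
        cluster = _toy_cluster({199: 5}, start=180, end=226)
        pred = cs.assign_mirna(cluster, [self.MIRNA, self.OTHER], seqs,
                               self.MODEL, variance=0.5)
        assert pred.mirna_id == "m1"

    def test_no_candidate_returns_none(self):
        seqs = {"tx": "G" * 400}
        cluster = _toy_cluster({200: 5}, start=180, end=220)
        assert cs.assign_mirna(cluster, [self.MIRNA], seqs, self.MODEL) is None

    def test_score_invariant_under_translation(self):
        site = seed_site_core(self.MIRNA.sequence)
        preds = []
        for shift in (0, 57):
            seqs = {"tx": self._seq_with_site(200 + shift, site)}
            cluster = _toy_cluster({199 + shift: 5}, start=180 + shift,
                                   end=220 + shift)
            preds.append(cs.assign_mirna(cluster, [self.MIRNA], seqs,
                                         self.MODEL, variance=0.5))
        assert preds[0].score == pytest.approx(preds[1].score, abs=1e-12)

    def test_summit_anchor_mode(self):
        site = seed_site_core(self.MIRNA.sequence)
        seqs = {"tx": self._seq_with_site(200, site)}
        cluster = _toy_cluster({199: 5}, start=180, end=220)
        pred = cs.assign_mirna(cluster, [self.MIRNA], seqs, self.MODEL,
                               variance=0.5, anchor="summit")
        # coverage is flat -> summit at the left edge, far from the site
        assert pred is None or pred.score < 0.5


class TestCollapseAndReproducibility:
    M1 = cs.MiRNA("mA", "UGAGGUAGUAGGUUGUAUAGUU")
    M2 = cs.MiRNA("mB", "UGAGGUAGUGGGUUGUAUAGUU")  # same positions 2-8
    M3 = cs.MiRNA("mC", "UAUCACAGCCAGCUUUGAUGAGC")

    def _pred(self, cluster_id, mirna_id, start, score=1.0):
        return cs.SeedPrediction(
            cluster_id=cluster_id, mirna_id=mirna_id,
            match=SeedMatch(start, start + 7, mirna_id, "7mer-m8"),
            score=score, variance=0.5,
        )

    def test_family_representative(self):
        fam = seed_family([self.M1, self.M2, self.M3])
        assert fam["mA"] == fam["mB"] == "mA"
        assert fam["mC"] == "mC"

    def test_same_site_two_isoforms_merges(self):
        preds = [self._pred(("iso1", "+", 0, 40), "mA", 10),
                 self._pred(("iso2", "+", 0, 40), "mA", 10)]
        iso = {"iso1": "gene1", "iso2": "gene1"}
        merged = cs.collapse_predictions(preds, [self.M1, self.M3], iso)
        assert len(merged) == 1

    def test_family_members_merge_to_representative(self):
        preds = [self._pred(("tx", "+", 0, 40), "mB", 10, score=2.0),
                 self._pred(("tx", "+", 0, 40), "mA", 10, score=1.0)]
        merged = cs.collapse_predictions(preds, [self.M1, self.M2])
        assert len(merged) == 1
        assert merged[0].mirna_id == "mA"
        assert merged[0].score == 2.0

    def test_distinct_sites_unchanged(self):
        preds = [self._pred(("tx", "+", 0, 40), "mA", 10),
                 self._pred(("tx", "+", 50, 90), "mC", 60)]
        assert len(cs.collapse_predictions(preds, [self.M1, self.M3])) == 2

    def test_reproducible_identity_disjoint_shared(self):
        mirnas = [self.M1, self.M3]
        a = [self._pred(("tx", "+", 0, 40), "mA", 10),
             self._pred(("tx", "+", 50, 90), "mC", 60),
             self._pred(("tx", "+", 100, 140), "mA", 110)]
        assert len(cs.reproducible_predictions(a, a, mirnas)) == 3
        assert cs.reproducible_predictions(a, [], mirnas) == []
        b = [self._pred(("tx", "+", 50, 90), "mC", 60)]
        shared = cs.reproducible_predictions(a, b, mirnas)
        assert len(shared) == 1 and shared[0].mirna_id == "mC"


class TestMonotoneStringency:
    def test_prediction_count_never_increases_as_variance_decreases(
            self, study):
        counts = []
        for v in (1.5, 1.0, 0.75, 0.5, 0.25, 0.2, 0.15, 0.1, 0.01, 0.005):
            preds = cs.assign_all(
                study["clusters"][:150], study["mirnas"],
                study["sequences"], study["model"], variance=v)
            counts.append(len(preds))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
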