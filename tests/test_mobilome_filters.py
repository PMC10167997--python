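import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from httflow.core_io import HitRecord
from httflow.mobilome_filters import (
    SaturatedDistanceError,
    TECopySet,
    build_consensus,
    build_landscape,
    filter_hits,
    greedy_cluster,
    k2p_distance,
)


def _hit(q, bitscore, length, subject="s"):
    return HitRecord(q, subject, bitscore, length, 90.0, 1, length)


class TestFilterHits:
    def test_thresholds_are_inclusive(self):
        kept = filter_hits([_hit("q", 160.0, 130)])
        assert len(kept) == 1

    def test_below_either_threshold_rejected(self):
        assert filter_hits([_hit("q", 159.9, 500)]) == []
        assert filter_hits([_hit("q", 500.0, 129)]) == []

    def test_brute_force_agreement_on_synthetic_hits(self):
        rng = np.random.default_rng(0)
        hits = [
            _hit(f"q{i}", float(rng.integers(100, 250)), int(rng.integers(50, 300)))
            for i in range(10)
        ]
        kept = filter_hits(hits)
        expected = {
            h.query for h in hits if h.bitscore >= 160 and h.length >= 130
        }
        assert {h.query for h in kept} == expected
        assert set(kept) <= set(hits)

    def test_best_hit_per_query_deterministic_ties(self):
        hits = [
            _hit("q", 200.0, 150, subject="zzz"),
            _hit("q", 200.0, 150, subject="aaa"),  # tie -> lexicographic
            _hit("q", 200.0, 200, subject="mid"),  # longer wins first
        ]
        kept = filter_hits(hits)
        assert len(kept) == 1 and kept[0].subject == "mid"
        kept2 = filter_hits(hits[:2])
        assert kept2[0].subject == "aaa"

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        hits = [
            _hit(f"q{i % 4}", float(rng.integers(150, 260)), int(rng.integers(100, 300)),
                 subject=f"s{i}")
            for i in range(12)
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert filter_hits(list(reversed(hits))) == once

    def test_empty_input(self):
        assert filter_hits([]) == []


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        assert len(greedy_cluster(["ACGT" * 30] * 2)) == 1

    def test_threshold_straddles_96pct_pair(self):
        a = "ACGT" * 25  # 100 bp
        b = a[:10] + "TGCA"[:1] + a[11:]  # engineer exactly 4 mismatches
        b = list(a)
        for pos in (10, 30, 50, 70):
            b[pos] = "A" if a[pos] != "A" else "C"
        b = "".join(b)
        assert sum(x != y for x, y in zip(a, b)) == 4  # 96% identity
        assert len(greedy_cluster([a, b], id_threshold=0.95)) == 1
        assert len(greedy_cluster([a, b], id_threshold=0.97)) == 2

    def test_dissimilar_sequences_stay_singletons(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(5)]
        from httflow.mobilome_filters import _global_identity

        for i in range(5):
            for j in range(i + 1, 5):
                assert _global_identity(seqs[i], seqs[j]) < 0.5
        assert len(greedy_cluster(seqs, id_threshold=0.9)) == 5

    def test_every_sequence_in_exactly_one_cluster(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(10)]
        clusters = greedy_cluster(seqs, id_threshold=0.8)
        members = sorted(i for c in clusters for i in c)
        assert members == list(range(10))

    def test_empty_input(self):
        assert greedy_cluster([]) == []


class TestK2P:
    def test_identical_is_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_value(self):
        # 100 sites: 10 transitions (P=0.1), 5 transversions (Q=0.05)
        a = ["A"] * 100
        b = ["A"] * 100
        for i in range(10):
            b[i] = "G"  # transition
        for i in range(10, 15):
            b[i] = "C"  # transversion
        d = k2p_distance("".join(a), "".join(b))
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.17018, abs=1e-4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 60))
        try:
            d1 = k2p_distance(a, b)
        except SaturatedDistanceError:
            with pytest.raises(SaturatedDistanceError):
                k2p_distance(b, a)
            return
        assert d1 == pytest.approx(k2p_distance(b, a), abs=1e-12)

    def test_gapped_sites_excluded(self):
        assert k2p_distance("ACG-", "ACGT") == 0.0

    def test_all_gap_pair_undefined(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_distance("----", "ACGT")


class TestConsensus:
    def test_single_copy_is_itself(self):
        cs = TECopySet("Gypsy", "LTR", [("A", "ACGTAC")])
        assert build_consensus(cs) == "ACGTAC"

    def test_majority_and_tie_rule(self):
        cs = TECopySet(
            "Gypsy", "LTR",
            [("A", "AAG"), ("B", "AAG"), ("C", "GAG")],
        )
        assert build_consensus(cs) == "AAG"
        tie = TECopySet("Gypsy", "LTR", [("A", "A"), ("B", "G")])
        assert build_consensus(tie) == "A"  # tie broken A<C<G<T

    def test_majority_gap_columns_dropped(self):
        cs = TECopySet(
            "Gypsy", "LTR",
            [("A", "A-CG"), ("B", "A-CG"), ("C", "AACG")],
        )
        assert build_consensus(cs) == "ACG"


class TestLandscape:
    def test_identical_copies_all_mass_in_first_bin(self):
        cs = TECopySet("Gypsy", "LTR", [("A", "ACGT" * 50)] * 3)
        bins = build_landscape([cs], bin_width=0.01)
        assert bins[0].frequencies["Gypsy"] == pytest.approx(1.0)

    def test_frequencies_sum_to_one_per_superfamily(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), 400))
        copies = []
        for i in range(6):
            seq = list(base)
            for pos in rng.integers(0, 400, size=10 * (i + 1)):
                seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
            copies.append((f"c{i}", "".join(seq)))
        cs = TECopySet("Mariner", "TIR", copies, consensus=base)
        bins = build_landscape([cs])
        total = sum(b.frequencies.get("Mariner", 0.0) for b in bins)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_simulated_ten_percent_divergence_modal_bin(self):
        # ~10% K2P: mutate 10% of sites of each copy independently
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 2000))
        copies = []
        for i in range(20):
            seq = list(base)
            for pos in rng.choice(2000, size=200, replace=False):
                seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            copies.append((f"c{i}", "".join(seq)))
        cs = TECopySet("Gypsy", "LTR", copies, consensus=base)
        bins = build_landscape([cs], bin_width=0.01)
        modal = max(bins, key=lambda b: b.frequencies.get("Gypsy", 0.0))
        assert 0.08 <= modal.lower <= 0.12

    def test_burst_mode_below_bimodal_second_mode(self):
        # L-shaped (recent burst) vs bimodal landscape: the burst's modal
        # divergence must sit below the bimodal pattern's older mode
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), 1500))

        def copies_at(frac, n):
            out = []
            for i in range(n):
                seq = list(base)
                k = int(frac * 1500)
                for pos in rng.choice(1500, size=k, replace=False):
                    seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
                out.append((f"c{frac}_{i}", "".join(seq)))
            return out

        burst = TECopySet("Young", "LTR", copies_at(0.02, 15), consensus=base)
        bimodal = TECopySet(
            "Old", "TIR", copies_at(0.02, 5) + copies_at(0.25, 10), consensus=base
        )
        bins = build_landscape([burst, bimodal], bin_width=0.02)
        modal_burst = max(bins, key=lambda b: b.frequencies.get("Young", 0))
        old_mode = max(
            (b for b in bins if b.lower >= 0.1),
            key=lambda b: b.frequencies.get("Old", 0),
        )
        assert modal_burst.lower < old_mode.lower
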