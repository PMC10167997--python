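import numpy as np
import pytest

from httflow.core_io import SpeciesTree
from httflow.divergence_stats import compute_ds
from httflow.eco_drivers import niche_breadth, schoener_d
from httflow.synthetic_data import (
    SimConfig,
    TEFamilySpec,
    TransferSpec,
    evolve_genes,
    evolve_te_family,
    inject_htt,
    make_cl133_fixture,
    make_ecology,
    simulate_dataset,
)


class TestEvolveGenes:
    def test_zero_rate_identical_sequences(self, two_species_tree):
        cfg = SimConfig(
            tree=two_species_tree, seed=1, rate=0.0, n_genes=2, n_codons=60
        )
        for gene in evolve_genes(cfg).genes:
            assert gene.sequences["A"] == gene.sequences["B"]
            assert compute_ds(gene, "A", "B") == 0.0

    def test_expected_ds_recovered(self, two_species_tree):
        # split at 15 Myr, r = 0.02 -> expected dS = 0.6
        estimates = []
        for rep in range(50):
            cfg = SimConfig(
                tree=two_species_tree, seed=60_000 + rep, rate=0.02,
                n_genes=1, n_codons=300,
            )
            estimates.append(compute_ds(evolve_genes(cfg).genes[0], "A", "B"))
        assert np.mean(estimates) == pytest.approx(0.6, rel=0.2)

    def test_seed_determinism(self, two_species_tree):
        cfg = SimConfig(tree=two_species_tree, seed=5, rate=0.02, n_genes=3,
                        n_codons=90)
        r1 = evolve_genes(cfg)
        r2 = evolve_genes(cfg)
        assert all(
            a.sequences == b.sequences for a, b in zip(r1.genes, r2.genes)
        )

    def test_amino_acid_sequence_frozen(self, two_species_tree):
        from Bio.Seq import Seq

        cfg = SimConfig(tree=two_species_tree, seed=8, rate=0.05, n_genes=1,
                        n_codons=100)
        gene = evolve_genes(cfg).genes[0]
        aa = {
            sp: str(Seq(seq).translate()) for sp, seq in gene.sequences.items()
        }
        assert aa["A"] == aa["B"]

    def test_branch_rate_override(self, two_species_tree):
        cfg = SimConfig(
            tree=two_species_tree, seed=9, rate=0.0, n_genes=1, n_codons=300,
            branch_rates={frozenset({"A"}): 0.05},
        )
        gene = evolve_genes(cfg).genes[0]
        # only A's branch evolves
        assert gene.sequences["A"] != gene.sequences["B"]


class TestInjectHtt:
    def test_transfer_now_gives_identical_copies(self, two_species_tree):
        cfg = SimConfig(tree=two_species_tree, seed=11, rate=0.02, n_genes=1,
                        n_codons=150)
        fam = inject_htt(cfg, "f", "A", "B", 0.0)
        assert fam.sequences["A"] == fam.sequences["B"]

    def test_transfer_age_sets_pair_divergence(self, two_species_tree):
        estimates = []
        for rep in range(30):
            cfg = SimConfig(
                tree=two_species_tree, seed=70_000 + rep, rate=0.02,
                n_genes=1, n_codons=300,
            )
            fam = inject_htt(cfg, "f", "A", "B", 5.0)
            estimates.append(compute_ds(fam, "A", "B"))
        assert np.mean(estimates) == pytest.approx(0.2, rel=0.25)

    def test_untransferred_pairs_keep_vertical_divergence(
        self, five_species_tree
    ):
        cfg = SimConfig(
            tree=five_species_tree, seed=12, rate=0.02, n_genes=1,
            n_codons=400,
        )
        rng = np.random.default_rng(12)
        fam = evolve_te_family(
            cfg,
            TEFamilySpec(name="f", transfer=TransferSpec("IC", "LT", 1.0)),
            rng,
        )
        # transferred pair is young...
        assert compute_ds(fam, "IC", "LT") < 0.15
        # ...but BM-IV still reflects the 8-Myr species divergence (~0.32)
        assert compute_ds(fam, "BM", "IV") > 0.15

    def test_invalid_transfer_time_rejected(self, two_species_tree):
        cfg = SimConfig(tree=two_species_tree, seed=13, rate=0.02, n_genes=1,
                        n_codons=60)
        with pytest.raises(ValueError, match="predates"):
            inject_htt(cfg, "f", "A", "B", 20.0)
        with pytest.raises(ValueError):
            inject_htt(cfg, "f", "A", "B", -1.0)


class TestEcology:
    def test_identical_niches_full_overlap(self):
        eco = make_ecology(
            ["a", "b"], seed=1,
            centers={"a": (0.0, 0.0), "b": (0.0, 0.0)},
            spreads={"a": 2.0, "b": 2.0},
        )
        assert schoener_d(eco.grids["a"], eco.grids["b"]) >= 0.98

    def test_distant_niches_no_overlap(self):
        eco = make_ecology(
            ["a", "b"], seed=2,
            centers={"a": (0.0, 0.0), "b": (20.0, 0.0)},  # 10 spreads apart
            spreads={"a": 2.0, "b": 2.0},
        )
        assert schoener_d(eco.grids["a"], eco.grids["b"]) <= 0.01

    def test_specialist_breadth_exact(self):
        eco = make_ecology(
            ["a", "b"], seed=3, flowers_used={"a": 1, "b": 12}
        )
        assert niche_breadth(eco.network, "a") == pytest.approx(1 / 12)
        assert niche_breadth(eco.network, "b") == pytest.approx(1.0)

    def test_minimum_point_count(self):
        eco = make_ecology(["a"], seed=4, n_points=5)
        assert (eco.occurrences.species == "a").sum() >= 20


class TestCl133Fixture:
    def test_pattern_is_deterministic(self):
        s1, _ = make_cl133_fixture()
        s2, _ = make_cl133_fixture()
        assert s1 == s2

    def test_significance_pattern(self):
        signals, tree = make_cl133_fixture()
        flags = {s.species_pair: s.significant for s in signals}
        assert flags[("BM", "IV")] and flags[("BD", "IV")]
        assert not flags[("BD", "BM")]
        ds = {s.species_pair: s.ds for s in signals}
        assert ds[("BD", "IV")] < ds[("BM", "IV")]
        assert tree.is_sister("BM", "BD")

    def test_roundtrip_through_signals_format(self):
        from httflow.htt_detection import signals_frame, signals_from_frame

        signals, _ = make_cl133_fixture()
        assert signals_from_frame(signals_frame(signals)) == signals


class TestEndToEnd:
    def test_full_synthetic_run_recovers_injected_events(
        self, five_species_tree
    ):
        """Detection -> events -> Muller on 20 vertical + 3 injected
        families recovers at least 2 of 3 transfers with the right pairs."""
        from httflow.core_io import RunConfig
        from httflow.htt_detection import run_detection
        from httflow.htt_events import build_events, count_events
        from httflow.potential_effects import build_alpha, muller_index

        transfers = [
            TransferSpec("IC", "LT", 1.0),
            TransferSpec("BM", "IV", 0.5),
            TransferSpec("BD", "LT", 2.0),
        ]
        te = [TEFamilySpec(name=f"vert{i:02d}") for i in range(20)] + [
            TEFamilySpec(name=f"htt{i}", transfer=tr)
            for i, tr in enumerate(transfers)
        ]
        cfg = SimConfig(
            tree=five_species_tree, seed=314, rate=0.02, n_genes=30,
            n_codons=300, te_families=te,
        )
        data = simulate_dataset(cfg)
        signals = run_detection(data.te_families, data.refs, RunConfig())
        events = build_events(signals, five_species_tree)
        recovered = {
            ev.family: ev.species for ev in events if ev.family.startswith("htt")
        }
        hits = 0
        for i, tr in enumerate(transfers):
            sp = recovered.get(f"htt{i}")
            if sp and {tr.donor, tr.acceptor} <= sp:
                hits += 1
        assert hits >= 2
        counts, _ = count_events(events)
        assert counts.sum() == pytest.approx(len(events))
        if events:
            alpha = build_alpha(events, resolution="family")
            m = muller_index(alpha)
            rows = m.table.dropna(how="all")
            sums = rows.sum(axis=1)
            finite = np.isfinite(rows.to_numpy()).all(axis=1)
            assert np.allclose(sums.to_numpy()[finite], 1.0, atol=1e-9)
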