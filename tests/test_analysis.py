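"""Fitness, fitness effects, DFE summaries, reduction, classification."""

import math

import numpy as np
import pytest

import evonet as ev
from evonet.analysis import (EventRecord, _clamped_pearson, classify_phenotype,
                             collect_dfe, dfe_summary, fitness, fitness_effect,
                             network_stats, reduce_network)
from evonet.netmodel import Edge, NodeKind


class TestFitness:
    def test_perfect_responder_scores_one(self, envs):
        nut = envs["XOR"].nutrient.astype(float)
        assert _clamped_pearson(nut, nut) == 1.0

    def test_constant_trace_scores_zero(self, envs):
        nut = envs["XOR"].nutrient.astype(float)
        assert _clamped_pearson(np.full_like(nut, 3.0), nut) == 0.0

    def test_anticorrelated_clamped_to_zero(self, envs):
        nut = envs["XOR"].nutrient.astype(float)
        assert _clamped_pearson(1.0 - nut, nut) == 0.0

    def test_silent_cell_scores_zero(self, envs, rng, warm_engine):
        from tests.test_expression import _bare_t0

        assert fitness(_bare_t0(), envs["XOR"], rng).w == 0.0

    def test_measurement_has_no_side_effects(self, envs, rng, warm_engine):
        cell = ev.build_reference_cell("A")
        before = ev.save_cell(cell)
        fitness(cell, envs["A"], rng, n_epochs=2)
        assert ev.save_cell(cell) == before

    def test_multi_epoch_averaging_reduces_spread(self, envs, warm_engine):
        """Averaging over 10 epochs tames the epoch-to-epoch variation."""
        rng = np.random.default_rng(3)
        cell = ev.build_reference_cell("A")
        single = np.array([fitness(cell, envs["A"], rng).w for _ in range(12)])
        avg10 = np.array([fitness(cell, envs["A"], rng, n_epochs=10).w
                          for _ in range(12)])
        assert single.std() > 2.0 * avg10.std()


class TestFitnessEffect:
    @pytest.mark.parametrize("before,after,expected", [
        (0.5, 0.5, 0.0),
        (0.5, 0.0, -1.0),
        (0.5, 0.6, pytest.approx(0.2)),
    ])
    def test_arithmetic(self, before, after, expected):
        assert fitness_effect(before, after) == expected

    def test_exclusion_floor(self):
        assert fitness_effect(0.005, 0.9) is None

    def test_domain_check(self):
        with pytest.raises(ValueError):
            fitness_effect(1.5, 0.2)

    def test_lethal_iff_after_zero(self):
        rec = EventRecord(0, 0, "weak", "x", w_before=0.4, w_after=0.0)
        assert rec.lethal and rec.effect == -1.0
        rec2 = EventRecord(0, 0, "weak", "x", w_before=0.4, w_after=0.01)
        assert not rec2.lethal


class TestDFESummary:
    def test_small_example(self):
        s = dfe_summary([-1.0, -1.0, 0.0, 0.1])
        assert s.lethal_fraction == 0.5
        assert s.n_viable == 2
        assert s.mean_effect == pytest.approx(0.05)

    def test_fraction_partition(self, rng):
        effects = np.concatenate([
            -np.ones(30), rng.uniform(-0.99, -0.81, 20), rng.uniform(-0.5, 1.0, 50)])
        s = dfe_summary(effects)
        lethal, viable = 30 / 100, s.n_viable / s.n_events
        intermediate = np.mean((effects > -1) & (effects <= -0.8))
        assert lethal + viable + intermediate == pytest.approx(1.0)

    def test_gaussian_reference(self, rng):
        s = dfe_summary(rng.normal(0.5, 0.1, 50_000))
        assert abs(s.skewness) < 0.05
        assert abs(s.kurtosis) < 0.1  # excess kurtosis convention

    def test_mirrored_sample_has_zero_skew(self, rng):
        x = rng.uniform(0, 0.5, 500)
        s = dfe_summary(np.concatenate([x, -x]))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)

    def test_moments_match_textbook_formulas(self, rng):
        x = rng.uniform(-0.5, 1.0, 400)
        s = dfe_summary(x)
        n = len(x)
        m = x.mean()
        m2 = np.mean((x - m) ** 2)
        m3 = np.mean((x - m) ** 3)
        m4 = np.mean((x - m) ** 4)
        g1 = m3 / m2 ** 1.5
        skew = math.sqrt(n * (n - 1)) / (n - 2) * g1
        kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * (m4 / m2 ** 2 - 3) + 6)
        assert s.variance == pytest.approx(x.var(ddof=1))
        assert s.skewness == pytest.approx(skew)
        assert s.kurtosis == pytest.approx(kurt)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dfe_summary([])


class TestCollectDFE:
    def test_rejects_bad_source(self, envs, rng):
        with pytest.raises(ValueError):
            collect_dfe([], envs["XOR"], "plasmid", 10, rng)
        with pytest.raises(ValueError, match="no events"):
            collect_dfe([], envs["XOR"], "mutation", 0, rng)

    def test_collects_requested_events(self, envs, rng, warm_engine):
        pop = ev.fixture_population("XOR", 8, rng, weight_jitter=0.3)
        s = collect_dfe(pop.cells, envs["XOR"], "mutation", 40, rng)
        assert s.n_events == 40
        assert s.effects.shape == (40,)
        assert np.all(s.effects >= -1.0)


class TestReduceNetwork:
    def test_zero_weight_edge_always_removed(self, envs, warm_engine):
        rng = np.random.default_rng(5)
        cell = ev.build_reference_cell("XOR")
        cell.add_edge(Edge((1, NodeKind.GENE_MRNA), (4, NodeKind.GENE_MRNA),
                           0.0, 5.0, 1.0))
        minimal = reduce_network(cell, envs["XOR"], rng, n_epochs=5)
        assert ((1, NodeKind.GENE_MRNA), (4, NodeKind.GENE_MRNA)) not in minimal.edges

    def test_reduction_only_removes(self, envs, warm_engine):
        rng = np.random.default_rng(5)
        cell = ev.build_reference_cell("XOR")
        minimal = reduce_network(cell, envs["XOR"], rng, n_epochs=5)
        assert set(minimal.edges) <= set(cell.edges)
        assert {t.id for t in minimal.triplets} <= {t.id for t in cell.triplets}

    def test_disconnected_triplet_dropped(self, envs, warm_engine):
        rng = np.random.default_rng(5)
        cell = ev.build_reference_cell("A")
        from evonet.netmodel import DEFAULT_INIT
        from evonet.mutation import create_triplet

        # an orphan triplet with no edges at all
        from evonet.netmodel import random_triplet

        cell.triplets.append(random_triplet(9, DEFAULT_INIT, rng))
        minimal = reduce_network(cell, envs["A"], rng, n_epochs=5)
        assert 9 not in {t.id for t in minimal.triplets}

    def test_zero_fitness_rejected(self, envs, rng, warm_engine):
        from tests.test_expression import _bare_t0

        with pytest.raises(ValueError, match="nothing to preserve"):
            reduce_network(_bare_t0(), envs["XOR"], rng, n_epochs=2)


class TestNetworkStats:
    def test_zero_edges_zero_sparsity(self, rng):
        from tests.test_expression import _bare_t0

        s = network_stats(_bare_t0())
        assert s == {"triplets": 1, "links": 0, "sparsity": 0.0}

    def test_fully_connected_toy_has_sparsity_one(self, rng):
        from tests.test_expression import _bare_t0

        cell = _bare_t0()
        refs = cell.node_refs()
        for src in list(refs) + ["S1", "S2"]:
            for tgt in refs:
                cell.add_edge(Edge(src, tgt, 1.0, 1.0, 1.0))
        s = network_stats(cell)
        assert s["sparsity"] == pytest.approx(1.0)

    def test_stats_survive_serialization(self, rng):
        cell = ev.sample_random_cell(rng=rng)
        reloaded = ev.load_cell(ev.save_cell(cell))
        assert network_stats(cell) == network_stats(reloaded)


class TestClassifyPhenotype:
    def test_reference_cells_classified(self, envs, warm_engine):
        rng = np.random.default_rng(2)
        for ph in ("A", "B", "XOR"):
            cell = ev.build_reference_cell(ph)
            assert classify_phenotype(cell, envs, rng, n_epochs=3) == ph

    def test_random_cells_mostly_unclassified(self, envs, warm_engine):
        rng = np.random.default_rng(2)
        labels = [classify_phenotype(ev.sample_random_cell(rng=rng), envs, rng,
                                     n_epochs=1) for _ in range(60)]
        assert labels.count("none") / len(labels) >= 0.9
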