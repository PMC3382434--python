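"""Stochastic expression engine: sigmoids, gating, energy accounting."""

import math

import numpy as np
import pytest

import evonet as ev
from evonet.expression import production_probability, regulator_effect, run_epoch, step
from evonet.netmodel import Cell, Edge, Node, NodeKind, Triplet


def _bare_t0(basal=(0.0, 0.0, 0.0), m_self=1.0, degr=1e-9, values=(0, 0, 0)) -> Cell:
    kinds = (NodeKind.GENE_MRNA, NodeKind.PROTEIN, NodeKind.MODIFIED_PROTEIN)
    nodes = [Node(k, v, b, m_self, 1.0, degr) for k, v, b in zip(kinds, values, basal)]
    return Cell(triplets=[Triplet(0, nodes, True)], energy=800_000.0)


class TestRegulatorEffect:
    @pytest.mark.parametrize("v,m,s,expected", [
        (5.0, 5.0, 1.0, 0.5),                       # midpoint
        (0.0, 5.0, 1.0, 0.5 * (1 + math.tanh(-5))),  # ~4.54e-5
        (1e6, 5.0, 1.0, 1.0),                        # saturation
    ])
    def test_closed_form(self, v, m, s, expected):
        assert regulator_effect(v, m, s) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_v(self):
        vals = [regulator_effect(v, 3.0, 2.0) for v in range(0, 20)]
        assert vals == sorted(vals)
        assert all(0.0 < f < 1.0 for f in vals)

    def test_invalid_slope(self):
        with pytest.raises(ValueError):
            regulator_effect(1.0, 0.0, 0.0)


class TestProductionProbability:
    def test_no_regulators_uses_zero_sum(self):
        cell = _bare_t0(basal=(0.3, 0.0, 0.0), m_self=0.0)
        # sum = m_self = 0 -> G = basal
        assert production_probability(cell, (0, NodeKind.GENE_MRNA)) == pytest.approx(0.3)

    def test_strong_inhibition_clamps_to_zero(self):
        cell = _bare_t0(basal=(0.2, 0.2, 0.0), m_self=0.0, values=(10, 0, 0))
        cell.add_edge(Edge((0, NodeKind.GENE_MRNA), (0, NodeKind.PROTEIN),
                           -100.0, 0.0, 1.0))
        raw = production_probability(cell, (0, NodeKind.PROTEIN), clamp=False)
        assert raw == pytest.approx(0.2 + 0.8 * math.tanh(-100), abs=1e-9)  # ~ -0.6
        assert production_probability(cell, (0, NodeKind.PROTEIN)) == 0.0

    def test_strong_activation_saturates_at_one(self):
        cell = _bare_t0(basal=(0.2, 0.2, 0.0), m_self=0.0, values=(10, 0, 0))
        cell.add_edge(Edge((0, NodeKind.GENE_MRNA), (0, NodeKind.PROTEIN),
                           100.0, 0.0, 1.0))
        assert production_probability(cell, (0, NodeKind.PROTEIN)) == pytest.approx(1.0)

    def test_activator_monotonicity(self):
        cell = _bare_t0(basal=(0.1, 0.1, 0.0), m_self=0.0)
        cell.add_edge(Edge((0, NodeKind.GENE_MRNA), (0, NodeKind.PROTEIN), 3.0, 5.0, 2.0))
        gs = []
        for v in (0, 2, 5, 10, 20):
            cell.t0.node(NodeKind.GENE_MRNA).value = v
            gs.append(production_probability(cell, (0, NodeKind.PROTEIN)))
        assert gs == sorted(gs)

    def test_dangling_source_is_structural_error(self):
        cell = _bare_t0()
        cell.edges[((9, NodeKind.PROTEIN), (0, NodeKind.PROTEIN))] = Edge(
            (9, NodeKind.PROTEIN), (0, NodeKind.PROTEIN), 1.0, 1.0, 1.0)
        with pytest.raises(KeyError):
            production_probability(cell, (0, NodeKind.PROTEIN))


class TestStep:
    def test_energy_arithmetic_one_rp0_molecule(self, rng, warm_engine):
        # RP_0 count 1, nutrient present, two other maintained nodes:
        # dE = 1*(50 - 1) - 2*10 = +29
        cell = _bare_t0(values=(0, 0, 1))
        delta = step(cell, {"s1": 0, "s2": 0, "nutrient": 1}, rng)
        assert delta == pytest.approx(29.0)

    def test_no_nutrient_pays_maintenance(self, rng, warm_engine):
        cell = _bare_t0(values=(0, 0, 1))
        delta = step(cell, {"s1": 0, "s2": 0, "nutrient": 0}, rng)
        assert delta == pytest.approx(-1.0 - 20.0)

    def test_full_degradation_clears_counts(self, rng, warm_engine):
        cell = _bare_t0(degr=1.0, values=(7, 5, 3))
        step(cell, {"s1": 0, "s2": 0, "nutrient": 0}, rng)
        assert all(n.value == 0 for n in cell.t0.nodes)

    def test_degenerate_probabilities_are_deterministic(self, warm_engine):
        # all production probabilities 1, all degradation 1: mRNA flips to 1
        # every step; results do not depend on the seed
        outcomes = []
        for seed in (1, 2):
            cell = _bare_t0(basal=(1.0, 1.0, 1.0), degr=1.0, values=(4, 4, 4))
            step(cell, {"s1": 0, "s2": 0, "nutrient": 0}, np.random.default_rng(seed))
            outcomes.append([n.value for n in cell.t0.nodes])
        # protein produced because old mRNA >= 1; modified produced and
        # consumes that protein
        assert outcomes[0] == outcomes[1] == [1, 0, 1]

    def test_mean_field_expectation_single_node(self, warm_engine):
        # E[v'] = v (1 - degr) + G for the self-free mRNA node
        v0, degr, g = 5, 0.2, 0.3
        n = 8000
        rng = np.random.default_rng(7)
        total = 0
        for _ in range(n):
            cell = _bare_t0(basal=(g, 0.0, 0.0), m_self=0.0, degr=degr,
                            values=(v0, 0, 0))
            step(cell, {"s1": 0, "s2": 0, "nutrient": 0}, rng)
            total += cell.t0.node(NodeKind.GENE_MRNA).value
        expected = v0 * (1 - degr) + g
        var = v0 * degr * (1 - degr) + g * (1 - g)
        assert abs(total / n - expected) < 3 * math.sqrt(var / n)


class TestRunEpoch:
    def test_trace_spans_full_epoch(self, envs, rng, warm_engine):
        cell = ev.build_reference_cell("A")
        tr = run_epoch(cell, envs["A"], rng, mortal=False)
        assert tr.steps == 4500 and len(tr.rp0) == 4500
        assert not tr.died

    def test_silent_network_goes_quiet(self, envs, rng, warm_engine):
        cell = _bare_t0(values=(0, 0, 5), degr=0.5)
        tr = run_epoch(cell, envs["A"], rng, mortal=False)
        assert tr.rp0[100:].sum() == 0  # initial molecules degrade, nothing made

    def test_death_truncates_and_flags(self, envs, rng, warm_engine):
        cell = ev.sample_random_cell(rng=rng)
        cell.energy = 1000.0  # cannot pay maintenance for long
        tr = run_epoch(cell, envs["XOR"], rng)
        assert tr.died and tr.steps < 4500
        assert cell.energy == 0.0

    def test_energy_bookkeeping_is_exact(self, envs, rng, warm_engine):
        cell = ev.build_reference_cell("A")
        e0 = cell.energy
        env = envs["A"]
        tr = run_epoch(cell, env, rng, mortal=False)
        nut = env.nutrient.astype(float)
        deltas = tr.rp0 * (50.0 * nut - 1.0) - 10.0 * (cell.n_nodes - 1)
        assert cell.energy == pytest.approx(e0 + deltas.sum(), abs=1e-6)
        assert tr.energy_delta == pytest.approx(deltas.sum(), abs=1e-6)

    def test_trace_dataframe_export(self, envs, rng, warm_engine):
        cell = ev.build_reference_cell("A")
        tr = run_epoch(cell, envs["A"], rng, mortal=False, record_full=True)
        df = tr.to_dataframe()
        assert df.shape == (4500, cell.n_nodes)
        assert (df >= 0).all().all()
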