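"""Stochastic gene expression and energy accounting.

Per step, every node i attempts to produce at most one molecule with
probability

    G_i = clamp( basal_i + (1 - basal_i) * tanh((sum_j w_ij f_ij(v_j) - m_i) / s_i) ),

where f_ij(v) = (1 + tanh((v - m~_ij)/s~_ij))/2 is the regulator-specific
sigmoid.  Updates are synchronous (all G_i evaluated on the previous step's
counts).  Substrate gating reflects the central dogma: translation requires
the triplet's mRNA count >= 1 (not consumed); modification requires a protein
and converts it.  Every existing molecule independently degrades with its
node's per-step probability.

Energy per step changes by
    v_RP0 * (gain * [nutrient present] - cost_rp0) - cost_node * (n_nodes - 1),
where v_RP0 is the RP_0 molecule count (the modified protein of T0): nutrient
metabolism earns `gain` per RP_0 molecule per step, maintaining the metabolic
protein costs `cost_rp0` per molecule per step, and every non-RP_0 node costs
`cost_node` per step regardless of expression.  RP_0 counts as "expressed"
(for the readout trace and fitness) when v_RP0 >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._engine import SIGNAL_ON, DIED, CompiledCell
from .environment import Environment
from .netmodel import Cell, NodeRef


@dataclass
class EnergyConstants:
    cost_rp0: float = 1.0
    cost_node: float = 10.0
    gain_nutrient: float = 50.0
    division_threshold: float = 1_600_000.0
    initial_energy: float = 800_000.0
    mutation_cost: float = 0.0  # per event; no printed value, defaults to free


DEFAULT_ENERGY = EnergyConstants()


@dataclass
class ExpressionTrace:
    """Per-step record of one epoch (or a truncated run up to death)."""

    rp0: np.ndarray                  # RP_0 modified-protein count per step
    values: np.ndarray | None        # steps x nodes matrix (None unless recorded)
    columns: list                    # (triplet id, kind) per node column
    energy_delta: float
    steps: int
    died: bool = False

    def to_dataframe(self):
        import pandas as pd

        cols = [f"T{tid}:{kind}" for tid, kind in self.columns]
        if self.values is None:
            raise ValueError("full trace was not recorded")
        return pd.DataFrame(self.values[: self.steps], columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_npz(self, path) -> None:
        np.savez_compressed(path, rp0=self.rp0[: self.steps],
                            values=(self.values[: self.steps]
                                    if self.values is not None else np.empty((0, 0))),
                            energy_delta=self.energy_delta, died=self.died)


def regulator_effect(v: float, m_reg: float, s_reg: float) -> float:
    """Regulatory sigmoid f(v) = (1 + tanh((v - m_reg)/s_reg)) / 2, in (0, 1)."""
    if s_reg <= 0:
        raise ValueError("s_reg must be > 0")
    return 0.5 * (1.0 + math.tanh((v - m_reg) / s_reg))


def production_probability(cell: Cell, node: NodeRef, signal_values: dict | None = None,
                           clamp: bool = True) -> float:
    """Molecule production probability G_i for one node, from current counts.

    ``signal_values`` maps "S1"/"S2" to their current values (molecule-count
    scale; an active signal is 10 by convention); missing signals read as 0.
    """
    signal_values = signal_values or {}
    nd = cell.node(node)
    total = 0.0
    for e in cell.edges.values():
        if tuple(e.target) != tuple(node):
            continue
        if isinstance(e.source, str):
            sv = float(signal_values.get(e.source, 0.0))
        else:
            sv = float(cell.node(e.source).value)  # raises on dangling source
        total += e.w * regulator_effect(sv, e.m_reg, e.s_reg)
    g = nd.basal + (1.0 - nd.basal) * math.tanh((total - nd.m_self) / nd.s_self)
    if clamp:
        g = min(1.0, max(0.0, g))
    return g


def _single_step_env(env_state: dict) -> Environment:
    one = np.array([1], np.int8)
    return Environment("step", epoch_len=1, delay=0, window_len=1,
                       s1=one * int(env_state.get("s1", 0)),
                       s2=one * int(env_state.get("s2", 0)),
                       nutrient=one * int(env_state.get("nutrient", 0)))


def step(cell: Cell, env_state: dict, rng: np.random.Generator,
         constants: EnergyConstants = DEFAULT_ENERGY) -> float:
    """Apply one synchronous update step in place; returns the energy delta.

    Energy is floored at zero; a cell that exhausts it is left at energy 0
    (the population layer treats such cells as dead).
    """
    cc = CompiledCell(cell, cost_node=constants.cost_node)
    e0 = cell.energy
    _, energy, _, _, _ = cc.run(_single_step_env(env_state), 0, 1,
                                int(rng.integers(2 ** 31 - 1)),
                                energy=cell.energy, gain=constants.gain_nutrient,
                                cost_rp0=constants.cost_rp0, mortal=True)
    cc.writeback()
    cell.energy = energy
    return energy - e0


def run_epoch(cell: Cell, env: Environment, rng: np.random.Generator,
              constants: EnergyConstants = DEFAULT_ENERGY, *,
              record_full: bool = False, mortal: bool = True,
              compiled: CompiledCell | None = None) -> ExpressionTrace:
    """Run one full epoch, updating the cell's counts and energy cumulatively.

    If the cell exhausts its energy mid-epoch (``mortal``), the trace is
    truncated at the step of death and flagged.
    """
    cc = compiled if compiled is not None else CompiledCell(cell, cost_node=constants.cost_node)
    e0 = cell.energy
    steps, energy, status, rp0, values = cc.run(
        env, 0, env.epoch_len, int(rng.integers(2 ** 31 - 1)),
        energy=cell.energy, gain=constants.gain_nutrient,
        cost_rp0=constants.cost_rp0, mortal=mortal, record_full=record_full)
    cc.writeback()
    cell.energy = energy
    return ExpressionTrace(rp0=rp0[:steps], values=values, columns=cc.columns,
                           energy_delta=energy - e0, steps=steps, died=status == DIED)
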