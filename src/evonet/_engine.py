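"""Compiled stochastic expression engine.

The per-step update is the hot loop of every simulation (population runs,
fitness measurements, DFE collection), so a cell's network is flattened into
numpy arrays and one epoch is executed inside a single numba-jitted kernel.
Semantics (synchronous update, Bernoulli production, per-molecule Bernoulli
degradation, substrate gating, energy accounting) live only here; the public
`expression` module is a thin wrapper.

Node layout: triplets in cell order, three nodes each in (mRNA, protein,
modified) order, so node j-1 is the substrate of node j within a triplet.
The RP_0 readout is always node index 2 (modified protein of T0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .netmodel import KIND_ORDER, Cell

#: molecule-count equivalent of an active external signal (top of the m_reg range)
SIGNAL_ON = 10.0

RAN_ALL, DIED, DIVIDE = 0, 1, 2


@njit(cache=True)
def _run(v, basal, m_self, s_self, degr, kind,
         esrc, etgt, ew, em, es,
         s1f, s2f, nut,
         start, n_steps, energy,
         gain, cost_rp0, maint_cost, div_threshold, mortal,
         seed, rp0_out, trace_out, record_full):
    np.random.seed(seed)
    n = v.size
    n_edges = esrc.size
    epoch_len = s1f.size
    acc = np.empty(n)
    prod = np.empty(n, np.int64)
    status = RAN_ALL
    steps_done = 0
    for i in range(n_steps):
        t = (start + i) % epoch_len
        acc[:] = 0.0
        for e in range(n_edges):
            s = esrc[e]
            if s == -1:
                sv = s1f[t]
            elif s == -2:
                sv = s2f[t]
            else:
                sv = v[s]
            f = 0.5 * (1.0 + np.tanh((sv - em[e]) / es[e]))
            acc[etgt[e]] += ew[e] * f
        # production decisions from the previous step's values (synchronous)
        for j in range(n):
            g = basal[j] + (1.0 - basal[j]) * np.tanh((acc[j] - m_self[j]) / s_self[j])
            if g < 0.0:
                g = 0.0
            elif g > 1.0:
                g = 1.0
            gated = kind[j] == 0 or v[j - 1] >= 1
            prod[j] = 1 if (gated and np.random.random() < g) else 0
        for j in range(n):
            surv = np.random.binomial(v[j], 1.0 - degr[j]) if v[j] > 0 else 0
            v[j] = surv + prod[j]
        # modification converts one protein into its modified form
        for j in range(n):
            if kind[j] == 2 and prod[j] == 1 and v[j - 1] > 0:
                v[j - 1] -= 1
        # energy: gain and RP_0 cost scale with the RP_0 molecule count,
        # maintenance with the number of non-RP_0 nodes in the genome
        energy += v[2] * (gain * nut[t] - cost_rp0) - maint_cost
        rp0_out[i] = v[2]
        if record_full:
            for j in range(n):
                trace_out[i, j] = v[j]
        steps_done = i + 1
        if mortal and energy <= 0.0:
            energy = 0.0
            status = DIED
            break
        if div_threshold > 0.0 and energy >= div_threshold:
            status = DIVIDE
            break
    return steps_done, energy, status


class CompiledCell:
    """Flat-array view of a cell, reusable across many kernel calls."""

    def __init__(self, cell: Cell, cost_node: float = 10.0):
        self.cell = cell
        n = cell.n_nodes
        self.index = {}
        self.columns = []
        basal = np.empty(n)
        m_self = np.empty(n)
        s_self = np.empty(n)
        degr = np.empty(n)
        kind = np.empty(n, np.int8)
        v = np.empty(n, np.int64)
        j = 0
        for t in cell.triplets:
            for ki, k in enumerate(KIND_ORDER):
                node = t.nodes[ki]
                self.index[(t.id, k)] = j
                self.columns.append((t.id, k.value))
                basal[j] = node.basal
                m_self[j] = node.m_self
                s_self[j] = node.s_self
                degr[j] = node.degr
                kind[j] = ki
                v[j] = node.value
                j += 1
        edges = list(cell.edges.values())
        self.esrc = np.array(
            [-1 if e.source == "S1" else -2 if e.source == "S2"
             else self.index[(e.source[0], e.source[1])] for e in edges],
            dtype=np.int64) if edges else np.empty(0, np.int64)
        self.etgt = np.array([self.index[(e.target[0], e.target[1])] for e in edges],
                             dtype=np.int64) if edges else np.empty(0, np.int64)
        self.ew = np.array([e.w for e in edges]) if edges else np.empty(0)
        self.em = np.array([e.m_reg for e in edges]) if edges else np.empty(0)
        self.es = np.array([e.s_reg for e in edges]) if edges else np.empty(0)
        self.basal, self.m_self, self.s_self = basal, m_self, s_self
        self.degr, self.kind, self.v = degr, kind, v
        self.maint_cost = cost_node * (n - 1)

    def run(self, env, start: int, n_steps: int, seed: int, *,
            energy: float, gain: float, cost_rp0: float,
            div_threshold: float = 0.0, mortal: bool = False,
            record_full: bool = False):
        """Advance n_steps from env-step `start`; returns (steps, energy, status,
        rp0 trace, full trace or None)."""
        rp0_out = np.zeros(n_steps, np.int64)
        trace_out = (np.zeros((n_steps, self.v.size), np.int64)
                     if record_full else np.zeros((0, self.v.size), np.int64))
        s1f, s2f, nutf = signal_traces(env)
        steps, energy, status = _run(
            self.v, self.basal, self.m_self, self.s_self, self.degr, self.kind,
            self.esrc, self.etgt, self.ew, self.em, self.es,
            s1f, s2f, nutf,
            start, n_steps, float(energy),
            float(gain), float(cost_rp0), float(self.maint_cost),
            float(div_threshold), mortal,
            np.int64(seed), rp0_out, trace_out, record_full)
        return steps, energy, status, rp0_out, (trace_out if record_full else None)

    def writeback(self) -> None:
        """Copy current molecule counts back onto the Cell objects."""
        j = 0
        for t in self.cell.triplets:
            for node in t.nodes:
                node.value = int(self.v[j])
                j += 1


def signal_traces(env) -> tuple:
    """Float signal/nutrient traces for the kernel, cached on the environment."""
    cached = getattr(env, "_float_traces", None)
    if cached is None:
        cached = (env.s1.astype(np.float64) * SIGNAL_ON,
                  env.s2.astype(np.float64) * SIGNAL_ON,
                  env.nutrient.astype(np.float64))
        env._float_traces = cached
    return cached
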