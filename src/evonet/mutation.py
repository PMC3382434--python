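"""Stochastic mutation operators.

Four event classes fire independently per triplet, per time step: weak
(Gaussian nudge of one parameter, clipped to its legal range), strong
(parameter redrawn from its initialization distribution), triplet creation
(duplication or fresh random insertion) and triplet destruction.  The
metabolic triplet T0 is never destroyed.  Signal (re)connection is one slot of
the weak-mutation parameter menu, as is every parameter of the triplet's
nodes and incident edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .netmodel import (DEFAULT_INIT, KIND_ORDER, SIGNALS, Cell, Edge, InitConfig,
                       random_triplet, sample_weight)

NODE_PARAMS = ("basal", "m_self", "s_self", "degr")
EDGE_PARAMS = ("w", "m_reg", "s_reg")


@dataclass
class MutationRates:
    """Per-triplet, per-time-step event probabilities."""

    weak: float = 1e-5
    strong: float = 4e-6
    create: float = 1e-6
    destroy: float = 1e-6
    weak_sigma_frac: float = 0.1   # Gaussian width as a fraction of the legal range
    weight_sigma: float = 0.4      # additive width for weak weight perturbation

    @property
    def total(self) -> float:
        return self.weak + self.strong + self.create + self.destroy


DEFAULT_RATES = MutationRates()


@dataclass
class MutationEvent:
    type: str           # weak | strong | create | destroy | signal
    triplet_id: int
    locus: str
    old: object = None
    new: object = None


def _param_range(name: str, init: InitConfig) -> tuple:
    return {"basal": init.basal_range, "m_self": init.m_self_range,
            "s_self": init.s_self_range, "degr": init.degr_range,
            "m_reg": init.m_reg_range, "s_reg": init.s_reg_range}[name]


def _incident_edges(cell: Cell, tid: int) -> list:
    def touches(ref) -> bool:
        return not isinstance(ref, str) and ref[0] == tid

    return [e for e in cell.edges.values() if touches(e.source) or touches(e.target)]


def _weak_slots(cell: Cell, tid: int) -> list:
    t = cell.triplet_by_id(tid)
    slots = [("node", t.id, kind, p) for kind in KIND_ORDER for p in NODE_PARAMS]
    slots += [("edge", e.key, p) for e in _incident_edges(cell, tid) for p in EDGE_PARAMS]
    slots.append(("signal",))
    return slots


def perturb_parameter(cell: Cell, slot, rng: np.random.Generator,
                      rates: MutationRates, init: InitConfig, strong: bool) -> MutationEvent:
    """Apply a weak (clipped Gaussian) or strong (redraw) change to one slot."""
    if slot[0] == "node":
        _, tid, kind, p = slot
        node = cell.triplet_by_id(tid).node(kind)
        lo, hi = _param_range(p, init)
        old = getattr(node, p)
        if strong:
            new = rng.uniform(lo, hi)
        else:
            new = min(hi, max(lo, old + rng.normal(0.0, rates.weak_sigma_frac * (hi - lo))))
        setattr(node, p, float(new))
        return MutationEvent("strong" if strong else "weak", tid,
                             f"T{tid}:{kind.value}.{p}", old, float(new))
    _, key, p = slot
    edge = cell.edges[key]
    tid = edge.target[0]
    old = getattr(edge, p)
    if p == "w":
        if strong:
            new = sample_weight(rng, init=init)
        else:
            new = old + rng.normal(0.0, rates.weight_sigma)
            new = min(init.weight_cap, max(-init.weight_cap, new))
    else:
        lo, hi = _param_range(p, init)
        if strong:
            new = rng.uniform(lo, hi)
        else:
            new = min(hi, max(lo, old + rng.normal(0.0, rates.weak_sigma_frac * (hi - lo))))
    setattr(edge, p, float(new))
    return MutationEvent("strong" if strong else "weak", tid,
                         f"edge{key}.{p}", old, float(new))


def connect_signal(cell: Cell, rng: np.random.Generator,
                   init: InitConfig = DEFAULT_INIT) -> MutationEvent:
    """Wire a uniformly chosen external signal onto a node.

    Nodes already regulated by n signals are chosen with probability
    ∝ exp(-n); an existing (signal, node) edge is replaced, never duplicated.
    """
    refs = cell.node_refs()
    n_sig = np.zeros(len(refs))
    idx = {r: i for i, r in enumerate(refs)}
    for e in cell.edges.values():
        if isinstance(e.source, str):
            n_sig[idx[tuple(e.target)]] += 1
    wts = np.exp(-n_sig)
    target = refs[int(rng.choice(len(refs), p=wts / wts.sum()))]
    sig = SIGNALS[int(rng.integers(2))]
    edge = Edge(sig, target, sample_weight(rng, init=init),
                rng.uniform(*init.m_reg_range), rng.uniform(*init.s_reg_range))
    cell.add_edge(edge)
    return MutationEvent("signal", target[0], f"{sig}->T{target[0]}:{target[1].value}",
                         None, edge.w)


def create_triplet(cell: Cell, rng: np.random.Generator,
                   init: InitConfig = DEFAULT_INIT) -> MutationEvent:
    """Grow the network by one triplet.

    With probability 1/2 an existing triplet is duplicated (parameters and
    incident edges copied, the copy never metabolic); otherwise a fresh random
    triplet is inserted and wired per the initialization config.
    """
    new_id = cell.next_triplet_id()
    if rng.random() < 0.5:
        src = cell.triplets[int(rng.integers(len(cell.triplets)))]
        dup = src.copy(new_id=new_id)
        dup.is_metabolic = False
        cell.triplets.append(dup)

        def remap(ref):
            if not isinstance(ref, str) and ref[0] == src.id:
                return (new_id, ref[1])
            return ref

        for e in list(cell.edges.values()):
            s, t = remap(e.source), remap(e.target)
            if (s, t) != e.key:
                cell.add_edge(Edge(s, t, e.w, e.m_reg, e.s_reg))
        return MutationEvent("create", new_id, f"duplicate T{src.id}")

    cell.triplets.append(random_triplet(new_id, init, rng))
    old_refs = [r for r in cell.node_refs() if r[0] != new_id]
    new_refs = [(new_id, k) for k in KIND_ORDER]
    pairs = ([(s, t) for s in old_refs + list(SIGNALS) + new_refs for t in new_refs]
             + [(s, t) for s in new_refs for t in old_refs])
    n_new = int(round(rng.uniform(*init.sparsity_range) * len(pairs)))
    for i in rng.choice(len(pairs), size=min(n_new, len(pairs)), replace=False):
        s, t = pairs[int(i)]
        cell.add_edge(Edge(s, t, sample_weight(rng, init=init),
                           rng.uniform(*init.m_reg_range), rng.uniform(*init.s_reg_range)))
    return MutationEvent("create", new_id, "fresh triplet")


def destroy_triplet(cell: Cell, rng: np.random.Generator,
                    tid: int | None = None) -> MutationEvent | None:
    """Delete one non-metabolic triplet (uniform if unspecified); no-op when
    only T0 remains."""
    candidates = [t.id for t in cell.triplets if not t.is_metabolic]
    if not candidates:
        return None
    if tid is None or tid not in candidates:
        tid = candidates[int(rng.integers(len(candidates)))]
    cell.remove_triplet(tid)
    return MutationEvent("destroy", tid, f"remove T{tid}")


def mutate_step(cell: Cell, rates: MutationRates, rng: np.random.Generator,
                init: InitConfig = DEFAULT_INIT, n_steps: int = 1) -> list:
    """Trigger mutation events for ``n_steps`` time steps in place.

    Each triplet independently draws each event class per step; the expected
    event count is rate x triplets x steps.  Returns the applied events.
    """
    events: list = []
    probs = np.array([rates.weak, rates.strong, rates.create, rates.destroy])
    n_t = len(cell.triplets)
    counts = rng.binomial(n_t * n_steps, probs)
    order = []
    for kind, c in zip(("weak", "strong", "create", "destroy"), counts):
        order += [kind] * int(c)
    rng.shuffle(order)
    for kind in order:
        tids = [t.id for t in cell.triplets]
        tid = tids[int(rng.integers(len(tids)))]
        ev = apply_event(cell, kind, rng, rates, init, tid=tid)
        if ev is not None:
            events.append(ev)
    return events


def apply_event(cell: Cell, kind: str, rng: np.random.Generator,
                rates: MutationRates = DEFAULT_RATES, init: InitConfig = DEFAULT_INIT,
                tid: int | None = None) -> MutationEvent | None:
    """Apply one event of the given class to a (given or uniform) triplet."""
    if tid is None:
        tid = cell.triplets[int(rng.integers(len(cell.triplets)))].id
    if kind == "create":
        return create_triplet(cell, rng, init)
    if kind == "destroy":
        target = tid if not cell.triplet_by_id(tid).is_metabolic else None
        return destroy_triplet(cell, rng, tid=target)
    slots = _weak_slots(cell, tid)
    if kind == "strong":
        slots = [s for s in slots if s[0] != "signal"]
    slot = slots[int(rng.integers(len(slots)))]
    if slot[0] == "signal":
        return connect_signal(cell, rng, init)
    return perturb_parameter(cell, slot, rng, rates, init, strong=kind == "strong")


def random_single_mutation(cell: Cell, rng: np.random.Generator,
                           rates: MutationRates = DEFAULT_RATES,
                           init: InitConfig = DEFAULT_INIT) -> MutationEvent | None:
    """One mutation event with class drawn ∝ its rate (the DFE unit event)."""
    probs = np.array([rates.weak, rates.strong, rates.create, rates.destroy])
    kind = ("weak", "strong", "create", "destroy")[int(rng.choice(4, p=probs / probs.sum()))]
    return apply_event(cell, kind, rng, rates, init)
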