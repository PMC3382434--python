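"""Fitness, distribution of fitness effects (DFE), network reduction and
phenotype classification.

Fitness w is the Pearson correlation between the RP_0 modified-protein trace
and the nutrient trace over an epoch, clamped below at zero (anti-correlated
or silent responders are treated as non-functional).  It is a read-out only:
selection in the simulator acts exclusively through energy.

The fitness effect of a single mutation or HGT event is w_after/w_before - 1;
an event is lethal when w_after = 0 (effect exactly -1) and excluded from the
ratio when w_before is below a small floor (default 0.01), since the ratio is
numerically meaningless for cells with no measurable function.  DFE moments
are computed over viable events only (effect > -0.8), matching the convention
used for the summary statistics the simulator is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from . import hgt as hgt_mod
from . import mutation as mut_mod
from ._engine import CompiledCell
from .environment import Environment, make_environment
from .expression import DEFAULT_ENERGY, EnergyConstants
from .netmodel import Cell, validate_cell

EPS_BEFORE = 0.01     # exclusion floor for w_before in fitness-effect ratios
VIABLE_FLOOR = -0.8   # events with effect <= -0.8 are outside the viable moments


@dataclass
class FitnessValue:
    w: float
    n_epochs: int = 1

    def __float__(self) -> float:
        return self.w


@dataclass
class EventRecord:
    epoch: int
    step: int
    type: str
    locus: str
    w_before: float
    w_after: float | None = None
    excluded: bool = False

    @property
    def effect(self) -> float | None:
        if self.excluded or self.w_after is None:
            return None
        return self.w_after / self.w_before - 1.0

    @property
    def lethal(self) -> bool:
        return self.w_after == 0.0 and not self.excluded

    def to_json(self) -> dict:
        return {"epoch": self.epoch, "step": self.step, "type": self.type,
                "locus": self.locus, "w_before": self.w_before,
                "w_after": self.w_after, "excluded": self.excluded,
                "effect": self.effect}


def _clamped_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size != y.size or x.size < 2:
        return 0.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return max(0.0, r)


def fitness(cell: Cell, env: Environment, rng: np.random.Generator,
            n_epochs: int = 1, constants: EnergyConstants = DEFAULT_ENERGY) -> FitnessValue:
    """Mean clamped Pearson correlation of RP_0 vs nutrients over n_epochs.

    Runs on a clone with energy bookkeeping disabled, so measuring fitness has
    no side effect on the cell.
    """
    clone = cell.copy()
    cc = CompiledCell(clone, cost_node=constants.cost_node)
    nut = env.nutrient.astype(float)
    ws = []
    for _ in range(n_epochs):
        _, _, _, rp0, _ = cc.run(env, 0, env.epoch_len, int(rng.integers(2 ** 31 - 1)),
                                 energy=1.0, gain=constants.gain_nutrient,
                                 cost_rp0=constants.cost_rp0, mortal=False)
        ws.append(_clamped_pearson(rp0.astype(float), nut))
    return FitnessValue(float(np.mean(ws)), n_epochs)


def fitness_effect(w_before: float, w_after: float,
                   eps: float = EPS_BEFORE) -> float | None:
    """Selection coefficient w_after/w_before - 1; None when excluded
    (w_before below the floor).  Exactly -1 iff w_after = 0."""
    if not (0.0 <= w_before <= 1.0 and 0.0 <= w_after <= 1.0):
        raise ValueError("fitness values must lie in [0, 1]")
    if w_before < eps:
        return None
    return w_after / w_before - 1.0


@dataclass
class DFESummary:
    mean_effect: float
    variance: float
    skewness: float
    kurtosis: float          # excess (Gaussian -> 0), bias-corrected
    lethal_fraction: float
    n_events: int
    n_viable: int
    n_excluded: int = 0
    effects: np.ndarray | None = field(default=None, repr=False)


def dfe_summary(effects, n_excluded: int = 0) -> DFESummary:
    """Summarize a set of non-excluded fitness effects.

    The lethal fraction is computed over all non-excluded events; the four
    moments over viable events only (effect > -0.8).
    """
    effects = np.asarray(list(effects), dtype=float)
    if effects.size == 0:
        raise ValueError("no events collected")
    lethal = float(np.mean(effects == -1.0))
    viable = effects[effects > VIABLE_FLOOR]
    if viable.size < 2:
        raise ValueError("too few viable events for moment estimates")
    return DFESummary(
        mean_effect=float(np.mean(viable)),
        variance=float(np.var(viable, ddof=1)),
        skewness=float(stats.skew(viable, bias=False)),
        kurtosis=float(stats.kurtosis(viable, fisher=True, bias=False)),
        lethal_fraction=lethal,
        n_events=int(effects.size),
        n_viable=int(viable.size),
        n_excluded=n_excluded,
        effects=effects)


def collect_dfe(source, env: Environment, event_source: str, n_events: int,
                rng: np.random.Generator, *,
                rates: mut_mod.MutationRates = mut_mod.DEFAULT_RATES,
                frag_model: hgt_mod.FragmentSizeModel | None = None,
                events_per_cell: int = 4, n_epochs: int = 1,
                eps: float = EPS_BEFORE,
                constants: EnergyConstants = DEFAULT_ENERGY) -> DFESummary:
    """Measure single-event fitness effects until n_events non-excluded events.

    ``source`` is a list of cells (cycled) or a zero-argument callable
    producing fresh cells.  For each base cell, w_before is measured once on a
    clone; each event is then applied to a fresh clone and w_after measured.
    ``event_source`` is "mutation" or "hgt"; HGT donors are drawn from the
    same source.
    """
    if event_source not in ("mutation", "hgt"):
        raise ValueError("event_source must be 'mutation' or 'hgt'")
    if n_events < 1:
        raise ValueError("no events collected")
    frag_model = frag_model or hgt_mod.FragmentSizeModel()

    if callable(source):
        make = source
    else:
        cells = list(source)
        if not cells:
            raise ValueError("no events collected: empty source")
        counter = {"i": 0}

        def make():
            c = cells[counter["i"] % len(cells)]
            counter["i"] += 1
            return c

    effects: list = []
    n_excluded = 0
    while len(effects) < n_events:
        base = make()
        w_before = fitness(base, env, rng, n_epochs, constants).w
        if w_before < eps:
            n_excluded += 1
            continue
        for _ in range(events_per_cell):
            if len(effects) >= n_events:
                break
            clone = base.copy(fresh_id=True)
            if event_source == "mutation":
                ev = mut_mod.random_single_mutation(clone, rng, rates)
                if ev is None:
                    continue
            else:
                donor = make()
                if len(donor.triplets) < 2:
                    continue
                if hgt_mod.transfer(donor, clone, frag_model, rng) is None:
                    continue
            w_after = fitness(clone, env, rng, n_epochs, constants).w
            effects.append(w_after / w_before - 1.0)
    return dfe_summary(effects, n_excluded=n_excluded)


def network_stats(cell: Cell) -> dict:
    """Triplet count, link count and sparsity (links per possible directed
    (source, target) pair, the two signals counted as sources)."""
    n = cell.n_nodes
    links = len(cell.edges)
    possible = (n + 2) * n
    return {"triplets": len(cell.triplets), "links": links,
            "sparsity": links / possible if possible else 0.0}


def reduce_network(cell: Cell, env: Environment, rng: np.random.Generator,
                   threshold: float = 0.05, n_epochs: int = 10,
                   constants: EnergyConstants = DEFAULT_ENERGY) -> Cell:
    """Iteratively strip non-essential edges to expose the minimal network.

    Each candidate edge is severed and fitness re-measured (averaged over
    n_epochs to tame epoch-to-epoch stochasticity); the removal is made
    permanent when the relative fitness change is below ``threshold``.  Full
    passes repeat until no edge is removed, after which triplets with no
    remaining (undirected) connection to T0 or to a signal are dropped.
    """
    current = cell.copy(fresh_id=True)
    w_cur = fitness(current, env, rng, n_epochs, constants).w
    if w_cur <= 0.0:
        raise ValueError("nothing to preserve: cell has zero fitness")
    removed_any = True
    while removed_any:
        removed_any = False
        for key in list(current.edges):
            trial = current.copy()
            del trial.edges[key]
            w_trial = fitness(trial, env, rng, n_epochs, constants).w
            if abs(w_trial - w_cur) < threshold * w_cur:
                current = trial
                w_cur = w_trial
                removed_any = True

    g = nx.Graph()
    g.add_nodes_from(t.id for t in current.triplets)
    g.add_nodes_from(["S1", "S2"])
    for e in current.edges.values():
        src = e.source if isinstance(e.source, str) else e.source[0]
        g.add_edge(src, e.target[0])
    t0_id = current.t0.id
    keep = set()
    for comp in nx.connected_components(g):
        if t0_id in comp or comp & {"S1", "S2"}:
            keep |= comp
    for t in list(current.triplets):
        if t.id not in keep and not t.is_metabolic:
            current.remove_triplet(t.id)
    validate_cell(current)
    return current


def default_envs(epoch_len: int = 4500, delay: int = 300) -> dict:
    return {k: make_environment(k, epoch_len, delay) for k in ("A", "B", "XOR")}


def classify_phenotype(cell: Cell, envs: dict | None = None,
                       rng: np.random.Generator | None = None,
                       threshold: float = 0.6, n_epochs: int = 10) -> str:
    """Label a cell A, B, XOR or none by its fitness in each environment.

    XOR wins whenever w_XOR clears the threshold (an XOR responder also
    correlates partially with A and B nutrients); otherwise the best single
    environment above threshold, else "none".
    """
    envs = envs or default_envs()
    rng = rng or np.random.default_rng()
    ws = {k: fitness(cell, e, rng, n_epochs).w for k, e in envs.items()}
    if ws.get("XOR", 0.0) >= threshold:
        return "XOR"
    single = {k: w for k, w in ws.items() if k != "XOR" and w >= threshold}
    if single:
        return max(single, key=single.get)
    return "none"
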