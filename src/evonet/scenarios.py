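"""Reproducible experiment designs and reference fixtures.

The experiments mirror the three ecological settings: (i) direct adaptation
of an unevolved population to the combined XOR environment ("single-step"),
(ii)/(iii) adaptation first to the simpler correlated environments A and B,
followed by 1:1 mixing and evolution in XOR with or without HGT ("dual-step"),
plus the fragment-size/rate sweeps and the network-union control.

`build_reference_cell` returns hand-wired minimal networks implementing the
A, B and XOR phenotypes.  Each single-environment cell computes a delayed
AND-gate: a slow "follower" protein integrates one signal (rise time ≈ the
nutrient delay), a second follower integrates the other signal as an
inhibitor, and a fast gate protein drives the RP_0 modification of T0.  The
XOR cell is exactly the union of the A and B mechanisms sharing one T0 —
which is also what a single whole-mechanism HGT event produces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import hgt as hgt_mod
from .environment import Environment, make_environment
from .expression import DEFAULT_ENERGY, EnergyConstants
from .mutation import DEFAULT_RATES, MutationRates
from .netmodel import (DEFAULT_INIT, Cell, Edge, InitConfig, Node, NodeKind,
                       Triplet, union_networks, validate_cell)
from .population import Population, Trajectory, evolve, mix_populations


# ---------------------------------------------------------------------------
# reference fixtures
# ---------------------------------------------------------------------------

def _triplet(tid, mrna, prot, mod, metabolic=False) -> Triplet:
    kinds = (NodeKind.GENE_MRNA, NodeKind.PROTEIN, NodeKind.MODIFIED_PROTEIN)
    nodes = [Node(k, 0, *params) for k, params in zip(kinds, (mrna, prot, mod))]
    return Triplet(tid, nodes, metabolic)


#: (basal, m_self, s_self, degr)
_SILENT = (0.0, 1.0, 1.0, 0.1)


def _t0() -> Triplet:
    return _triplet(0,
                    mrna=(0.5, 0.0, 1.0, 0.1),
                    prot=(0.6, 0.0, 1.0, 0.05),
                    mod=(0.0, 1.0, 1.0, 0.02),
                    metabolic=True)


def _follower(tid: int, signal: str) -> tuple:
    """Signal-integrating triplet: mRNA tracks the signal, the protein
    accumulates slowly (rise time ~200 steps), providing the delay."""
    t = _triplet(tid,
                 mrna=(0.0, 1.0, 2.0, 0.1),
                 prot=(0.06, 0.0, 1.0, 0.005),
                 mod=_SILENT)
    e = Edge(signal, (tid, NodeKind.GENE_MRNA), 10.0, 5.0, 1.0)
    return t, [e]


def _gate(tid: int, act_tid: int, inh_tid: int) -> tuple:
    """Fast AND-NOT gate protein: activated by one follower, vetoed by the
    other; its output drives the RP_0 modification of T0."""
    t = _triplet(tid,
                 mrna=(0.5, 0.0, 1.0, 0.1),
                 prot=(0.0, 1.0, 1.0, 0.05),
                 mod=_SILENT)
    edges = [
        Edge((act_tid, NodeKind.PROTEIN), (tid, NodeKind.PROTEIN), 8.0, 7.0, 1.0),
        Edge((inh_tid, NodeKind.PROTEIN), (tid, NodeKind.PROTEIN), -16.0, 5.0, 1.0),
        Edge((tid, NodeKind.PROTEIN), (0, NodeKind.MODIFIED_PROTEIN), 8.0, 3.0, 1.0),
    ]
    return t, edges


def build_reference_cell(phenotype: str,
                         init: InitConfig = DEFAULT_INIT) -> Cell:
    """Hand-wired minimal network for phenotype "A", "B" or "XOR".

    A: T1 integrates S1 (activator), T2 integrates S2 (inhibitor), T3 gates
    RP_0 — a delayed (S1 AND NOT S2) responder.  B mirrors it on T4..T6.
    XOR is the union of both mechanisms on a shared T0.
    """
    if phenotype == "XOR":
        return union_networks(build_reference_cell("A", init),
                              build_reference_cell("B", init), init)
    if phenotype == "A":
        specs = [_follower(1, "S1"), _follower(2, "S2"), _gate(3, 1, 2)]
    elif phenotype == "B":
        specs = [_follower(4, "S2"), _follower(5, "S1"), _gate(6, 4, 5)]
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    cell = Cell(triplets=[_t0()], energy=init.initial_energy)
    for t, edges in specs:
        cell.triplets.append(t)
        for e in edges:
            cell.add_edge(e)
    validate_cell(cell)
    return cell


def fixture_population(phenotype: str, size: int, rng: np.random.Generator,
                       weight_jitter: float = 0.5,
                       init: InitConfig = DEFAULT_INIT) -> Population:
    """Population of jittered copies of a reference cell (weights perturbed
    by a Gaussian) — a stand-in for a population evolved in that environment."""
    cells = []
    for _ in range(size):
        c = build_reference_cell(phenotype, init).copy(fresh_id=True)
        for e in c.edges.values():
            e.w += float(rng.normal(0.0, weight_jitter))
        cells.append(c)
    return Population(cells)


# ---------------------------------------------------------------------------
# experiment configuration & manifest
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Desk-scale defaults; `full_scale` switches to the full-size design."""

    pop_size: int = 64
    n_epochs: int = 400
    epoch_len: int = 4500
    delay: int = 300
    thresholds: tuple = (0.75, 0.90)
    hgt_rate: float = 5e-5
    frag_m: float = 5.0
    frag_s: float = 5.0
    segment_len: int = 450
    record_fitness: bool = False
    full_scale: bool = False

    def __post_init__(self):
        if self.full_scale:
            self.pop_size = 256
            self.n_epochs = max(self.n_epochs, 2000)

    def frag_model(self) -> hgt_mod.FragmentSizeModel:
        return hgt_mod.FragmentSizeModel(self.frag_m, self.frag_s)

    def environment(self, kind: str) -> Environment:
        return make_environment(kind, self.epoch_len, self.delay)


@dataclass
class RunManifest:
    scenario: str
    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class FossilRecord:
    """Append-only log of mutation/HGT events of one run."""

    records: list = field(default_factory=list)

    def save_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r.to_json()) + "\n")


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------

def run_single_step(env_kind: str, config: ScenarioConfig, seed: int,
                    hgt: bool = False):
    """Unevolved population evolved directly in one environment."""
    rng = np.random.default_rng(seed)
    env = config.environment(env_kind)
    pop = Population.random(config.pop_size, rng)
    traj = evolve(pop, env, config.n_epochs, rng,
                  hgt_mode="pairwise" if hgt else "off",
                  hgt_rate=config.hgt_rate, frag_model=config.frag_model(),
                  segment_len=config.segment_len,
                  record_fitness=config.record_fitness)
    manifest = RunManifest("single_step", dataclasses.asdict(config) | {"env": env_kind},
                           seed)
    manifest.outputs["epochs_to_threshold"] = {
        str(th): traj.first_epoch_above(th) for th in config.thresholds}
    return traj, FossilRecord(traj.events), manifest


def run_dual_step(config: ScenarioConfig, seed: int, hgt: bool,
                  source_a: Population | None = None,
                  source_b: Population | None = None,
                  xor_epochs: int | None = None):
    """Two-stage adaptation: evolve (or take) A- and B-adapted populations,
    mix 1:1, then evolve the mixture in the XOR environment."""
    rng = np.random.default_rng(seed)
    if source_a is None:
        pa = Population.random(config.pop_size, rng)
        evolve(pa, config.environment("A"), config.n_epochs, rng,
               segment_len=config.segment_len)
        source_a = pa
    if source_b is None:
        pb = Population.random(config.pop_size, rng)
        evolve(pb, config.environment("B"), config.n_epochs, rng,
               segment_len=config.segment_len)
        source_b = pb
    mixed = mix_populations(source_a, source_b, config.pop_size, rng)
    traj = evolve(mixed, config.environment("XOR"),
                  xor_epochs or config.n_epochs, rng,
                  hgt_mode="pairwise" if hgt else "off",
                  hgt_rate=config.hgt_rate, frag_model=config.frag_model(),
                  segment_len=config.segment_len,
                  record_fitness=config.record_fitness)
    manifest = RunManifest("dual_step", dataclasses.asdict(config) | {"hgt": hgt}, seed)
    manifest.outputs["epochs_to_threshold"] = {
        str(th): traj.first_epoch_above(th) for th in config.thresholds}
    return traj, FossilRecord(traj.events), manifest


def build_fragment_pool(donors, rng: np.random.Generator,
                        model: hgt_mod.FragmentSizeModel, n_fragments: int) -> list:
    """Extract a naked-DNA fragment pool from evolved donor cells."""
    pool = []
    for _ in range(n_fragments):
        donor = donors[int(rng.integers(len(donors)))]
        n = len(donor.triplets) - 1
        if n < 1:
            continue
        size = hgt_mod.sample_fragment_size(model, n, rng)
        pool.append(hgt_mod.extract_fragment(donor, size, rng))
    return pool


def run_fragment_sweep(values, vary: str, config: ScenarioConfig, seeds,
                       donors, threshold: float = 0.75):
    """Pool-mode evolution of unevolved populations for each swept value of
    the fragment-size midpoint ("m") or the HGT rate ("rate").

    Returns a list of rows {value, seed, epochs_to_threshold}; None means the
    threshold was not reached within the budget (capped runs).
    """
    if vary not in ("m", "rate"):
        raise ValueError("vary must be 'm' or 'rate'")
    rows = []
    for val in values:
        model = (hgt_mod.FragmentSizeModel(val, val) if vary == "m"
                 else config.frag_model())
        rate = config.hgt_rate if vary == "m" else val
        for seed in seeds:
            rng = np.random.default_rng(seed)
            pool = build_fragment_pool(donors, rng, model, n_fragments=64) if rate else None
            pop = Population.random(config.pop_size, rng)
            traj = evolve(pop, config.environment("XOR"), config.n_epochs, rng,
                          hgt_mode="pool" if rate else "off",
                          hgt_rate=rate, frag_model=model, frag_pool=pool,
                          segment_len=config.segment_len)
            rows.append({"value": val, "seed": seed,
                         "epochs_to_threshold": traj.first_epoch_above(threshold),
                         "final_max_fitness": float(traj.max_fitness[-1])})
    return rows


def unevolved_dfe(event_source: str, n_events: int, seed: int,
                  env: Environment | None = None, events_per_cell: int = 4,
                  frag_model: hgt_mod.FragmentSizeModel | None = None):
    """Distribution of fitness effects of single events on freshly generated
    random cells (the un-adapted baseline): one-epoch clamped-Pearson fitness
    before and after each event, ratio effects over non-excluded events."""
    from .analysis import collect_dfe
    from .netmodel import sample_random_cell

    rng = np.random.default_rng(seed)
    env = env or make_environment("XOR")
    return collect_dfe(lambda: sample_random_cell(rng=rng), env, event_source,
                       n_events, rng, events_per_cell=events_per_cell,
                       frag_model=frag_model)


def run_union_test(pop_a: Population, pop_b: Population, n_pairs: int,
                   rng: np.random.Generator, env: Environment | None = None,
                   n_epochs: int = 1) -> np.ndarray:
    """Fitness distribution (in XOR) of direct pairwise network unions."""
    from .analysis import fitness

    env = env or make_environment("XOR")
    ws = np.empty(n_pairs)
    for k in range(n_pairs):
        a = pop_a.cells[int(rng.integers(len(pop_a.cells)))]
        b = pop_b.cells[int(rng.integers(len(pop_b.cells)))]
        ws[k] = fitness(union_networks(a, b), env, rng, n_epochs).w
    return ws
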