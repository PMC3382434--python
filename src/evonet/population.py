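"""Fixed-size population dynamics.

A population holds a constant number of cells.  Cells gain or lose energy
through expression; a cell reaching the division threshold splits its energy
with a daughter that replaces a low-energy competitor (probability inversely
proportional to energy), and a cell that exhausts its energy is replaced by a
fresh random cell.  Selection therefore acts purely through the energy
economy — fitness (the RP_0/nutrient correlation) is recorded but never used
by the dynamics.

`evolve` advances whole epochs.  Expression and energy accounting are exact
per step inside the compiled kernel; mutation, HGT, division and replacement
are settled at fixed segment boundaries (default 450 steps, i.e. ten times
per epoch), with per-segment event counts drawn at the per-step rates.  Events
are rare at the default rates, so this quantization leaves the event
statistics unchanged while keeping the population loop out of Python's
per-step overhead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hgt as hgt_mod
from ._engine import DIED, DIVIDE, CompiledCell
from .environment import Environment
from .expression import DEFAULT_ENERGY, EnergyConstants
from .mutation import DEFAULT_RATES, MutationRates, mutate_step
from .netmodel import DEFAULT_INIT, Cell, InitConfig, sample_random_cell


@dataclass
class Population:
    cells: list
    epoch: int = 0

    def __len__(self) -> int:
        return len(self.cells)

    @classmethod
    def random(cls, size: int, rng: np.random.Generator,
               init: InitConfig = DEFAULT_INIT) -> "Population":
        return cls([sample_random_cell(init, rng) for _ in range(size)])


@dataclass
class Trajectory:
    """Per-epoch summary of an evolve() run."""

    rows: list = field(default_factory=list)
    events: list = field(default_factory=list)

    @property
    def max_fitness(self) -> np.ndarray:
        return np.array([r["max_fitness"] for r in self.rows])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def first_epoch_above(self, w: float) -> int | None:
        hits = np.flatnonzero(self.max_fitness > w)
        return int(self.rows[hits[0]]["epoch"]) if hits.size else None


def _replacement_index(pop: Population, rng: np.random.Generator,
                       exclude: int) -> int:
    """Pick the cell to be replaced, with probability ∝ 1/energy."""
    weights = np.array([0.0 if i == exclude else 1.0 / max(c.energy, 1.0)
                        for i, c in enumerate(pop.cells)])
    return int(rng.choice(len(pop.cells), p=weights / weights.sum()))


def divide(pop: Population, cell_index: int, rng: np.random.Generator,
           constants: EnergyConstants = DEFAULT_ENERGY) -> int:
    """Split the cell's energy with a daughter that replaces a competitor.

    Returns the replaced index.  Population size is unchanged.
    """
    parent = pop.cells[cell_index]
    if parent.energy < constants.division_threshold:
        raise ValueError("cell below division threshold")
    parent.energy /= 2.0
    daughter = parent.copy(fresh_id=True)
    victim = _replacement_index(pop, rng, exclude=cell_index)
    pop.cells[victim] = daughter
    return victim


def replace_dead(pop: Population, init: InitConfig, rng: np.random.Generator) -> list:
    """Replace every energy-exhausted cell with a fresh random cell."""
    replaced = []
    for i, c in enumerate(pop.cells):
        if c.energy <= 0.0:
            pop.cells[i] = sample_random_cell(init, rng)
            replaced.append(i)
    return replaced


def mix_populations(pop_a: Population, pop_b: Population, size: int,
                    rng: np.random.Generator,
                    init: InitConfig = DEFAULT_INIT) -> Population:
    """Sample size/2 cells uniformly (with replacement) from each source,
    re-energized to the initial energy."""
    cells = []
    for src, n in ((pop_a, size // 2), (pop_b, size - size // 2)):
        for i in rng.integers(len(src.cells), size=n):
            c = src.cells[int(i)].copy(fresh_id=True)
            c.energy = init.initial_energy
            cells.append(c)
    return Population(cells)


def evolve(pop: Population, env: Environment, n_epochs: int,
           rng: np.random.Generator, *,
           rates: MutationRates = DEFAULT_RATES,
           init: InitConfig = DEFAULT_INIT,
           constants: EnergyConstants = DEFAULT_ENERGY,
           hgt_mode: str = "off", hgt_rate: float = 5e-5,
           frag_model: hgt_mod.FragmentSizeModel | None = None,
           frag_pool: list | None = None,
           segment_len: int = 450,
           record_fitness: bool = False) -> Trajectory:
    """Run the full population loop for n_epochs.

    hgt_mode: "off", "pairwise" (donors drawn from the population) or "pool"
    (fragments drawn from ``frag_pool``).  Fully reproducible from the rng
    state.  Per-epoch fitness is computed from each cell's live RP_0 trace
    over that epoch (cells replaced mid-epoch score 0).
    """
    if hgt_mode not in ("off", "pairwise", "pool"):
        raise ValueError(f"unknown hgt_mode {hgt_mode!r}")
    if hgt_mode == "pool" and not frag_pool:
        raise ValueError("pool mode needs a fragment pool")
    frag_model = frag_model or hgt_mod.FragmentSizeModel()
    if env.epoch_len % segment_len:
        raise ValueError("epoch_len must be divisible by segment_len")
    n_seg = env.epoch_len // segment_len

    traj = Trajectory()
    compiled = {i: CompiledCell(c, constants.cost_node) for i, c in enumerate(pop.cells)}
    nut = env.nutrient.astype(float)

    def recompiled(i):
        compiled[i] = CompiledCell(pop.cells[i], constants.cost_node)

    for _ in range(n_epochs):
        rp0 = np.zeros((len(pop.cells), env.epoch_len), np.int64)
        alive = np.ones(len(pop.cells), bool)
        n_div = n_dead = 0
        epoch_events = []
        for seg in range(n_seg):
            start = seg * segment_len
            pending_div = []
            for i, cell in enumerate(pop.cells):
                if not alive[i]:
                    continue
                consumed = 0
                while consumed < segment_len:
                    steps, energy, status, r, _ = compiled[i].run(
                        env, start + consumed, segment_len - consumed,
                        int(rng.integers(2 ** 31 - 1)),
                        energy=cell.energy, gain=constants.gain_nutrient,
                        cost_rp0=constants.cost_rp0, mortal=True,
                        div_threshold=constants.division_threshold)
                    rp0[i, start + consumed:start + consumed + steps] = r[:steps]
                    cell.energy = energy
                    consumed += steps
                    if status == DIED:
                        alive[i] = False
                        break
                    if status == DIVIDE:
                        cell.energy /= 2.0  # daughter takes the other half at the boundary
                        pending_div.append((i, cell.energy))

            # mutation, at the printed per-triplet per-step rates
            for i, cell in enumerate(pop.cells):
                if not alive[i]:
                    continue
                compiled[i].writeback()
                snap = cell.copy() if record_fitness else None
                evs = mutate_step(cell, rates, rng, init, n_steps=segment_len)
                if evs:
                    _record(epoch_events, evs, pop.epoch, start, snap, cell,
                            env, rng, record_fitness)
                    recompiled(i)
                    cell.energy = max(0.0, cell.energy - constants.mutation_cost * len(evs))

            # horizontal transfer
            if hgt_mode != "off":
                live = [j for j in range(len(pop.cells)) if alive[j]]
                if live and (hgt_mode == "pool" or len(live) > 1):
                    sub = [pop.cells[j] for j in live]
                    for j in live:
                        compiled[j].writeback()
                    snaps = [c.copy() for c in sub] if record_fitness else None
                    events = hgt_mod.hgt_step(
                        sub, hgt_rate, frag_model, rng,
                        pool=frag_pool if hgt_mode == "pool" else None,
                        n_steps=segment_len)
                    for k, frag in events:
                        _record(epoch_events, [("hgt", frag.size)], pop.epoch, start,
                                snaps[k] if record_fitness else None, sub[k],
                                env, rng, record_fitness)
                        recompiled(live[k])

            # divisions: daughters replace low-energy competitors
            for i, half_energy in pending_div:
                if not alive[i]:
                    continue
                compiled[i].writeback()
                daughter = pop.cells[i].copy(fresh_id=True)
                daughter.energy = half_energy
                victim = _replacement_index(pop, rng, exclude=i)
                pop.cells[victim] = daughter
                alive[victim] = True
                # daughter's live trace so far is the parent's (it is a copy)
                rp0[victim, :start + segment_len] = rp0[i, :start + segment_len]
                recompiled(victim)
                n_div += 1

            # deaths: energy-exhausted cells restart as fresh random cells
            for i in np.flatnonzero(~alive):
                pop.cells[int(i)] = sample_random_cell(init, rng)
                rp0[int(i), :start + segment_len] = 0
                recompiled(int(i))
                alive[i] = True
                n_dead += 1

        from .analysis import _clamped_pearson  # local import avoids a cycle

        ws = np.array([_clamped_pearson(rp0[i].astype(float), nut)
                       for i in range(len(pop.cells))])
        traj.rows.append({"epoch": pop.epoch, "max_fitness": float(ws.max()),
                          "mean_fitness": float(ws.mean()),
                          "divisions": n_div, "deaths": n_dead,
                          "events": len(epoch_events)})
        traj.events.extend(epoch_events)
        pop.epoch += 1
    for i in compiled:
        compiled[i].writeback()
    return traj


def _record(out: list, evs, epoch: int, step: int, before_cell, after_cell,
            env, rng, record_fitness: bool) -> None:
    """Append event records; before/after fitness measured on clones in a
    frozen environment when requested (events in one segment share the pair
    of measurements)."""
    from .analysis import EPS_BEFORE, EventRecord, fitness

    w_before = w_after = None
    if record_fitness:
        w_before = fitness(before_cell, env, rng).w
        w_after = fitness(after_cell, env, rng).w
    for ev in evs:
        if isinstance(ev, tuple):
            etype, locus = ev[0], f"fragment size {ev[1]}"
        else:
            etype, locus = ev.type, ev.locus
        rec = EventRecord(epoch=epoch, step=step, type=etype, locus=locus,
                          w_before=float("nan") if w_before is None else w_before,
                          w_after=w_after,
                          excluded=(w_before is not None and w_before < EPS_BEFORE))
        out.append(rec)
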