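"""Domain types for cells and their regulatory networks.

A cell's genome is a collection of *triplets* — gene/mRNA, protein and
modified-protein nodes capturing transcription, translation and
post-translational modification — plus a set of weighted, signed regulatory
edges between nodes (or from one of the two external signals S1/S2 onto a
node).  Every cell carries exactly one metabolic triplet T0 whose
modified-protein node is the RP_0 readout: its expression while nutrients are
present is what earns the cell energy.

This module holds the data model, the random-cell generator used to build
unevolved populations, network union, validation and JSON serialization.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Union

import numpy as np

SIGNALS = ("S1", "S2")

_cell_ids = itertools.count(1)


class NodeKind(str, Enum):
    """The three node types of a triplet."""

    GENE_MRNA = "mrna"
    PROTEIN = "protein"
    MODIFIED_PROTEIN = "modified"


KIND_ORDER = (NodeKind.GENE_MRNA, NodeKind.PROTEIN, NodeKind.MODIFIED_PROTEIN)

#: a node is addressed as (triplet id, kind); an edge source may also be a signal
NodeRef = tuple  # (int, NodeKind)
SourceRef = Union[str, tuple]


class CellInvariantError(ValueError):
    """A cell violates one of its structural invariants."""


@dataclass
class Node:
    kind: NodeKind
    value: int = 0
    basal: float = 0.0
    m_self: float = 0.0
    s_self: float = 1.0
    degr: float = 0.05

    def copy(self) -> "Node":
        return Node(self.kind, self.value, self.basal, self.m_self, self.s_self, self.degr)


@dataclass
class Edge:
    """Directed regulatory interaction.

    ``source`` is either a (triplet id, NodeKind) pair or one of the external
    signal ids "S1"/"S2"; ``target`` is always a node reference.  ``w`` is the
    signed regulatory weight, ``m_reg``/``s_reg`` the midpoint and slope of the
    regulator-specific sigmoid applied to the source's molecule count.
    """

    source: SourceRef
    target: NodeRef
    w: float
    m_reg: float
    s_reg: float

    @property
    def key(self) -> tuple:
        return (self.source, self.target)

    def copy(self) -> "Edge":
        return Edge(self.source, self.target, self.w, self.m_reg, self.s_reg)


@dataclass
class Triplet:
    id: int
    nodes: list  # [mrna, protein, modified] in KIND_ORDER
    is_metabolic: bool = False

    def node(self, kind: NodeKind) -> Node:
        return self.nodes[KIND_ORDER.index(kind)]

    def copy(self, new_id: int | None = None) -> "Triplet":
        return Triplet(self.id if new_id is None else new_id,
                       [n.copy() for n in self.nodes], self.is_metabolic)


@dataclass
class InitConfig:
    """Parameter ranges used to draw random unevolved cells."""

    max_triplets: int = 15
    sparsity_range: tuple = (0.0, 0.2)
    basal_range: tuple = (0.0, 0.5)
    m_self_range: tuple = (-1.0, 1.0)
    s_self_range: tuple = (1.0, 4.0)
    m_reg_range: tuple = (0.0, 10.0)
    s_reg_range: tuple = (1.0, 4.0)
    degr_range: tuple = (0.01, 0.1)
    weight_exponent: float = 1.5
    weight_tail_at: float = 4.0
    weight_tail_p: float = 0.1
    weight_cap: float = 100.0
    initial_energy: float = 800_000.0

    @property
    def weight_min(self) -> float:
        """Lower cutoff of the |w| power law, fixed by P(|w| > tail_at) = tail_p."""
        a = self.weight_exponent
        return self.weight_tail_at * self.weight_tail_p ** (1.0 / (a - 1.0))


DEFAULT_INIT = InitConfig()


@dataclass
class Cell:
    triplets: list = field(default_factory=list)  # T0 first
    edges: dict = field(default_factory=dict)  # key -> Edge
    energy: float = 800_000.0
    id: int = 0
    parent_id: int | None = None

    # -- structure helpers -------------------------------------------------
    @property
    def t0(self) -> Triplet:
        return self.triplets[0]

    @property
    def n_nodes(self) -> int:
        return 3 * len(self.triplets)

    def triplet_by_id(self, tid: int) -> Triplet:
        for t in self.triplets:
            if t.id == tid:
                return t
        raise KeyError(f"no triplet with id {tid}")

    def node_refs(self) -> list:
        return [(t.id, k) for t in self.triplets for k in KIND_ORDER]

    def node(self, ref: NodeRef) -> Node:
        tid, kind = ref
        return self.triplet_by_id(tid).node(NodeKind(kind))

    def add_edge(self, edge: Edge) -> None:
        """Insert an edge, replacing any existing edge on the same (source, target)."""
        self.edges[edge.key] = edge

    def remove_triplet(self, tid: int) -> None:
        t = self.triplet_by_id(tid)
        if t.is_metabolic:
            raise CellInvariantError("the metabolic triplet T0 cannot be removed")
        self.triplets.remove(t)
        dead = {(tid, k) for k in KIND_ORDER}
        self.edges = {k: e for k, e in self.edges.items()
                      if e.target not in dead and e.source not in dead}

    def next_triplet_id(self) -> int:
        return max(t.id for t in self.triplets) + 1

    def copy(self, fresh_id: bool = False) -> "Cell":
        c = Cell([t.copy() for t in self.triplets],
                 {k: e.copy() for k, e in self.edges.items()},
                 self.energy,
                 next(_cell_ids) if fresh_id else self.id,
                 self.id if fresh_id else self.parent_id)
        return c


def sample_weight(rng: np.random.Generator, size=None, init: InitConfig = DEFAULT_INIT):
    """Draw signed regulatory weights.

    |w| follows a power law with density ∝ |w|^(-a) (a = 1.5) above a lower
    cutoff fixed so that P(|w| > 4) = 0.10; magnitudes are capped at
    ``weight_cap`` (clipping, so the printed tail probability is preserved).
    The sign is equiprobable.
    """
    a = init.weight_exponent
    u = rng.random(size)
    mag = init.weight_min * u ** (-1.0 / (a - 1.0))
    mag = np.minimum(mag, init.weight_cap)
    sign = np.where(rng.random(size) < 0.5, -1.0, 1.0)
    out = sign * mag
    return float(out) if size is None else out


def _random_node(kind: NodeKind, init: InitConfig, rng: np.random.Generator) -> Node:
    return Node(kind=kind, value=0,
                basal=rng.uniform(*init.basal_range),
                m_self=rng.uniform(*init.m_self_range),
                s_self=rng.uniform(*init.s_self_range),
                degr=rng.uniform(*init.degr_range))


def random_triplet(tid: int, init: InitConfig, rng: np.random.Generator,
                   is_metabolic: bool = False) -> Triplet:
    return Triplet(tid, [_random_node(k, init, rng) for k in KIND_ORDER], is_metabolic)


def _random_edge_params(init: InitConfig, rng: np.random.Generator) -> tuple:
    return (sample_weight(rng, init=init),
            rng.uniform(*init.m_reg_range),
            rng.uniform(*init.s_reg_range))


def sample_random_cell(init: InitConfig = DEFAULT_INIT,
                       rng: np.random.Generator | None = None) -> Cell:
    """Generate one random unevolved cell.

    The cell carries the metabolic triplet T0 plus 1..max_triplets random
    triplets.  Total edge count is drawn from the sparsity range (fraction of
    all (source, target) pairs, signals counted as sources); signal edges are
    attached first with probability ∝ exp(-n) where n is the number of nodes
    already signal-regulated, the remainder is wired uniformly at random.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_extra = int(rng.integers(1, init.max_triplets + 1))
    triplets = [random_triplet(0, init, rng, is_metabolic=True)]
    triplets += [random_triplet(i, init, rng) for i in range(1, n_extra + 1)]
    cell = Cell(triplets=triplets, energy=init.initial_energy, id=next(_cell_ids))

    refs = cell.node_refs()
    n_nodes = len(refs)
    n_possible = (n_nodes + 2) * n_nodes
    sparsity = rng.uniform(*init.sparsity_range)
    n_edges = int(round(sparsity * n_possible))

    # signal attachment: each additional connection accepted w.p. exp(-n)
    unattached = list(range(n_nodes))
    n_sig = 0
    while n_sig < n_edges and unattached:
        if rng.random() >= math.exp(-n_sig):
            break
        sig = SIGNALS[int(rng.integers(2))]
        node_i = unattached.pop(int(rng.integers(len(unattached))))
        w, m, s = _random_edge_params(init, rng)
        cell.add_edge(Edge(sig, refs[node_i], w, m, s))
        n_sig += 1

    sources: list = list(refs) + list(SIGNALS)
    while len(cell.edges) < n_edges:
        src = sources[int(rng.integers(len(sources)))]
        tgt = refs[int(rng.integers(n_nodes))]
        if (src, tgt) in cell.edges:
            continue
        w, m, s = _random_edge_params(init, rng)
        cell.add_edge(Edge(src, tgt, w, m, s))
    return cell


def union_networks(a: Cell, b: Cell, init: InitConfig = DEFAULT_INIT) -> Cell:
    """Merge two cells into one: all triplets and edges of both, with the two
    metabolic triplets collapsed onto ``a``'s T0 (edges touching ``b``'s T0 are
    remapped).  The union starts with fresh initial energy.
    """
    new = Cell(energy=init.initial_energy, id=next(_cell_ids))
    amap: dict = {}
    bmap: dict = {}
    nid = 0
    for t in a.triplets:
        amap[t.id] = nid
        new.triplets.append(t.copy(new_id=nid))
        nid += 1
    for t in b.triplets:
        if t.is_metabolic:
            bmap[t.id] = amap[a.t0.id]
            continue
        bmap[t.id] = nid
        new.triplets.append(replace(t.copy(new_id=nid), is_metabolic=False))
        nid += 1

    def remap(ref: SourceRef, m: dict) -> SourceRef:
        if isinstance(ref, str):
            return ref
        tid, kind = ref
        return (m[tid], kind)

    for e in a.edges.values():
        new.add_edge(Edge(remap(e.source, amap), remap(e.target, amap), e.w, e.m_reg, e.s_reg))
    for e in b.edges.values():
        key = (remap(e.source, bmap), remap(e.target, bmap))
        if key in new.edges:  # keep a's edge on conflict
            continue
        new.add_edge(Edge(key[0], key[1], e.w, e.m_reg, e.s_reg))
    return new


# -- validation -----------------------------------------------------------

def validate_cell(cell: Cell) -> None:
    """Raise CellInvariantError if any structural invariant is violated."""
    if not cell.triplets:
        raise CellInvariantError("cell has no triplets")
    metabolic = [t for t in cell.triplets if t.is_metabolic]
    if len(metabolic) != 1:
        raise CellInvariantError(f"expected exactly one metabolic triplet, found {len(metabolic)}")
    if not cell.triplets[0].is_metabolic:
        raise CellInvariantError("metabolic triplet must be first")
    ids = [t.id for t in cell.triplets]
    if len(set(ids)) != len(ids):
        raise CellInvariantError("duplicate triplet ids")
    if cell.energy < 0:
        raise CellInvariantError("negative energy")
    refs = set(cell.node_refs())
    for t in cell.triplets:
        if len(t.nodes) != 3 or tuple(n.kind for n in t.nodes) != KIND_ORDER:
            raise CellInvariantError(f"triplet {t.id} does not have one node of each kind")
        for n in t.nodes:
            if n.value < 0:
                raise CellInvariantError(f"negative molecule count in triplet {t.id}")
            if not (0.0 <= n.basal <= 1.0):
                raise CellInvariantError(f"basal out of [0,1] in triplet {t.id}")
            if n.s_self <= 0:
                raise CellInvariantError(f"s_self <= 0 in triplet {t.id}")
            if n.degr <= 0:
                raise CellInvariantError(f"degr <= 0 in triplet {t.id}")
    for key, e in cell.edges.items():
        if key != (e.source, e.target):
            raise CellInvariantError("edge stored under wrong key")
        if e.s_reg <= 0:
            raise CellInvariantError("s_reg <= 0")
        if e.m_reg < 0:
            raise CellInvariantError("m_reg < 0")
        if isinstance(e.source, str):
            if e.source not in SIGNALS:
                raise CellInvariantError(f"unknown signal source {e.source!r}")
        elif tuple(e.source) not in refs:
            raise CellInvariantError(f"dangling edge source {e.source}")
        if tuple(e.target) not in refs:
            raise CellInvariantError(f"dangling edge target {e.target}")


# -- serialization (JSON, schema 1) ---------------------------------------

def _ref_to_json(ref: SourceRef):
    return ref if isinstance(ref, str) else [ref[0], NodeKind(ref[1]).value]


def _ref_from_json(obj):
    if isinstance(obj, str):
        if obj not in SIGNALS:
            raise ValueError(f"bad signal id {obj!r}")
        return obj
    return (int(obj[0]), NodeKind(obj[1]))


def save_cell(cell: Cell) -> dict:
    """Serialize a cell to a JSON-ready dict (versioned schema)."""
    return {
        "schema": 1,
        "id": cell.id,
        "parent_id": cell.parent_id,
        "energy": cell.energy,
        "triplets": [
            {"id": t.id, "is_metabolic": t.is_metabolic,
             "nodes": [{"kind": n.kind.value, "value": n.value, "basal": n.basal,
                        "m_self": n.m_self, "s_self": n.s_self, "degr": n.degr}
                       for n in t.nodes]}
            for t in cell.triplets],
        "edges": [
            {"source": _ref_to_json(e.source), "target": _ref_to_json(e.target),
             "w": e.w, "m_reg": e.m_reg, "s_reg": e.s_reg}
            for e in cell.edges.values()],
    }


def load_cell(record: dict) -> Cell:
    """Rebuild a cell from its serialized record; validates invariants."""
    try:
        if record.get("schema") != 1:
            raise ValueError(f"unsupported schema {record.get('schema')!r}")
        triplets = []
        for t in record["triplets"]:
            nodes = [Node(NodeKind(n["kind"]), int(n["value"]), float(n["basal"]),
                          float(n["m_self"]), float(n["s_self"]), float(n["degr"]))
                     for n in t["nodes"]]
            triplets.append(Triplet(int(t["id"]), nodes, bool(t["is_metabolic"])))
        cell = Cell(triplets=triplets, energy=float(record["energy"]),
                    id=int(record["id"]),
                    parent_id=None if record.get("parent_id") is None else int(record["parent_id"]))
        for e in record["edges"]:
            cell.add_edge(Edge(_ref_from_json(e["source"]), _ref_from_json(e["target"]),
                               float(e["w"]), float(e["m_reg"]), float(e["s_reg"])))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed cell record: {exc}") from exc
    if not any(t.is_metabolic for t in cell.triplets):
        raise ValueError("malformed cell record: no metabolic triplet")
    validate_cell(cell)
    return cell


def save_population(cells: Iterable[Cell], path) -> None:
    with open(path, "w") as fh:
        json.dump([save_cell(c) for c in cells], fh)


def load_population(path) -> list:
    with open(path) as fh:
        return [load_cell(rec) for rec in json.load(fh)]


def cells_equal(a: Cell, b: Cell) -> bool:
    """Structural equality, ignoring cell identity."""
    return (save_cell(a) | {"id": 0, "parent_id": None}) == (save_cell(b) | {"id": 0, "parent_id": None})
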