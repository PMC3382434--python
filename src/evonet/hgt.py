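"""Horizontal gene transfer: fragment-size law, extraction, integration.

A transfer copies a random subset of a donor's non-metabolic triplets into a
recipient, preserving the fragment's internal wiring, its incoming signal
edges, and its regulation of (and by) the metabolic triplet T0 — remapped onto
the recipient's T0.  No other cross-edges are created at integration time;
coupling to the rest of the recipient network can only arise later through
mutation.

Fragment sizes follow the normalized sigmoid density

    p(x) ∝ 1 - tanh((x - m)/s),   x >= 0,

whose normalization constant is Z = 2m + s·ln(1 + e^(-2m/s)).  With s = m the
continuous CDF at x = m is (1 + ln cosh 1) / (2 + ln(1 + e^-2)) ≈ 0.67, i.e.
two thirds of transferred fragments are no larger than m triplets.  Actual
draws use the discrete renormalized pmf on 1..support_max, truncated to the
donor's size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netmodel import Cell, Edge, Triplet, validate_cell


@dataclass
class FragmentSizeModel:
    m: float = 5.0
    s: float = 5.0
    support_max: int = 20

    def __post_init__(self):
        if self.m <= 0 or self.s <= 0:
            raise ValueError("m and s must be > 0")
        if self.support_max < 1:
            raise ValueError("support_max must be >= 1")

    # -- continuous closed form (x >= 0) ----------------------------------
    @property
    def normalization(self) -> float:
        """Z = ∫_0^∞ (1 - tanh((x-m)/s)) dx = 2m + s ln(1 + e^(-2m/s))."""
        return 2.0 * self.m + self.s * math.log1p(math.exp(-2.0 * self.m / self.s))

    def cdf(self, x: float) -> float:
        """Continuous CDF; antiderivative of the density is (x - s ln cosh((x-m)/s))/Z."""
        if x <= 0:
            return 0.0
        f = lambda y: y - self.s * math.log(math.cosh((y - self.m) / self.s))
        return min(1.0, (f(x) - f(0.0)) / self.normalization)

    def mean(self) -> float:
        """Continuous expectation ∫ x p(x) dx (numerical quadrature)."""
        from scipy.integrate import quad

        hi = self.m + 40.0 * self.s
        val, _ = quad(lambda x: x * (1.0 - math.tanh((x - self.m) / self.s)),
                      0.0, hi, limit=200)
        return val / self.normalization


def fragment_size_pmf(model: FragmentSizeModel, support_max: int | None = None) -> np.ndarray:
    """Discrete renormalized pmf over n = 1..support_max (index 0 ↔ n = 1)."""
    smax = model.support_max if support_max is None else support_max
    if smax < 1:
        raise ValueError("support_max must be >= 1")
    n = np.arange(1, smax + 1, dtype=float)
    raw = 1.0 - np.tanh((n - model.m) / model.s)
    return raw / raw.sum()


def sample_fragment_size(model: FragmentSizeModel, donor_size: int,
                         rng: np.random.Generator) -> int:
    """Draw a size from the pmf truncated and renormalized to 1..donor_size."""
    if donor_size < 1:
        raise ValueError("donor has no transferable triplets")
    pmf = fragment_size_pmf(model, min(model.support_max, donor_size))
    return int(rng.choice(len(pmf), p=pmf)) + 1


@dataclass
class Fragment:
    """A copied sub-network: triplets, their internal edges, their edges
    to/from the donor's T0, and incoming signal edges."""

    triplets: list = field(default_factory=list)
    internal_edges: list = field(default_factory=list)
    t0_edges: list = field(default_factory=list)   # with T0 side tagged as tid "T0"
    signal_edges: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.triplets)


T0_TAG = -1  # stand-in triplet id for "the recipient's T0" inside a fragment


def extract_fragment(donor: Cell, size: int, rng: np.random.Generator,
                     keep_t0_to_fragment: bool = True) -> Fragment:
    """Copy ``size`` uniformly chosen non-metabolic triplets out of the donor.

    Edges between fragment triplets, edges onto/from the donor's T0 and
    incoming signal edges are kept; all other edges dangle and are dropped.
    ``keep_t0_to_fragment`` controls whether edges *from* T0 into the fragment
    are preserved alongside the fragment's regulation of T0.
    """
    pool = [t for t in donor.triplets if not t.is_metabolic]
    if not 1 <= size <= len(pool):
        raise ValueError(f"fragment size {size} out of range 1..{len(pool)}")
    chosen = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
    ids = {t.id for t in chosen}
    t0_id = donor.t0.id
    frag = Fragment(triplets=[t.copy() for t in chosen])

    def tag(ref):
        return (T0_TAG, ref[1]) if ref[0] == t0_id else tuple(ref)

    for e in donor.edges.values():
        src_sig = isinstance(e.source, str)
        src_in = not src_sig and e.source[0] in ids
        tgt_in = e.target[0] in ids
        copy = Edge(e.source if src_sig else tag(e.source), tag(e.target),
                    e.w, e.m_reg, e.s_reg)
        if src_in and tgt_in:
            frag.internal_edges.append(copy)
        elif src_sig and tgt_in:
            frag.signal_edges.append(copy)
        elif src_in and e.target[0] == t0_id:
            frag.t0_edges.append(copy)
        elif tgt_in and not src_sig and e.source[0] == t0_id and keep_t0_to_fragment:
            frag.t0_edges.append(copy)
    return frag


def integrate_fragment(recipient: Cell, frag: Fragment) -> Cell:
    """Append the fragment to the recipient in place (fresh triplet ids),
    remapping T0-tagged edge endpoints onto the recipient's T0."""
    if not frag.triplets:
        return recipient
    base = recipient.next_triplet_id()
    idmap = {t.id: base + i for i, t in enumerate(frag.triplets)}
    idmap[T0_TAG] = recipient.t0.id
    for t in frag.triplets:
        recipient.triplets.append(t.copy(new_id=idmap[t.id]))
    for e in frag.internal_edges + frag.t0_edges + frag.signal_edges:
        src = e.source if isinstance(e.source, str) else (idmap[e.source[0]], e.source[1])
        tgt = (idmap[e.target[0]], e.target[1])
        recipient.add_edge(Edge(src, tgt, e.w, e.m_reg, e.s_reg))
    return recipient


def transfer(donor: Cell, recipient: Cell, model: FragmentSizeModel,
             rng: np.random.Generator) -> Fragment | None:
    """One pairwise HGT event: sample a size, extract from donor, integrate."""
    pool = len(donor.triplets) - 1
    if pool < 1:
        return None
    size = sample_fragment_size(model, pool, rng)
    frag = extract_fragment(donor, size, rng)
    integrate_fragment(recipient, frag)
    return frag


def hgt_step(cells: list, rate: float, model: FragmentSizeModel,
             rng: np.random.Generator, pool: list | None = None,
             n_steps: int = 1) -> list:
    """Apply HGT events across a population for ``n_steps`` time steps.

    Each cell independently receives a transfer with probability ``rate`` per
    step; the donor is a uniformly chosen other cell (pairwise mode) or a
    fragment from ``pool`` (naked-DNA mode).  Returns (recipient index,
    fragment) pairs for the events applied.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    events = []
    if rate == 0.0 or len(cells) < 2 and pool is None:
        return events
    p_any = 1.0 - (1.0 - rate) ** n_steps
    hits = np.flatnonzero(rng.random(len(cells)) < p_any)
    for i in hits:
        if pool is not None:
            frag = pool[int(rng.integers(len(pool)))]
            take = Fragment([t.copy() for t in frag.triplets],
                            [e.copy() for e in frag.internal_edges],
                            [e.copy() for e in frag.t0_edges],
                            [e.copy() for e in frag.signal_edges])
            integrate_fragment(cells[i], take)
            events.append((int(i), take))
        else:
            j = int(rng.integers(len(cells) - 1))
            j = j if j < i else j + 1
            frag = transfer(cells[j], cells[i], model, rng)
            if frag is not None:
                events.append((int(i), frag))
    return events


# -- fragment serialization ------------------------------------------------

def save_fragment(frag: Fragment) -> dict:
    def enc_edge(e: Edge):
        src = e.source if isinstance(e.source, str) else [e.source[0], e.source[1].value]
        return {"source": src, "target": [e.target[0], e.target[1].value],
                "w": e.w, "m_reg": e.m_reg, "s_reg": e.s_reg}

    return {"schema": 1,
            "triplets": [{"id": t.id,
                          "nodes": [{"kind": n.kind.value, "value": n.value,
                                     "basal": n.basal, "m_self": n.m_self,
                                     "s_self": n.s_self, "degr": n.degr}
                                    for n in t.nodes]}
                         for t in frag.triplets],
            "internal_edges": [enc_edge(e) for e in frag.internal_edges],
            "t0_edges": [enc_edge(e) for e in frag.t0_edges],
            "signal_edges": [enc_edge(e) for e in frag.signal_edges]}


def load_fragment(record: dict) -> Fragment:
    from .netmodel import Node, NodeKind

    def dec_ref(obj):
        return obj if isinstance(obj, str) else (int(obj[0]), NodeKind(obj[1]))

    def dec_edge(d):
        return Edge(dec_ref(d["source"]), dec_ref(d["target"]),
                    float(d["w"]), float(d["m_reg"]), float(d["s_reg"]))

    triplets = [Triplet(int(t["id"]),
                        [Node(NodeKind(n["kind"]), int(n["value"]), float(n["basal"]),
                              float(n["m_self"]), float(n["s_self"]), float(n["degr"]))
                         for n in t["nodes"]])
                for t in record["triplets"]]
    return Fragment(triplets,
                    [dec_edge(e) for e in record["internal_edges"]],
                    [dec_edge(e) for e in record["t0_edges"]],
                    [dec_edge(e) for e in record["signal_edges"]])
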