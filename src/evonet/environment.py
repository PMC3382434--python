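"""Deterministic environments: two square-wave signals and a delayed-gate
nutrient schedule.

One epoch (default 4,500 steps) is split into four equal windows cycling the
signal combinations (0,0), (1,0), (1,1), (0,1).  Nutrient presence is a
boolean gate of the *delayed* signals, N(t) = gate(s1(t-d), s2(t-d)) with
periodic wrap-around:

    A   : s1 AND NOT s2
    B   : NOT s1 AND s2
    XOR : s1 XOR s2

XOR is not linearly separable in (s1, s2), which is what makes the combined
environment qualitatively harder than A or B alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPOCH_LEN = 4500

GATES = {
    "A": lambda s1, s2: s1 & ~s2,
    "B": lambda s1, s2: ~s1 & s2,
    "XOR": lambda s1, s2: s1 ^ s2,
}

#: order in which the four signal combinations cycle within an epoch
WINDOW_ORDER = ((0, 0), (1, 0), (1, 1), (0, 1))


class EnvironmentConfigError(ValueError):
    pass


@dataclass
class Environment:
    kind: str
    epoch_len: int = EPOCH_LEN
    delay: int = 300
    window_len: int = EPOCH_LEN // 4
    s1: np.ndarray = field(repr=False, default=None)
    s2: np.ndarray = field(repr=False, default=None)
    nutrient: np.ndarray = field(repr=False, default=None)

    def state(self, t: int) -> dict:
        i = t % self.epoch_len
        return {"s1": int(self.s1[i]), "s2": int(self.s2[i]),
                "nutrient": int(self.nutrient[i])}

    def to_config(self) -> dict:
        return {"kind": self.kind, "epoch_len": self.epoch_len,
                "delay": self.delay, "window_len": self.window_len}


def make_environment(kind: str, epoch_len: int = EPOCH_LEN, delay: int = 300,
                     window_len: int | None = None) -> Environment:
    """Build an environment with square-wave signals and delayed-gate nutrients."""
    if kind not in GATES:
        raise EnvironmentConfigError(f"unknown environment kind {kind!r}")
    if window_len is None:
        window_len = epoch_len // 4
    if epoch_len % window_len:
        raise EnvironmentConfigError("epoch_len must be divisible by window_len")
    if not (0 <= delay < window_len):
        raise EnvironmentConfigError("need 0 <= delay < window_len")
    n_windows = epoch_len // window_len
    t = np.arange(epoch_len)
    widx = (t // window_len) % len(WINDOW_ORDER)
    order = np.array(WINDOW_ORDER, dtype=bool)
    s1 = order[widx % len(WINDOW_ORDER), 0][:n_windows * window_len]
    s2 = order[widx % len(WINDOW_ORDER), 1][:n_windows * window_len]
    gate = GATES[kind](s1, s2)
    nutrient = np.roll(gate, delay)  # periodic delayed image
    return Environment(kind, epoch_len, delay, window_len,
                       s1=s1.astype(np.int8), s2=s2.astype(np.int8),
                       nutrient=nutrient.astype(np.int8))


def env_state(env: Environment, t: int) -> dict:
    return env.state(t)


def environment_from_config(cfg: dict) -> Environment:
    return make_environment(cfg["kind"], cfg.get("epoch_len", EPOCH_LEN),
                            cfg.get("delay", 300), cfg.get("window_len"))
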