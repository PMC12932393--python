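"""Small shared numerics: logit transforms, BH adjustment, seed streaming."""

from __future__ import annotations

import numpy as np


def logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


class SeedStream:
    """Deterministic per-component RNG streams from one root seed.

    Children are spawned in call order via an internal counter, so every
    generator in a run is reproducible from the single root integer.
    """

    def __init__(self, seed: int):
        self.root = int(seed)
        self._counter = 0
        self.log: list[tuple[int, str]] = []

    def child(self, name: str) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.root, spawn_key=(self._counter,))
        self.log.append((self._counter, name))
        self._counter += 1
        return np.random.Generator(np.random.PCG64(ss))
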