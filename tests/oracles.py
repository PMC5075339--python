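"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's dynamic-programming
implementations: likelihoods are computed by exhaustive enumeration of
all state paths through the ipHMM state graph.
"""

from __future__ import annotations

import numpy as np

from cmiphmm.alphabet import AA_INDEX
from cmiphmm.iphmm import IpHMM


def enumerate_path_likelihood(model: IpHMM, seq: str) -> float:
    """P(seq | model) by summing the probability of every Begin->End state
    path that emits the sequence exactly.  Exponential in sequence
    length; only usable for tiny models."""
    sp = model.space
    x = [AA_INDEX[ch] for ch in seq]
    n = len(x)
    emitting = sp.emitting
    succs = {}
    for a, b in sp.allowed_arcs():
        succs.setdefault(a, []).append(b)

    total = 0.0

    def walk(state: int, emitted: int, prob: float) -> None:
        nonlocal total
        if state == sp.END:
            if emitted == n:
                total += prob
            return
        for nxt in succs.get(state, []):
            p = model.T[state, nxt]
            if p == 0.0:
                continue
            if emitting[nxt]:
                if emitted == n:
                    continue
                e = model.E[nxt, x[emitted]]
                if e > 0.0:
                    walk(nxt, emitted + 1, prob * p * e)
            else:
                walk(nxt, emitted, prob * p)

    walk(sp.B, 0, 1.0)
    return total


def random_model(L: int, rng: np.random.Generator) -> IpHMM:
    """A random fully-connected ipHMM with Dirichlet-distributed rows."""
    from cmiphmm.iphmm import StateSpace

    space = StateSpace(L)
    S = space.n_states
    T = np.zeros((S, S))
    arcs_by_src: dict[int, list[int]] = {}
    for a, b in space.allowed_arcs():
        arcs_by_src.setdefault(a, []).append(b)
    for src, dests in arcs_by_src.items():
        T[src, dests] = rng.dirichlet(np.ones(len(dests)))
    E = np.zeros((S, 20))
    for s in np.flatnonzero(space.emitting):
        E[int(s)] = rng.dirichlet(np.full(20, 0.8))
    return IpHMM(n_match=L, T=T, E=E)
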