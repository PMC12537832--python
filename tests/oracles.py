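"""Brute-force oracles kept independent of the implementation paths."""

from collections import deque

import numpy as np

_OFFSETS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def flood_fill_components(mask):
    """26-connectivity components of a boolean volume by breadth-first
    search; returns a list of voxel-index lists."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        comp = []
        while q:
            v = q.popleft()
            comp.append(v)
            for off in _OFFSETS:
                w = tuple(np.add(v, off))
                if (
                    all(0 <= w[d] < mask.shape[d] for d in range(3))
                    and mask[w]
                    and not seen[w]
                ):
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def bh_step_up(p):
    """Benjamini-Hochberg adjusted p-values computed by the step-up
    recursion directly."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
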