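"""Shared test utilities: random masks and the independent geodesic oracle."""

import numpy as np


def random_connected_mask(rng, shape=(64, 64), n_grow=400):
    """Random blobby connected mask grown pixel by pixel from the centre."""
    mask = np.zeros(shape, dtype=bool)
    r, c = shape[0] // 2, shape[1] // 2
    mask[r, c] = True
    frontier = [(r, c)]
    for _ in range(n_grow):
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        nr = int(np.clip(r + dr, 0, shape[0] - 1))
        nc = int(np.clip(c + dc, 0, shape[1] - 1))
        if not mask[nr, nc]:
            mask[nr, nc] = True
            frontier.append((nr, nc))
    return mask


def networkx_geodesic(mask, p1, p2):
    """Independent oracle: Dijkstra on an explicit 8-connected pixel graph
    with weights 1 (axial) and sqrt(2) (diagonal)."""
    import networkx as nx

    g = nx.Graph()
    ys, xs = np.nonzero(mask)
    pix = set(zip(ys.tolist(), xs.tolist()))
    for (y, x) in pix:
        g.add_node((y, x))
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                n = (y + dy, x + dx)
                if n in pix:
                    g.add_edge((y, x), n, weight=float(np.hypot(dy, dx)))
    return nx.dijkstra_path_length(g, tuple(p1), tuple(p2))
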