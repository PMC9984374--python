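"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (exhaustive enumeration, direct
formulas, dense linear algebra) kept separate from the package code paths
they validate.
"""

from __future__ import annotations

import numpy as np


def fps_bruteforce(X: np.ndarray, n_select: int, start: int = 0) -> list:
    """Greedy max-min selection by exhaustive O(n^2) scanning."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    selected = [start]
    for _ in range(1, n_select):
        best_i, best_d = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            d = min(np.linalg.norm(X[i] - X[j]) for j in selected)
            if d > best_d + 1e-15:
                best_d, best_i = d, i
        selected.append(best_i)
    return selected


def quickshift_bruteforce(points, density, bandwidths, alpha):
    """Steepest-ascent assignment: follow nearest strictly-higher-density
    neighbour within alpha * bandwidth until a mode is reached."""
    points = np.asarray(points, dtype=float)
    G = points.shape[0]
    parent = np.full(G, -1)
    for i in range(G):
        best, best_d = -1, np.inf
        for j in range(G):
            if density[j] <= density[i]:
                continue
            d = np.linalg.norm(points[i] - points[j])
            if d <= alpha * bandwidths[i] and d < best_d - 1e-15:
                best, best_d = j, d
        parent[i] = best
    labels = np.empty(G, dtype=int)
    for i in range(G):
        r = i
        while parent[r] != -1:
            r = parent[r]
        labels[i] = r
    # relabel by root order
    roots = sorted(set(labels))
    remap = {r: c for c, r in enumerate(roots)}
    return np.array([remap[r] for r in labels]), parent


def ward_merge_bruteforce(centroids, sizes, adjacency):
    """Exhaustive Ward agglomeration restricted to an adjacency relation.

    ``adjacency`` maps cluster key -> set of adjacent keys; merged clusters
    take the key min(a, b) and the union of neighbours.  Returns the list
    of merges as (node_a, node_b, height) with scipy-style node numbering.
    """
    k = len(sizes)
    active = {i: (np.asarray(centroids[i], float), float(sizes[i]))
              for i in range(k)}
    adj = {i: set(adjacency[i]) for i in range(k)}
    node_of = {i: i for i in range(k)}
    merges = []
    nxt = k
    last_h = 0.0
    while len(active) > 1:
        keys = sorted(active)
        pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]
                 if b in adj[a]]
        if not pairs:
            pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
        best = None
        for a, b in pairs:
            ca, na = active[a]
            cb, nb = active[b]
            d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        h = max(d, last_h)
        last_h = h
        ca, na = active.pop(a)
        cb, nb = active.pop(b)
        merges.append((node_of[a], node_of[b], h))
        key = min(a, b)
        active[key] = ((na * ca + nb * cb) / (na + nb), na + nb)
        node_of[key] = nxt
        nxt += 1
        neigh = (adj[a] | adj[b]) - {a, b}
        adj[key] = neigh
        for c in adj:
            if a in adj[c]:
                adj[c].discard(a)
                adj[c].add(key)
            if b in adj[c]:
                adj[c].discard(b)
                adj[c].add(key)
        adj[key].discard(key)
    return merges


def triplets_bruteforce(coords, species, cutoff=4.5, min_sep=3):
    """All N-H...O triplets by cubic-loop enumeration with an independent
    bond-graph (Floyd-Warshall shortest paths)."""
    coords = np.asarray(coords, dtype=float)
    n = len(species)
    D = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    INF = 10**6
    sep = np.full((n, n), INF)
    np.fill_diagonal(sep, 0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lim = 1.3 if ("H" in (species[i], species[j])) else 1.8
            if D[i, j] < lim:
                sep[i, j] = 1
    for m in range(n):
        for i in range(n):
            for j in range(n):
                if sep[i, m] + sep[m, j] < sep[i, j]:
                    sep[i, j] = sep[i, m] + sep[m, j]
    out = []
    for d in range(n):
        if species[d] != "N":
            continue
        for h in range(n):
            if species[h] != "H" or D[d, h] >= 1.3:
                continue
            for a in range(n):
                if species[a] != "O" or D[d, a] > cutoff:
                    continue
                if sep[d, a] < min_sep:
                    continue
                out.append((d, h, a, D[d, h], D[a, h], D[d, a]))
    return out


def pendry_bruteforce(grid, ia, ib, v_oi):
    """Direct evaluation of R_P from its defining formula."""
    grid = np.asarray(grid, float)
    eps_a = 1e-8 * np.max(np.abs(ia))
    eps_b = 1e-8 * np.max(np.abs(ib))

    def yfun(I, eps):
        dI = np.gradient(I, grid)
        y = np.zeros_like(I)
        for k in range(len(I)):
            if abs(I[k]) > eps:
                L = dI[k] / I[k]
                y[k] = L / (1.0 + v_oi**2 * L**2)
        return y

    ya = yfun(np.asarray(ia, float), eps_a)
    yb = yfun(np.asarray(ib, float), eps_b)
    return float(np.sum((ya - yb) ** 2) / np.sum(ya**2 + yb**2))


def soap_coeff_bruteforce(positions, l_max, n_max, rcut, sigma, n_r=600,
                          n_theta=600):
    """Expansion coefficients c_{n l m=0} of a Gaussian neighbour density
    that is azimuthally symmetric about z, by direct 2-D quadrature.

    ``positions``: neighbour positions, all on the z axis.  Returns array
    (n_max, l_max+1).
    """
    from numpy.polynomial.legendre import leggauss
    from scipy.special import eval_legendre

    # radial basis identical in definition, rebuilt independently
    nvec = np.arange(1, n_max + 1)
    nm = nvec[:, None] + nvec[None, :]
    S = 2.0 * rcut ** (nm + 7) / ((nm + 5) * (nm + 6) * (nm + 7))
    w, V = np.linalg.eigh(S)
    W = V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    xr, wr = leggauss(n_r)
    r = 0.5 * rcut * (xr + 1.0)
    wr = 0.5 * rcut * wr
    xc, wc = leggauss(n_theta)  # cos(theta) in [-1, 1]

    phi = (rcut - r)[None, :] ** (nvec[:, None] + 2)
    g = W @ phi  # (n_max, n_r)

    alpha = 1.0 / (2.0 * sigma**2)
    R, C = np.meshgrid(r, xc, indexing="ij")  # (n_r, n_theta)
    rho = np.zeros_like(R)
    for p in positions:
        z = p[2]
        d2 = R**2 + z**2 - 2.0 * R * C * z
        rho += np.exp(-alpha * d2)

    out = np.empty((n_max, l_max + 1))
    for l in range(l_max + 1):
        ylm0 = np.sqrt((2 * l + 1) / (4.0 * np.pi)) * eval_legendre(l, xc)
        ang = rho * ylm0[None, :]  # Y_l0 is real
        ang_int = 2.0 * np.pi * ang @ wc  # integrate over phi and cos(theta)
        out[:, l] = g @ (wr * r**2 * ang_int)
    return out
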