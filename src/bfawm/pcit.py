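"""PCIT co-association network inference.

PCIT (partial correlation coupled with information theory) prunes a
correlation matrix to "significant" associations without a fixed global
cutoff.  For every trio of nodes (x, y, z) the three first-order partial
correlations are computed, e.g.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

and the trio's local tolerance is the mean absolute ratio of partial to
direct correlation.  The x-y association is flagged non-significant in that
trio if |r_xy| <= |eps r_xz| and |r_xy| <= |eps r_yz|; an edge survives only
if no trio flags it.  Ratios whose direct correlation is numerically zero are
excluded from the tolerance; a trio with all three excluded is skipped.

With AWM input the correlations are taken between gene rows across the trait
columns; with only a handful of traits these correlations are high-variance,
so edge counts are sensitive to the number of trait columns.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from ._jit import njit

NOISE_FLOOR = 1e-12


def row_correlations(awm: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between AWM rows across trait columns."""
    if awm.shape[1] < 3:
        raise ValueError("need at least 3 trait columns")
    X = awm.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant row(s): {list(awm.index[flat])}")
    C = np.corrcoef(X)
    return pd.DataFrame(C, index=awm.index, columns=awm.index)


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """First-order partial correlation of x and y given z."""
    for r in (rxy, rxz, ryz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1,1]")
    if abs(rxz) >= 1.0 or abs(ryz) >= 1.0:
        raise ValueError("partial correlation undefined when a conditioning correlation is +-1")
    return (rxy - rxz * ryz) / math.sqrt((1.0 - rxz * rxz) * (1.0 - ryz * ryz))


@njit(cache=True)
def _pcit_kernel(C, floor):
    n = C.shape[0]
    keep = np.ones((n, n), np.bool_)
    for x in range(n - 2):
        for y in range(x + 1, n - 1):
            for z in range(y + 1, n):
                rxy = C[x, y]
                rxz = C[x, z]
                ryz = C[y, z]
                d1 = (1.0 - rxz * rxz) * (1.0 - ryz * ryz)
                d2 = (1.0 - rxy * rxy) * (1.0 - ryz * ryz)
                d3 = (1.0 - rxy * rxy) * (1.0 - rxz * rxz)
                if d1 <= 0.0 or d2 <= 0.0 or d3 <= 0.0:
                    continue  # a |correlation| of 1 makes partials undefined
                pxy = (rxy - rxz * ryz) / math.sqrt(d1)
                pxz = (rxz - rxy * ryz) / math.sqrt(d2)
                pyz = (ryz - rxy * rxz) / math.sqrt(d3)
                s = 0.0
                k = 0
                if abs(rxy) > floor:
                    s += abs(pxy / rxy)
                    k += 1
                if abs(rxz) > floor:
                    s += abs(pxz / rxz)
                    k += 1
                if abs(ryz) > floor:
                    s += abs(pyz / ryz)
                    k += 1
                if k == 0:
                    continue
                tol = s / k
                if abs(rxy) <= abs(tol * rxz) and abs(rxy) <= abs(tol * ryz):
                    keep[x, y] = False
                    keep[y, x] = False
                if abs(rxz) <= abs(tol * rxy) and abs(rxz) <= abs(tol * ryz):
                    keep[x, z] = False
                    keep[z, x] = False
                if abs(ryz) <= abs(tol * rxy) and abs(ryz) <= abs(tol * rxz):
                    keep[y, z] = False
                    keep[z, y] = False
    return keep


def pcit_filter(C: pd.DataFrame | np.ndarray) -> nx.Graph:
    """Run PCIT on a correlation matrix and return the surviving network.

    Nodes are all matrix rows; undirected edges carry the direct correlation
    as ``weight`` and ``significant=True``.  Edges below the numerical noise
    floor are dropped even if never flagged.
    """
    if isinstance(C, pd.DataFrame):
        labels = list(C.index)
        M = C.to_numpy(dtype=float)
    else:
        M = np.asarray(C, dtype=float)
        labels = list(range(M.shape[0]))
    n = M.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 nodes")
    if M.shape != (n, n) or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    keep = _pcit_kernel(np.ascontiguousarray(M), NOISE_FLOOR)
    G = nx.Graph()
    G.add_nodes_from(labels)
    for x in range(n - 1):
        for y in range(x + 1, n):
            if keep[x, y] and abs(M[x, y]) > NOISE_FLOOR:
                G.add_edge(labels[x], labels[y], weight=float(M[x, y]), significant=True)
    return G


def network_summary(G: nx.Graph) -> dict:
    """Node/edge counts, density and the highest-degree nodes."""
    n = G.number_of_nodes()
    e = G.number_of_edges()
    degrees = dict(G.degree())
    density = 0.0 if n < 2 else 2.0 * e / (n * (n - 1))
    top = sorted(degrees, key=lambda k: (-degrees[k], str(k)))[:10]
    return {
        "n_nodes": n,
        "n_edges": e,
        "density": density,
        "degree": degrees,
        "top_degree_nodes": [str(t) for t in top],
    }
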