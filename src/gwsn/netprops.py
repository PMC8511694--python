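"""Nine-statistic characterization of a weighted network snapshot.

For one snapshot the suite computes: average degree <k>, degree
assortativity rho_k, average link weight <w>, average (unweighted)
clustering coefficient C, average link overlap O, the Pearson
correlations rho_ck (local clustering vs degree, over nodes) and rho_ow
(link overlap vs weight, over links), and the ascending/descending
weight-ordered link-percolation transition points rescaled by the
average degree, (1 - f_c) <k>.

Undefined statistics (zero variance, empty network, fewer than two
links) are reported as NaN — an explicit missing marker, never a silent
zero; campaign tables serialize them as empty cells.

Percolation "disintegration" is detected by the susceptibility peak:
chi(f) = sum_{s != giant} s^2 n_s / N over component sizes excluding the
largest component, maximized over the removal fraction f (ties broken
toward smaller f).  A largest-giant-drop detector is available behind a
flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import scipy.sparse as sp

from .model_core import WeightedNetwork

PROPERTY_NAMES = (
    "k_avg", "rho_k", "w_avg", "C", "O", "rho_ck", "rho_ow",
    "perc_asc", "perc_desc",
)


@dataclass(frozen=True)
class NetworkProperties:
    """The nine per-snapshot outputs; NaN marks an undefined statistic."""

    k_avg: float
    rho_k: float
    w_avg: float
    C: float
    O: float
    rho_ck: float
    rho_ow: float
    perc_asc: float   # (1 - f_c^a) <k>, ascending (weakest-first) removal
    perc_desc: float  # (1 - f_c^d) <k>, descending (strongest-first) removal

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROPERTY_NAMES])


# ---------------------------------------------------------------------------
# Edge-array plumbing
# ---------------------------------------------------------------------------

def _edge_arrays(net):
    """(src, dst, weight, n_nodes) with src < dst, from any accepted input."""
    if isinstance(net, WeightedNetwork):
        e = net.edges()
        return e[:, 0].astype(np.int64), e[:, 1].astype(np.int64), e[:, 2], net.n_nodes
    raise TypeError(f"expected WeightedNetwork, got {type(net)!r}")


def _degrees(src, dst, n):
    return np.bincount(src, minlength=n) + np.bincount(dst, minlength=n)


def _pearson(x, y):
    """Pearson r with a NaN guard for zero variance or n < 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Individual statistics
# ---------------------------------------------------------------------------

def average_degree(net) -> float:
    """<k> = 2 L / N."""
    src, dst, w, n = _edge_arrays(net)
    return 2.0 * len(w) / n


def degree_assortativity(net) -> float:
    """Newman degree-degree correlation over links (excess-degree form).

    Equals the Pearson correlation of the degrees at the two ends of every
    link, counting each link in both directions; NaN when the excess-degree
    variance vanishes (regular graphs, a single link).
    """
    src, dst, w, n = _edge_arrays(net)
    if len(w) < 1:
        return math.nan
    k = _degrees(src, dst, n)
    x = np.concatenate([k[src], k[dst]]) - 1.0
    y = np.concatenate([k[dst], k[src]]) - 1.0
    return _pearson(x, y)


def average_link_weight(net) -> float:
    """<w> = sum_ij w_ij / L; NaN for an empty network."""
    src, dst, w, n = _edge_arrays(net)
    return float(np.mean(w)) if len(w) else math.nan


def _local_clustering(src, dst, w, n):
    """Per-node unweighted local clustering; c_i = 0 for k_i < 2."""
    k = _degrees(src, dst, n)
    if len(w) == 0:
        return np.zeros(n), k
    a = sp.coo_matrix((np.ones(len(w)), (src, dst)), shape=(n, n))
    a = (a + a.T).tocsr()
    # triangles through i: ((A @ A) .* A) row sums / 2
    tri = np.asarray((a @ a).multiply(a).sum(axis=1)).ravel() / 2.0
    denom = k * (k - 1) / 2.0
    c = np.zeros(n)
    mask = denom > 0
    c[mask] = tri[mask] / denom[mask]
    return c, k


def average_clustering(net) -> float:
    """C = mean over all N nodes of the local clustering coefficient.

    Nodes with k_i < 2 contribute c_i = 0 (and are included in the
    mean); an empty network has no defined clustering and yields NaN.
    """
    src, dst, w, n = _edge_arrays(net)
    if len(w) == 0:
        return math.nan
    c, _ = _local_clustering(src, dst, w, n)
    return float(np.mean(c))


def _link_overlap(src, dst, w, n):
    """Per-link overlap o_ij = n_ij / ((k_i - 1) + (k_j - 1) - n_ij).

    n_ij is the number of common neighbors; a zero denominator (both
    endpoints degree 1) yields o_ij = 0 — an isolated dyad has no
    possible common neighbor.
    """
    k = _degrees(src, dst, n)
    a = sp.coo_matrix((np.ones(len(w)), (src, dst)), shape=(n, n))
    a = (a + a.T).tocsr()
    common = np.asarray((a @ a)[src, dst]).ravel()
    denom = k[src] + k[dst] - 2.0 - common
    o = np.zeros(len(w))
    mask = denom > 0
    o[mask] = common[mask] / denom[mask]
    return o


def average_overlap(net) -> float:
    """O = mean link overlap over the L links; NaN when L = 0."""
    src, dst, w, n = _edge_arrays(net)
    if len(w) == 0:
        return math.nan
    return float(np.mean(_link_overlap(src, dst, w, n)))


def correlations(net) -> tuple[float, float]:
    """(rho_ck, rho_ow): Pearson r of (c_i, k_i) over nodes and of
    (o_ij, w_ij) over links; NaN when either variance is zero."""
    src, dst, w, n = _edge_arrays(net)
    c, k = _local_clustering(src, dst, w, n)
    rho_ck = _pearson(c, k)
    if len(w) == 0:
        return rho_ck, math.nan
    o = _link_overlap(src, dst, w, n)
    rho_ow = _pearson(o, w)
    return rho_ck, rho_ow


# ---------------------------------------------------------------------------
# Weight-ordered link percolation
# ---------------------------------------------------------------------------

class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, i):
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i, j):
        """Merge; returns (sa, sb, merged) component sizes before merging."""
        a, b = self.find(i), self.find(j)
        if a == b:
            return 0, 0, False
        if self.size[a] < self.size[b]:
            a, b = b, a
        sa, sb = int(self.size[a]), int(self.size[b])
        self.parent[b] = a
        self.size[a] = sa + sb
        return sa, sb, True


def _removal_order(w, order, rng):
    """Indices of links in removal order; equal weights tie-shuffled."""
    w = np.asarray(w, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    perm = rng.permutation(len(w))
    key = w[perm]
    idx = perm[np.argsort(key, kind="stable")]
    if order == "descending":
        # reverse, keeping the shuffled order within equal-weight blocks
        idx = perm[np.argsort(-key, kind="stable")]
    elif order != "ascending":
        raise ValueError(f"order must be 'ascending' or 'descending', got {order!r}")
    return idx


def link_percolation_transition(net, order: str = "ascending", rng=None,
                                detector: str = "susceptibility") -> float:
    """Transition point f_c of weight-ordered link percolation.

    Links are removed one by one in ``order`` of weight (ascending =
    weakest first).  The returned f_c is the removal fraction at which
    the network disintegrates, located by sweeping f in {0, 1/L, ..., 1}
    via reverse-order link addition with union-find and maximizing the
    susceptibility chi(f) = sum' s^2 n_s / N over components excluding
    the largest (ties toward smaller f).  ``detector='giant_drop'``
    instead returns the f with the largest single-removal drop of the
    giant component.  NaN when L < 2.
    """
    src, dst, w, n = _edge_arrays(net)
    L = len(w)
    if L < 2:
        return math.nan
    removal = _removal_order(w, order, rng)
    addition = removal[::-1]

    uf = _UnionFind(n)
    sum_sq = float(n)        # all singletons
    max_size = 1
    giant = np.empty(L + 1)  # giant size after a additions
    chi = np.empty(L + 1)    # susceptibility after a additions
    giant[0] = max_size
    chi[0] = (sum_sq - max_size**2) / n
    for a, e in enumerate(addition, start=1):
        sa, sb, merged = uf.union(src[e], dst[e])
        if merged:
            sum_sq += (sa + sb) ** 2 - sa**2 - sb**2
            if sa + sb > max_size:
                max_size = sa + sb
        giant[a] = max_size
        chi[a] = (sum_sq - max_size**2) / n

    f = (L - np.arange(L + 1)) / L  # removal fraction after a additions
    if detector == "susceptibility":
        # maximize chi; on ties prefer smaller f (= later addition index)
        best = int(np.flatnonzero(chi == chi.max())[-1])
    elif detector == "giant_drop":
        # largest drop of the giant on a single removal: between addition
        # steps a and a-1; transition assigned to the post-removal state
        drops = giant[1:] - giant[:-1]
        best = int(np.flatnonzero(drops == drops.max())[-1])
    else:
        raise ValueError(f"unknown detector {detector!r}")
    return float(f[best])


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def compute_all(net, rng=None, detector: str = "susceptibility") -> NetworkProperties:
    """All nine statistics for one snapshot (percolation rescaled by <k>)."""
    src, dst, w, n = _edge_arrays(net)
    k_avg = 2.0 * len(w) / n
    rho_ck, rho_ow = correlations(net)
    if len(w) >= 2:
        f_a = link_percolation_transition(net, "ascending", rng=rng, detector=detector)
        f_d = link_percolation_transition(net, "descending", rng=rng, detector=detector)
        perc_asc = (1.0 - f_a) * k_avg
        perc_desc = (1.0 - f_d) * k_avg
    else:
        perc_asc = perc_desc = math.nan
    return NetworkProperties(
        k_avg=k_avg,
        rho_k=degree_assortativity(net),
        w_avg=average_link_weight(net),
        C=average_clustering(net),
        O=average_overlap(net) if len(w) else math.nan,
        rho_ck=rho_ck,
        rho_ow=rho_ow,
        perc_asc=perc_asc,
        perc_desc=perc_desc,
    )
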