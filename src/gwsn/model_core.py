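"""Agent-based simulator for the generalized weighted social network (GWSN) model.

The model grows a weighted, undirected social network among ``N`` agents.
Each agent has a fixed position on the unit torus and a fixed vector of
``F`` categorical traits, each taking one of ``q`` values.  Per Monte Carlo
step every agent attempts

* one **global attachment** (GA): link creation with a trait-compatible
  non-neighbor, chosen with probability proportional to ``r**(-alpha)``
  where ``r`` is the torus distance (focal closure / homophily), and
* one **local attachment** (LA): a weight-biased two-hop walk among
  trait-compatible neighbors, with optional closure of the triad
  (probability ``p_delta``) and reinforcement ``+w_r`` of the traversed
  links (triadic closure / Granovetterian weight organization),

followed by three network-wide termination sweeps: node deletion
(isolate each node with probability ``p_nd``), link deletion (drop each
link with probability ``p_ld``) and link aging (multiply every weight by
``1 - A`` and drop links whose weight falls below ``w_th``).

The per-step inner loop is JIT-compiled with numba; the module-level
functions (``global_attachment``, ``local_attachment``, ...) are thin
seeded wrappers over the same kernels so that individual mechanisms can
be exercised and instrumented in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

logger = logging.getLogger("gwsn")

# Distance floor for coincident positions (probability-zero under
# continuous sampling; avoids division by zero in the GA kernel).
MIN_DISTANCE = 1e-12

# Number of uniform-rejection probes in the alpha=0 GA kernel before
# falling back to explicit candidate enumeration.
_GA_REJECTION_TRIES = 30

# Head-room (in links per node) kept between the adjacency capacity and
# the maximum degree; when exceeded the run pauses and the arrays grow.
_GROW_MARGIN = 8

PARAM_NAMES = ("N", "F", "q", "alpha", "p_r", "p_delta", "w_r", "p_nd", "p_ld", "A")


# ---------------------------------------------------------------------------
# Parameters, protocol, population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GWSNParams:
    """Input parameters of the GWSN model.

    ``w0`` (initial link weight) and ``w_th`` (aging deletion threshold)
    only set scales and default to their conventional fixed values 1 and
    0.5; the remaining ten parameters span the model's sampled input box.
    """

    N: int
    F: int = 1
    q: int = 1
    alpha: float = 0.0
    p_r: float = 1e-3
    p_delta: float = 1e-2
    w_r: float = 1.0
    p_nd: float = 0.0
    p_ld: float = 0.0
    A: float = 0.0
    w0: float = 1.0
    w_th: float = 0.5

    def __post_init__(self) -> None:
        if int(self.N) < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if int(self.F) < 1 or int(self.q) < 1:
            raise ValueError("F and q must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.w_r < 0 or self.w0 < 0 or self.w_th < 0:
            raise ValueError("weights must be non-negative")
        for name in ("p_r", "p_delta", "p_nd", "p_ld", "A"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES + ("w0", "w_th")}


@dataclass(frozen=True)
class SimulationProtocol:
    """Run horizon, checkpointing and abort rule for one simulation."""

    t_max: int = 50_000
    measure_every: int = 5_000
    k_th: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_max < 0 or self.measure_every <= 0:
            raise ValueError("t_max must be >= 0 and measure_every > 0")
        if self.t_max % self.measure_every != 0:
            raise ValueError("t_max must be divisible by measure_every")
        if self.k_th <= 0:
            raise ValueError("k_th must be > 0")

    @property
    def n_checkpoints(self) -> int:
        return self.t_max // self.measure_every


@dataclass(frozen=True)
class Population:
    """Fixed agent attributes: torus positions and trait vectors.

    positions : (N, 2) float array in [0, 1) x [0, 1)
    traits    : (N, F) integer array with values in {1, ..., q}
    """

    positions: np.ndarray
    traits: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]


def init_population(params: GWSNParams, rng: np.random.Generator) -> Population:
    """Draw i.i.d. uniform positions on the unit torus and uniform traits."""
    pos = rng.random((params.N, 2))
    traits = rng.integers(1, params.q + 1, size=(params.N, params.F), dtype=np.int64)
    pos.setflags(write=False)
    traits.setflags(write=False)
    return Population(positions=pos, traits=traits)


def torus_distance(p1, p2) -> float:
    """Minimum-image Euclidean distance on the unit torus [0,1) x [0,1)."""
    d = np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))
    d = np.minimum(d, 1.0 - d)
    return float(np.sqrt((d * d).sum(axis=-1)))


def _distance_matrix(positions: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances, (N, N)."""
    d = np.abs(positions[:, None, :] - positions[None, :, :])
    d = np.minimum(d, 1.0 - d)
    return np.sqrt((d * d).sum(axis=-1))


def _ga_kernel_matrix(positions: np.ndarray, alpha: float) -> np.ndarray:
    """Pairwise GA propensities r_ij**(-alpha), diagonal zeroed."""
    r = _distance_matrix(positions)
    np.fill_diagonal(r, 1.0)  # overwritten below
    r = np.maximum(r, MIN_DISTANCE)
    k = r ** (-alpha)
    np.fill_diagonal(k, 0.0)
    return k


def _trait_buckets(traits: np.ndarray, q: int):
    """Per-feature node lists grouped by trait value.

    Returns (bucket_nodes, bucket_off): for feature f the nodes with
    trait value v are bucket_nodes[f, bucket_off[f, v-1]:bucket_off[f, v]].
    """
    n, f_count = traits.shape
    bucket_nodes = np.empty((f_count, n), dtype=np.int64)
    bucket_off = np.zeros((f_count, q + 1), dtype=np.int64)
    for f in range(f_count):
        order = np.argsort(traits[:, f], kind="stable")
        bucket_nodes[f] = order
        counts = np.bincount(traits[:, f], minlength=q + 1)[1:]
        bucket_off[f, 1:] = np.cumsum(counts)
    return bucket_nodes, bucket_off


# ---------------------------------------------------------------------------
# Weighted network container
# ---------------------------------------------------------------------------

class WeightedNetwork:
    """Undirected weighted graph over n nodes; weight 0 <=> link absent.

    Adjacency is stored twice (once per endpoint) in flat per-node arrays
    sized for the JIT kernels; ``validate()`` checks the mirror/symmetry
    invariants after instrumented runs.
    """

    def __init__(self, n_nodes: int, capacity: int = 64):
        capacity = max(8, min(capacity, max(1, n_nodes - 1) + _GROW_MARGIN))
        self.n_nodes = int(n_nodes)
        self.nbr = np.zeros((n_nodes, capacity), dtype=np.int64)
        self.wgt = np.zeros((n_nodes, capacity), dtype=np.float64)
        self.deg = np.zeros(n_nodes, dtype=np.int64)

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(cls, n_nodes: int, edges: Sequence) -> "WeightedNetwork":
        """Build from (src, dst, weight) triples (or (src, dst) with w=1)."""
        net = cls(n_nodes)
        for e in edges:
            if len(e) == 2:
                i, j, w = int(e[0]), int(e[1]), 1.0
            else:
                i, j, w = int(e[0]), int(e[1]), float(e[2])
            net.add_link(i, j, w)
        return net

    # -- basic edits ---------------------------------------------------
    def _grow(self, new_capacity: int) -> None:
        cap = self.nbr.shape[1]
        new_capacity = min(new_capacity, self.n_nodes - 1 + _GROW_MARGIN)
        if new_capacity <= cap:
            raise RuntimeError("adjacency capacity exhausted (complete graph?)")
        nbr = np.zeros((self.n_nodes, new_capacity), dtype=np.int64)
        wgt = np.zeros((self.n_nodes, new_capacity), dtype=np.float64)
        nbr[:, :cap] = self.nbr
        wgt[:, :cap] = self.wgt
        self.nbr, self.wgt = nbr, wgt

    def _ensure_capacity(self) -> None:
        cap = self.nbr.shape[1]
        if self.deg.max(initial=0) > cap - _GROW_MARGIN and cap < self.n_nodes - 1 + _GROW_MARGIN:
            self._grow(2 * cap)

    def add_link(self, i: int, j: int, w: float) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed")
        if w <= 0:
            raise ValueError("link weight must be positive")
        if self.get_weight(i, j) > 0:
            raise ValueError(f"link {i}-{j} already exists")
        if max(self.deg[i], self.deg[j]) + 1 >= self.nbr.shape[1]:
            self._grow(2 * self.nbr.shape[1])
        for a, b in ((i, j), (j, i)):
            self.nbr[a, self.deg[a]] = b
            self.wgt[a, self.deg[a]] = w
            self.deg[a] += 1

    def remove_link(self, i: int, j: int) -> None:
        _remove_link(self.nbr, self.wgt, self.deg, i, j)

    def get_weight(self, i: int, j: int) -> float:
        idx = _find_neighbor(self.nbr, self.deg, i, j)
        return float(self.wgt[i, idx]) if idx >= 0 else 0.0

    # -- queries --------------------------------------------------------
    @property
    def degrees(self) -> np.ndarray:
        return self.deg.copy()

    @property
    def n_links(self) -> int:
        return int(self.deg.sum()) // 2

    @property
    def average_degree(self) -> float:
        return float(self.deg.sum()) / self.n_nodes

    def total_weight(self) -> float:
        return float(sum(self.wgt[i, : self.deg[i]].sum() for i in range(self.n_nodes))) / 2.0

    def edges(self) -> np.ndarray:
        """(L, 3) array of (src, dst, weight) with src < dst, sorted."""
        rows = []
        for i in range(self.n_nodes):
            for idx in range(self.deg[i]):
                j = self.nbr[i, idx]
                if i < j:
                    rows.append((float(i), float(j), float(self.wgt[i, idx])))
        if not rows:
            return np.empty((0, 3), dtype=np.float64)
        out = np.array(rows, dtype=np.float64)
        return out[np.lexsort((out[:, 1], out[:, 0]))]

    def copy(self) -> "WeightedNetwork":
        net = WeightedNetwork(self.n_nodes, capacity=self.nbr.shape[1])
        net.nbr = self.nbr.copy()
        net.wgt = self.wgt.copy()
        net.deg = self.deg.copy()
        return net

    def validate(self) -> None:
        """Assert the structural invariants: symmetry, no self-loops, w > 0."""
        for i in range(self.n_nodes):
            seen = set()
            for idx in range(self.deg[i]):
                j = int(self.nbr[i, idx])
                w = float(self.wgt[i, idx])
                if j == i:
                    raise AssertionError(f"self-loop at node {i}")
                if j in seen:
                    raise AssertionError(f"duplicate neighbor {j} of {i}")
                seen.add(j)
                if w <= 0:
                    raise AssertionError(f"non-positive stored weight on {i}-{j}")
                jdx = _find_neighbor(self.nbr, self.deg, j, i)
                if jdx < 0 or self.wgt[j, jdx] != w:
                    raise AssertionError(f"asymmetric link {i}-{j}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedNetwork) or self.n_nodes != other.n_nodes:
            return NotImplemented if not isinstance(other, WeightedNetwork) else False
        return np.array_equal(self.edges(), other.edges())


# ---------------------------------------------------------------------------
# JIT kernels (adjacency arrays; numba's global RNG supplies randomness)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _find_neighbor(nbr, deg, i, j):
    for idx in range(deg[i]):
        if nbr[i, idx] == j:
            return idx
    return -1


@njit(cache=True)
def _append_link(nbr, wgt, deg, i, j, w):
    cap = nbr.shape[1]
    if deg[i] >= cap or deg[j] >= cap:
        return False
    nbr[i, deg[i]] = j
    wgt[i, deg[i]] = w
    deg[i] += 1
    nbr[j, deg[j]] = i
    wgt[j, deg[j]] = w
    deg[j] += 1
    return True


@njit(cache=True)
def _remove_at(nbr, wgt, deg, i, idx):
    deg[i] -= 1
    nbr[i, idx] = nbr[i, deg[i]]
    wgt[i, idx] = wgt[i, deg[i]]


@njit(cache=True)
def _remove_link(nbr, wgt, deg, i, j):
    ii = _find_neighbor(nbr, deg, i, j)
    jj = _find_neighbor(nbr, deg, j, i)
    if ii < 0 or jj < 0:
        return
    _remove_at(nbr, wgt, deg, i, ii)
    _remove_at(nbr, wgt, deg, j, jj)


@njit(cache=True)
def _ga_select(nbr, deg, bucket_nodes, bucket_off, traits, kern, alpha, i, f, mark):
    """Choose the GA partner j for focal node i and feature f, or -1.

    Candidates are the same-trait non-neighbors (the focal node's
    homophily set); selection is proportional to r**(-alpha).  For
    alpha == 0 (uniform) a rejection loop over the trait bucket is tried
    first and falls back to reservoir enumeration; the fallback leaves
    the overall selection uniform because rejection failure is
    independent of the candidate identity.
    """
    v = traits[i, f]
    lo = bucket_off[f, v - 1]
    hi = bucket_off[f, v]
    if hi - lo <= 1:
        return -1
    if alpha == 0.0:
        m = hi - lo
        for _ in range(_GA_REJECTION_TRIES):
            j = bucket_nodes[f, lo + np.random.randint(0, m)]
            if j == i:
                continue
            if _find_neighbor(nbr, deg, i, j) >= 0:
                continue
            return j
        # reservoir sampling over the explicit candidate set
        for idx in range(deg[i]):
            mark[nbr[i, idx]] = True
        count = 0
        chosen = -1
        for t in range(lo, hi):
            j = bucket_nodes[f, t]
            if j == i or mark[j]:
                continue
            count += 1
            if np.random.random() * count < 1.0:
                chosen = j
        for idx in range(deg[i]):
            mark[nbr[i, idx]] = False
        return chosen
    # distance-weighted selection using the precomputed kernel matrix
    for idx in range(deg[i]):
        mark[nbr[i, idx]] = True
    total = 0.0
    for t in range(lo, hi):
        j = bucket_nodes[f, t]
        if j == i or mark[j]:
            continue
        total += kern[i, j]
    chosen = -1
    if total > 0.0:
        u = np.random.random() * total
        acc = 0.0
        for t in range(lo, hi):
            j = bucket_nodes[f, t]
            if j == i or mark[j]:
                continue
            acc += kern[i, j]
            if acc >= u:
                chosen = j
                break
        if chosen == -1:  # guard against accumulated round-off
            for t in range(hi - 1, lo - 1, -1):
                j = bucket_nodes[f, t]
                if j != i and not mark[j]:
                    chosen = j
                    break
    for idx in range(deg[i]):
        mark[nbr[i, idx]] = False
    return chosen


@njit(cache=True)
def _ga_event(nbr, wgt, deg, bucket_nodes, bucket_off, traits, kern,
              alpha, i, F, p_r, w0, mark):
    """One global-attachment attempt by node i. Returns 1 on overflow.

    The link-creation coin (probability p_r when k_i > 0) is drawn
    before the partner selection: selection has no side effects, so
    skipping it when the coin fails is observationally equivalent and
    avoids the candidate scan on the vast majority of attempts.
    """
    f = np.random.randint(0, F)
    if deg[i] > 0 and np.random.random() >= p_r:
        return 0
    j = _ga_select(nbr, deg, bucket_nodes, bucket_off, traits, kern, alpha, i, f, mark)
    if j < 0:
        return 0
    if not _append_link(nbr, wgt, deg, i, j, w0):
        return 1
    return 0


@njit(cache=True)
def _la_event(nbr, wgt, deg, traits, i, F, p_delta, w_r, w0):
    """One local-attachment attempt by node i. Returns 1 on overflow.

    The two-hop walk i -> j -> l is weight-biased and restricted to
    neighbors sharing the drawn feature's trait value.  If either
    candidate set is empty the whole event is a no-op (no partial
    reinforcement).  A pre-existing i-l link is reinforced; a freshly
    closed one starts at exactly w0.
    """
    f = np.random.randint(0, F)
    v = traits[i, f]
    total = 0.0
    for idx in range(deg[i]):
        if traits[nbr[i, idx], f] == v:
            total += wgt[i, idx]
    if total <= 0.0:
        return 0
    u = np.random.random() * total
    acc = 0.0
    jidx = -1
    for idx in range(deg[i]):
        if traits[nbr[i, idx], f] == v:
            acc += wgt[i, idx]
            if acc >= u:
                jidx = idx
                break
    if jidx < 0:
        for idx in range(deg[i] - 1, -1, -1):
            if traits[nbr[i, idx], f] == v:
                jidx = idx
                break
    j = nbr[i, jidx]

    total2 = 0.0
    for idx in range(deg[j]):
        l = nbr[j, idx]
        if l != i and traits[l, f] == v:
            total2 += wgt[j, idx]
    if total2 <= 0.0:
        return 0
    u = np.random.random() * total2
    acc = 0.0
    lidx = -1
    for idx in range(deg[j]):
        l = nbr[j, idx]
        if l != i and traits[l, f] == v:
            acc += wgt[j, idx]
            if acc >= u:
                lidx = idx
                break
    if lidx < 0:
        for idx in range(deg[j] - 1, -1, -1):
            l = nbr[j, idx]
            if l != i and traits[l, f] == v:
                lidx = idx
                break
    l = nbr[j, lidx]

    il = _find_neighbor(nbr, deg, i, l)
    if il < 0:
        if np.random.random() < p_delta:
            if not _append_link(nbr, wgt, deg, i, l, w0):
                return 1
    else:
        wgt[i, il] += w_r
        li = _find_neighbor(nbr, deg, l, i)
        wgt[l, li] += w_r
    wgt[i, jidx] += w_r
    ji = _find_neighbor(nbr, deg, j, i)
    wgt[j, ji] += w_r
    wgt[j, lidx] += w_r
    lj = _find_neighbor(nbr, deg, l, j)
    wgt[l, lj] += w_r
    return 0


@njit(cache=True)
def _nd_sweep(nbr, wgt, deg, p_nd):
    """Replace each node by an isolated node with probability p_nd."""
    if p_nd <= 0.0:
        return
    n = deg.shape[0]
    for i in range(n):
        if np.random.random() < p_nd:
            for idx in range(deg[i] - 1, -1, -1):
                j = nbr[i, idx]
                jj = _find_neighbor(nbr, deg, j, i)
                _remove_at(nbr, wgt, deg, j, jj)
            deg[i] = 0


@njit(cache=True)
def _ld_sweep(nbr, wgt, deg, p_ld):
    """Delete each link independently with probability p_ld."""
    if p_ld <= 0.0:
        return
    n = deg.shape[0]
    for i in range(n):
        idx = 0
        while idx < deg[i]:
            j = nbr[i, idx]
            if j > i and np.random.random() < p_ld:
                jj = _find_neighbor(nbr, deg, j, i)
                _remove_at(nbr, wgt, deg, j, jj)
                _remove_at(nbr, wgt, deg, i, idx)
                # swapped-in entry re-examined at the same idx
            else:
                idx += 1


@njit(cache=True)
def _aging_sweep(nbr, wgt, deg, A, w_th):
    """Multiply weights by (1 - A); drop links falling below w_th."""
    if A <= 0.0:
        return
    n = deg.shape[0]
    for i in range(n):
        idx = 0
        while idx < deg[i]:
            j = nbr[i, idx]
            if j > i:
                w = wgt[i, idx] * (1.0 - A)
                if w < w_th:
                    jj = _find_neighbor(nbr, deg, j, i)
                    _remove_at(nbr, wgt, deg, j, jj)
                    _remove_at(nbr, wgt, deg, i, idx)
                    continue
                wgt[i, idx] = w
                jj = _find_neighbor(nbr, deg, j, i)
                wgt[j, jj] = w
            idx += 1


@njit(cache=True)
def _step_kernel(nbr, wgt, deg, bucket_nodes, bucket_off, traits, kern,
                 alpha, F, p_r, p_delta, w_r, w0, p_nd, p_ld, A, w_th,
                 perm, mark):
    """One Monte Carlo step: per-node GA then LA in shuffled order,
    then the ND -> LD -> aging sweeps over the whole network."""
    n = deg.shape[0]
    for i in range(n):
        perm[i] = i
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp
    for t in range(n):
        i = perm[t]
        if _ga_event(nbr, wgt, deg, bucket_nodes, bucket_off, traits, kern,
                     alpha, i, F, p_r, w0, mark):
            return 1
        if _la_event(nbr, wgt, deg, traits, i, F, p_delta, w_r, w0):
            return 1
    _nd_sweep(nbr, wgt, deg, p_nd)
    _ld_sweep(nbr, wgt, deg, p_ld)
    _aging_sweep(nbr, wgt, deg, A, w_th)
    return 0


@njit(cache=True)
def _run_steps(nbr, wgt, deg, bucket_nodes, bucket_off, traits, kern,
               alpha, F, p_r, p_delta, w_r, w0, p_nd, p_ld, A, w_th,
               perm, mark, n_steps, margin):
    """Advance n_steps; returns (steps_done, status).

    status 0: done; 1: hard overflow mid-step (should not occur with the
    soft margin); 2: capacity head-room exhausted after a completed step
    (caller grows the arrays and resumes).
    """
    cap = nbr.shape[1]
    for s in range(n_steps):
        st = _step_kernel(nbr, wgt, deg, bucket_nodes, bucket_off, traits, kern,
                          alpha, F, p_r, p_delta, w_r, w0, p_nd, p_ld, A, w_th,
                          perm, mark)
        if st:
            return s, 1
        mx = 0
        for i in range(deg.shape[0]):
            if deg[i] > mx:
                mx = deg[i]
        if mx > cap - margin:
            return s + 1, 2
    return n_steps, 0


@njit(cache=True)
def _ga_select_counts(nbr, deg, bucket_nodes, bucket_off, traits, kern,
                      alpha, i, f, mark, n_draws, counts):
    """Instrumentation: tally n_draws repeated GA partner selections."""
    for _ in range(n_draws):
        j = _ga_select(nbr, deg, bucket_nodes, bucket_off, traits, kern,
                       alpha, i, f, mark)
        if j >= 0:
            counts[j] += 1


# ---------------------------------------------------------------------------
# Python-level simulation state and per-mechanism wrappers
# ---------------------------------------------------------------------------

class _SimState:
    """Bundles the arrays the kernels operate on for one (net, pop, params)."""

    def __init__(self, net: WeightedNetwork, pop: Population, params: GWSNParams):
        if pop.n != net.n_nodes:
            raise ValueError("population and network sizes differ")
        self.net = net
        self.params = params
        self.traits = np.ascontiguousarray(pop.traits, dtype=np.int64)
        self.bucket_nodes, self.bucket_off = _trait_buckets(self.traits, params.q)
        if params.alpha > 0:
            self.kern = _ga_kernel_matrix(np.asarray(pop.positions, float), params.alpha)
        else:
            self.kern = np.zeros((1, 1))
        self.perm = np.empty(net.n_nodes, dtype=np.int64)
        self.mark = np.zeros(net.n_nodes, dtype=np.bool_)

    def kernel_args(self):
        net, p = self.net, self.params
        return (net.nbr, net.wgt, net.deg, self.bucket_nodes, self.bucket_off,
                self.traits, self.kern, float(p.alpha), p.F, float(p.p_r),
                float(p.p_delta), float(p.w_r), float(p.w0), float(p.p_nd),
                float(p.p_ld), float(p.A), float(p.w_th))


def _seed_from(rng) -> None:
    """Seed the kernel RNG from a Generator, an int, or None."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        seed = int(rng) % (2**32)
    else:
        seed = int(rng.integers(0, 2**32))
    _seed_kernel_rng(seed)


def global_attachment(net: WeightedNetwork, pop: Population, i: int,
                      params: GWSNParams, rng=None) -> WeightedNetwork:
    """Perform one GA event for focal node i (in place; returns net)."""
    _seed_from(rng)
    st = _SimState(net, pop, params)
    net._ensure_capacity()
    if _ga_event(net.nbr, net.wgt, net.deg, st.bucket_nodes, st.bucket_off,
                 st.traits, st.kern, float(params.alpha), i, params.F,
                 float(params.p_r), float(params.w0), st.mark):
        raise RuntimeError("adjacency capacity overflow")
    return net


def ga_selection_counts(net: WeightedNetwork, pop: Population, i: int, f: int,
                        params: GWSNParams, n_draws: int, rng=None) -> np.ndarray:
    """Tally n_draws GA partner selections for (i, f) without mutating net."""
    _seed_from(rng)
    st = _SimState(net, pop, params)
    counts = np.zeros(net.n_nodes, dtype=np.int64)
    _ga_select_counts(net.nbr, net.deg, st.bucket_nodes, st.bucket_off, st.traits,
                      st.kern, float(params.alpha), i, f, st.mark, n_draws, counts)
    return counts


def local_attachment(net: WeightedNetwork, pop: Population, i: int,
                     params: GWSNParams, rng=None) -> WeightedNetwork:
    """Perform one LA event for focal node i (in place; returns net)."""
    _seed_from(rng)
    st = _SimState(net, pop, params)
    net._ensure_capacity()
    if _la_event(net.nbr, net.wgt, net.deg, st.traits, i, params.F,
                 float(params.p_delta), float(params.w_r), float(params.w0)):
        raise RuntimeError("adjacency capacity overflow")
    return net


def apply_node_deletion(net: WeightedNetwork, params: GWSNParams, rng=None) -> WeightedNetwork:
    _seed_from(rng)
    _nd_sweep(net.nbr, net.wgt, net.deg, float(params.p_nd))
    return net


def apply_link_deletion(net: WeightedNetwork, params: GWSNParams, rng=None) -> WeightedNetwork:
    _seed_from(rng)
    _ld_sweep(net.nbr, net.wgt, net.deg, float(params.p_ld))
    return net


def apply_link_aging(net: WeightedNetwork, params: GWSNParams) -> WeightedNetwork:
    """Deterministic aging sweep: w <- (1-A) w, drop w < w_th."""
    _aging_sweep(net.nbr, net.wgt, net.deg, float(params.A), float(params.w_th))
    return net


def step(net: WeightedNetwork, pop: Population, params: GWSNParams, rng=None) -> WeightedNetwork:
    """Advance the model by one Monte Carlo step (in place; returns net)."""
    _seed_from(rng)
    st = _SimState(net, pop, params)
    net._ensure_capacity()
    if _step_kernel(*st.kernel_args(), st.perm, st.mark):
        raise RuntimeError("adjacency capacity overflow")
    return net


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Checkpoints and final state of one simulation run."""

    checkpoints: list  # [(t, NetworkProperties)]
    aborted: bool
    abort_step: int | None
    network: WeightedNetwork
    population: Population
    params: GWSNParams
    protocol: SimulationProtocol

    @property
    def checkpoint_times(self) -> list:
        return [t for t, _ in self.checkpoints]


def run(params: GWSNParams, protocol: SimulationProtocol,
        compute_properties=None) -> RunResult:
    """Execute one full GWSN simulation.

    The run starts from an empty network, iterates the per-step dynamics
    to ``protocol.t_max`` and records network properties at every
    multiple of ``protocol.measure_every``.  If the average degree
    exceeds ``protocol.k_th`` at a checkpoint, the run is aborted: the
    triggering checkpoint is not recorded and ``aborted`` is set.

    A single seed (``protocol.seed``) drives the whole run: population
    initialization consumes the Python-level stream first, then a
    derived seed initializes the kernel RNG; the checkpoint property
    evaluation (percolation tie-shuffles) continues on the Python stream.

    ``compute_properties(net, rng) -> NetworkProperties`` may be injected;
    by default the full nine-statistic suite from :mod:`gwsn.netprops`.
    """
    from . import netprops  # local import to avoid a cycle at import time

    if compute_properties is None:
        compute_properties = lambda net, rng: netprops.compute_all(net, rng=rng)

    rng = np.random.default_rng(protocol.seed)
    pop = init_population(params, rng)
    net = WeightedNetwork(params.N)
    _seed_kernel_rng(int(rng.integers(0, 2**32)))
    state = _SimState(net, pop, params)

    checkpoints = []
    aborted = False
    abort_step = None
    t = 0
    while t < protocol.t_max:
        target = min(t + protocol.measure_every, protocol.t_max)
        remaining = target - t
        while remaining > 0:
            done, status = _run_steps(*state.kernel_args(), state.perm, state.mark,
                                      remaining, _GROW_MARGIN)
            t += done
            remaining -= done
            if status == 1:
                raise RuntimeError("adjacency capacity overflow mid-step")
            if status == 2:
                net._grow(2 * net.nbr.shape[1])
                state = _SimState(net, pop, params)
        if net.average_degree > protocol.k_th:
            aborted = True
            abort_step = t
            logger.info("run aborted at t=%d: <k>=%.1f > k_th=%.1f",
                        t, net.average_degree, protocol.k_th)
            break
        checkpoints.append((t, compute_properties(net, rng)))
    return RunResult(checkpoints=checkpoints, aborted=aborted, abort_step=abort_step,
                     network=net, population=pop, params=params, protocol=protocol)
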