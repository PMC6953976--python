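"""Modified preferential-attachment network model.

A network over ``m`` nodes grows sequentially: two founders form a dyad, and
each subsequent entrant draws a censored-Poisson number of edges back into
the existing network, attaching to existing nodes by weighted sampling
without replacement.  The weight of an existing node mixes its current
degree (classical preferential attachment) with its recency of entry,
governed by ``gamma`` in [0, 1]; ``gamma = 0`` is the pure
degree-proportional rule.

The exact probability of a realised graph given the entry order is the
product over entry steps of the censored-Poisson pmf and the
without-replacement selection probability of the realised neighbour set;
see :func:`log_graph_given_order`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from . import _kernels
from .graphs import Graph, NetworkOrder, back_degrees

__all__ = [
    "PaParams",
    "cpois_logpmf",
    "cpois_sample",
    "cpois_mean",
    "attachment_weights",
    "sample_attachment_set",
    "generate_pa_network",
    "log_graph_given_order",
    "mu_star",
    "enumerate_supported_graphs",
]


@dataclass(frozen=True)
class PaParams:
    """Network parameters: censored-Poisson mean ``mu`` and PA mixture ``gamma``."""

    mu: float
    gamma: float = 0.0

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


def mu_star(mu: float) -> float:
    """Mean connectivity ``mu + e^{-mu}``; the large-network mean of the
    censored edge-count distribution.  Minimum 1 at mu = 0."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return float(mu + math.exp(-mu))


def cpois_logpmf(x: int, mu: float, i: int) -> float:
    """Log-pmf of the censored Poisson edge count for the i-th entrant.

    Support is {1, ..., i-1}: the Poisson mass at 0 is moved to 1 and the
    upper tail beyond i-1 is lumped at i-1 (computed through the Poisson
    survival function, i.e. the regularised incomplete gamma function).
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if int(x) != x or int(i) != i:
        raise ValueError("x and i must be integers")
    x, i = int(x), int(i)
    if i < 3:
        raise ValueError("censored edge counts apply from the third entrant on")
    if not 1 <= x <= i - 1:
        return -np.inf
    if mu == 0.0:  # degenerate limit: all mass at x = 1
        return 0.0 if x == 1 else -np.inf
    if x == i - 1:
        return float(stats.poisson.logsf(i - 2, mu))
    if x == 1:
        return float(-mu + np.log1p(mu))
    return float(stats.poisson.logpmf(x, mu))


def cpois_sample(mu: float, i: int, rng: np.random.Generator) -> int:
    """Draw from the censored Poisson on {1, ..., i-1}."""
    if not mu > 0:
        raise ValueError("mu must be positive")
    if i < 3:
        raise ValueError("i must be at least 3")
    z = int(rng.poisson(mu))
    return min(max(z, 1), i - 1)


def cpois_mean(mu: float, i: int) -> float:
    """Exact mean of the censored edge-count distribution (by summation)."""
    xs = np.arange(1, i)
    pmf = np.exp([cpois_logpmf(int(x), mu, i) for x in xs])
    return float((xs * pmf).sum())


def attachment_weights(prefix_degrees: np.ndarray, gamma: float) -> np.ndarray:
    """Attachment weights over the first i-1 entrants.

    ``prefix_degrees[j-1]`` is the degree of the j-th entrant within the
    network restricted to the first i-1 entrants.  The weight mixes the
    degree share with the recency share j / (1 + 2 + ... + (i-1)).
    """
    d = np.asarray(prefix_degrees, dtype=float)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    total = d.sum()
    if total <= 0:
        raise ValueError("total prefix degree must be positive")
    n = d.size
    recency = np.arange(1, n + 1) / (n * (n + 1) / 2.0)
    return (1.0 - gamma) * d / total + gamma * recency


def sample_attachment_set(
    weights: np.ndarray, x: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``x`` distinct indices by successive weighted sampling.

    One index is drawn at a time; its weight is removed and the remainder
    renormalised before the next draw.  Returns 0-based indices in draw
    order.
    """
    w = np.array(weights, dtype=float)
    if x > w.size:
        raise ValueError("cannot draw more items than there are weights")
    if x < 1:
        raise ValueError("x must be at least 1")
    chosen = np.empty(x, dtype=np.int64)
    for t in range(x):
        p = w / w.sum()
        idx = int(rng.choice(w.size, p=p))
        chosen[t] = idx
        w[idx] = 0.0
    return chosen


def generate_pa_network(
    m: int,
    params: PaParams,
    rng: np.random.Generator,
    order: NetworkOrder | str | None = "random",
) -> tuple[Graph, NetworkOrder]:
    """Grow a preferential-attachment network of ``m`` nodes.

    With ``order="random"`` the entry order is drawn uniformly over
    permutations (matching the uniform prior on the network order); a
    :class:`NetworkOrder` pins it instead.  The resulting graph is always
    connected and lies in the support of :func:`log_graph_given_order`.
    """
    if m < 2:
        raise ValueError("need at least 2 nodes")
    if order is None or (isinstance(order, str) and order == "random"):
        o = rng.permutation(m).astype(np.int64)
        order = NetworkOrder.from_array0(o)
    elif isinstance(order, NetworkOrder):
        if order.m != m:
            raise ValueError("order size differs from m")
        o = order.as_array0()
    else:
        raise ValueError("order must be 'random' or a NetworkOrder")
    adj = np.zeros((m, m), dtype=bool)
    adj[o[0], o[1]] = adj[o[1], o[0]] = True
    deg = np.zeros(m)  # degree by entry position, within current prefix
    deg[0] = deg[1] = 1.0
    for p in range(2, m):
        x = cpois_sample(params.mu, p + 1, rng)
        w = attachment_weights(deg[:p], params.gamma)
        targets = sample_attachment_set(w, x, rng)
        v = o[p]
        for q in targets:
            adj[v, o[q]] = adj[o[q], v] = True
            deg[q] += 1.0
        deg[p] = x
    return Graph(adj), order


# ---------------------------------------------------------------------------
# exact graph density given the entry order
# ---------------------------------------------------------------------------

def _cpois_tables(mu: float, m: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Poisson log-pmf/log-tail tables feeding the compiled kernel."""
    z = np.arange(m + 1)
    logpmf = stats.poisson.logpmf(z, mu)
    # logtail[k] = log P(Z >= k)
    logtail = np.empty(m + 1)
    logtail[0] = 0.0
    logtail[1:] = stats.poisson.logsf(z[:-1], mu)
    log1mass = float(-mu + np.log1p(mu)) if mu > 0 else 0.0
    return np.ascontiguousarray(logpmf), np.ascontiguousarray(logtail), log1mass


def log_graph_given_order(
    g: Graph, order: NetworkOrder, params: PaParams
) -> float:
    """Exact log probability of the graph given the entry order.

    Product over entry steps of the censored-Poisson pmf of the backward
    edge count and the without-replacement selection probability of the
    realised neighbour set.  Returns -inf off support (the dyad edge absent,
    or some entrant with no backward edge).
    """
    if g.m != order.m:
        raise ValueError("graph and order sizes differ")
    logpmf, logtail, log1mass = _cpois_tables(params.mu, g.m)
    return float(
        _kernels.pa_order_loglik(
            g.adj.astype(np.uint8),
            order.as_array0(),
            float(params.gamma),
            logpmf,
            logtail,
            log1mass,
        )
    )


def _set_logprob_bruteforce(weights: np.ndarray, chosen: list[int]) -> float:
    """Reference selection-set probability: explicit sum over draw orders.

    Exponential cost; intended for oracle tests on tiny sets only.
    """
    w = np.asarray(weights, dtype=float)
    p = 0.0
    for perm in itertools.permutations(chosen):
        q = 1.0
        used = 0.0
        for idx in perm:
            q *= w[idx] / (1.0 - used)
            used += w[idx]
        p += q
    return math.log(p)


def log_graph_given_order_ref(
    g: Graph, order: NetworkOrder, params: PaParams
) -> float:
    """Pure-Python reference for :func:`log_graph_given_order`.

    Same constructive density, but with the selection probability evaluated
    by brute-force enumeration of draw orders; used to validate the compiled
    kernel on small graphs.
    """
    m = g.m
    o = order.as_array0()
    if not g.adj[o[0], o[1]]:
        return -np.inf
    deg = np.zeros(m)
    deg[0] = deg[1] = 1.0
    total = 0.0
    for p in range(2, m):
        v = o[p]
        chosen = [q for q in range(p) if g.adj[v, o[q]]]
        x = len(chosen)
        if x == 0:
            return -np.inf
        total += cpois_logpmf(x, params.mu, p + 1)
        w = attachment_weights(deg[:p], params.gamma)
        total += _set_logprob_bruteforce(w, chosen)
        for q in chosen:
            deg[q] += 1.0
        deg[p] = x
    return float(total)


def enumerate_supported_graphs(
    m: int, order: NetworkOrder | None = None
) -> Iterator[Graph]:
    """All graphs with positive probability under a fixed entry order.

    Exponential in C(m, 2); a diagnostic for normalisation checks at m <= 5.
    """
    order = NetworkOrder.identity(m) if order is None else order
    pairs = list(itertools.combinations(range(1, m + 1), 2))
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, b in zip(pairs, bits) if b]
        g = Graph.from_edges(m, edges)
        x = back_degrees(g, order)
        if x[0] == 1 and np.all(x[1:] >= 1):
            yield g
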