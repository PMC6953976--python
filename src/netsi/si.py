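"""Markovian SI epidemic on a fixed contact network.

Every infected individual makes infectious contacts along each of its graph
edges at rate ``beta``; a contact with a susceptible neighbour infects it.
Because clocks are exponential this is equivalent to a race of independent
per-edge Exponential(beta) clocks across the infected-susceptible cut, and
on a connected graph every node is eventually infected.

The path density of an observed epidemic factorises into a transmission-tree
probability (who infected whom: uniform over the earlier-infected neighbours
of each node) and an infection-times density driven by the total edge
exposure sum_{i<j} G_ij (t_j - t_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import Epidemic, Graph, NetworkOrder, validate_epidemic

__all__ = [
    "EpiParams",
    "SiSample",
    "simulate_si",
    "log_tree_given_graph",
    "log_times_given_graph",
    "edge_exposure",
    "total_exposure",
    "predictive_counts",
]


@dataclass(frozen=True)
class EpiParams:
    """Per-edge infection rate ``beta`` (per unit time)."""

    beta: float

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class SiSample:
    """One realised SI epidemic.

    ``epidemic`` is expressed in epidemic-order labels (valid
    :class:`Epidemic`); ``perm0`` maps original 0-based node indices to
    epidemic-order 0-based indices, so the true contact network and entry
    order can be carried into the epidemic labelling.  ``times_raw`` /
    ``parents_raw`` keep the unrelabelled view (0-based, parent -1 for the
    index case).
    """

    epidemic: Epidemic | None
    perm0: np.ndarray
    times_raw: np.ndarray
    parents_raw: np.ndarray

    def relabel_graph(self, g: Graph) -> Graph:
        """The contact network re-expressed in epidemic-order labels."""
        p = self.perm0
        adj = np.zeros_like(g.adj)
        adj[np.ix_(p, p)] = g.adj
        return Graph(adj)

    def relabel_order(self, order: NetworkOrder) -> NetworkOrder:
        """The network entry order re-expressed in epidemic-order labels."""
        return NetworkOrder.from_array0(self.perm0[order.as_array0()])


def simulate_si(
    g: Graph, beta: float, rng: np.random.Generator, relabel: bool = True
) -> SiSample:
    """Simulate an SI epidemic on ``g`` started from node 1, to completion.

    Uses the Markov-chain form of the per-edge exponential race: the waiting
    time to the next infection is Exponential(beta x cut size), the new
    infectee is chosen proportionally to its number of infected neighbours,
    and its infector uniformly among those neighbours.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    m = g.m
    if not g.is_connected():
        raise ValueError("SI epidemic on a disconnected graph never completes")
    adj = g.adj
    infected = np.zeros(m, dtype=bool)
    infected[0] = True
    # number of infected neighbours per node
    k = adj[:, 0].astype(np.int64).copy()
    times = np.zeros(m)
    parents = np.full(m, -1, dtype=np.int64)
    t = 0.0
    seq = [0]
    for _ in range(m - 1):
        k_sus = np.where(infected, 0, k)
        total = k_sus.sum()
        t += rng.exponential(1.0 / (beta * total))
        s = int(rng.choice(m, p=k_sus / total))
        nbrs = np.flatnonzero(adj[s] & infected)
        parents[s] = int(nbrs[rng.integers(nbrs.size)])
        times[s] = t
        infected[s] = True
        k += adj[s].astype(np.int64)
        seq.append(s)
    seq_arr = np.asarray(seq, dtype=np.int64)
    perm0 = np.empty(m, dtype=np.int64)
    perm0[seq_arr] = np.arange(m)
    ep = None
    if relabel:
        new_times = times[seq_arr]
        new_parents = {
            int(perm0[s]) + 1: int(perm0[parents[s]]) + 1
            for s in range(m)
            if parents[s] >= 0
        }
        ep = Epidemic(new_times, new_parents)
    return SiSample(ep, perm0, times, parents)


def log_tree_given_graph(ep: Epidemic, g: Graph) -> float:
    """Log probability of the transmission tree given the contact network.

    Each node's infector is uniform over its earlier-infected neighbours;
    the tree must sit inside the graph, with exactly one infector per
    non-index node and no reverse/self transmissions.  Violations give -inf.
    """
    bad = validate_epidemic(ep)
    if bad:
        raise ValueError("invalid epidemic: " + "; ".join(bad))
    if g.m != ep.m:
        raise ValueError("graph size differs from epidemic size")
    total = 0.0
    for j in range(2, ep.m + 1):
        i = ep.parents[j]
        if not g.has_edge(i, j):
            return -np.inf
        n_earlier = int(g.adj[j - 1, : j - 1].sum())
        total -= np.log(n_earlier)
    return float(total)


def edge_exposure(ep: Epidemic, i: int, j: int) -> float:
    """Exposure contributed by pair (i, j), i < j: the time node j spent
    susceptible while node i was infected (t_j - t_i for an SI epidemic
    observed to completion)."""
    if not i < j:
        raise ValueError("require i < j")
    return float(ep.times[j - 1] - ep.times[i - 1])


def total_exposure(ep: Epidemic, g: Graph) -> float:
    """Total edge exposure sum_{i<j} G_ij (t_j - t_i)."""
    t = ep.times
    gaps = np.abs(t[:, None] - t[None, :])
    return float((gaps * g.adj).sum() / 2.0)


def log_times_given_graph(ep: Epidemic, g: Graph, beta: float) -> float:
    """Log density of the infection times given graph and rate:
    (m-1) log beta - beta * total exposure."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    return float((ep.m - 1) * np.log(beta) - beta * total_exposure(ep, g))


def predictive_counts(
    beta_draws: np.ndarray,
    mu_draws: np.ndarray,
    m: int,
    time_grid: np.ndarray,
    n_sims: int,
    rng: np.random.Generator,
    gamma: float = 0.0,
) -> dict[str, np.ndarray]:
    """Posterior-predictive cumulative infection counts over a time grid.

    For each simulation a (beta, mu) pair is drawn from the posterior
    sample, a preferential-attachment network is generated with a random
    entry order, an SI epidemic is simulated on it, and the infections up to
    each grid time are counted.  Returns pointwise 2.5%/50%/97.5% quantiles
    (the 95% predictive interval and median).
    """
    from .pa import PaParams, generate_pa_network  # local import: avoid cycle

    beta_draws = np.asarray(beta_draws, dtype=float)
    mu_draws = np.asarray(mu_draws, dtype=float)
    if beta_draws.size == 0 or beta_draws.size != mu_draws.size:
        raise ValueError("need matching non-empty posterior draws")
    time_grid = np.asarray(time_grid, dtype=float)
    counts = np.empty((n_sims, time_grid.size), dtype=np.int64)
    for s in range(n_sims):
        idx = int(rng.integers(beta_draws.size))
        g, _ = generate_pa_network(m, PaParams(mu_draws[idx], gamma), rng)
        sim = simulate_si(g, beta_draws[idx], rng)
        counts[s] = np.searchsorted(sim.epidemic.times, time_grid, side="right")
    lo, med, hi = np.quantile(counts, [0.025, 0.5, 0.975], axis=0)
    return {
        "time": time_grid,
        "lower": lo,
        "median": med,
        "upper": hi,
        "counts": counts,
    }
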