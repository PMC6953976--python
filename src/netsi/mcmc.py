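"""Metropolis-within-Gibbs sampler for the latent-network SI model.

The joint target is the posterior of (beta, mu, gamma, sigma, G) given the
transmission tree and infection times, proportional to

    pi(P | G) pi(t | G, beta) pi(G | mu, gamma, sigma)
        x Gamma(beta) Gamma(mu) U[0,1](gamma) Uniform(sigma).

Component updates:

* ``beta`` — conjugate Gibbs draw, Gamma(a_beta + m - 1, b_beta + E) with E
  the total edge exposure;
* ``mu``, ``gamma`` — Gaussian random-walk Metropolis, adapted during
  burn-in toward ~0.25 acceptance;
* ``sigma`` — random transpositions of the entry order;
* each unknown potential edge — delayed-acceptance Metropolis flips.

The Bernoulli-random-graph (BRG) comparison model replaces the network
density with p^{|G|} (1-p)^{C(m,2)-|G|}; ``p`` then has a conjugate Beta
update and the entry order and network parameters disappear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import _kernels
from .graphs import (
    Epidemic,
    Graph,
    GraphObservation,
    KNOWN_PRESENT,
    NetworkOrder,
    validate_epidemic,
)
from .pa import _cpois_tables, mu_star

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "BrgParams",
    "Trace",
    "TraceSummary",
    "run_mwg",
    "run_brg_mwg",
    "alpha_trace",
    "summarize",
    "binomial_degree_tail",
    "MwgSampler",
    "BrgSampler",
]

_ADAPT_BATCH = 50
_TARGET_ACCEPT = 0.25
_REFRESH_EVERY = 250  # periodic exact refresh of incrementally-updated caches


@dataclass(frozen=True)
class PriorSpec:
    """Vaguely informative independent priors.

    Gamma(shape, rate) on beta and mu; U[0,1] on gamma; uniform over
    permutations on the entry order.  ``a_p``/``b_p`` are the Beta
    hyperparameters of the edge-inclusion probability in the BRG comparison
    model (flat by default).
    """

    a_beta: float = 1.0
    b_beta: float = 0.001
    a_mu: float = 1.0
    b_mu: float = 0.001
    a_p: float = 1.0
    b_p: float = 1.0

    def __post_init__(self):
        for name in ("a_beta", "b_beta", "a_mu", "b_mu", "a_p", "b_p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``gamma_fixed=None`` estimates gamma; a float fixes it (default 0,
    the pure preferential-attachment rule).  ``edges_per_iter=None`` sweeps
    every unknown potential edge once per iteration in a freshly shuffled
    order; an integer proposes that many uniformly chosen unknown pairs
    instead.  ``sigma_moves_per_iter=None`` defaults to m transpositions.
    Adaptation of the random-walk proposal scales runs during burn-in only.
    """

    n_iter: int = 20000
    n_burnin: int = 10000
    gamma_fixed: float | None = 0.0
    proposal_sd_mu: float = 1.0
    proposal_sd_gamma: float = 0.1
    adapt: bool = True
    edges_per_iter: int | None = None
    sigma_moves_per_iter: int | None = None
    seed: int = 0
    thin: int = 1
    init_beta: float | None = None
    init_mu: float | None = None
    init_gamma: float | None = None
    store_sigma: bool = False
    track_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.proposal_sd_mu <= 0 or self.proposal_sd_gamma <= 0:
            raise ValueError("proposal standard deviations must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.gamma_fixed is not None and not 0 <= self.gamma_fixed <= 1:
            raise ValueError("gamma_fixed must lie in [0, 1]")


@dataclass(frozen=True)
class BrgParams:
    """Bernoulli-random-graph parameters: edge probability and epidemic rate."""

    p: float
    beta: float

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass
class Trace:
    """Posterior sample of the scalar parameters plus edge summaries."""

    model: str  # "pa" or "brg"
    beta: np.ndarray
    logpost: np.ndarray
    edge_freq: np.ndarray  # m x m posterior edge-inclusion frequencies
    accept: dict[str, tuple[int, int]]  # update -> (accepted, attempted)
    m: int
    n_burnin: int
    mu: np.ndarray | None = None
    gamma: np.ndarray | None = None
    p: np.ndarray | None = None
    sigma: np.ndarray | None = None  # optional (n_kept, m) entry orders
    pair_series: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.beta.size

    def edge_probability(self, i: int, j: int) -> float:
        return float(self.edge_freq[i - 1, j - 1])


def alpha_trace(trace: Trace) -> np.ndarray:
    """Per-sample network scaled epidemic rate alpha = beta * (mu + e^-mu)."""
    if trace.mu is None:
        raise ValueError("alpha requires a PA-model trace")
    if trace.beta.size == 0:
        raise ValueError("empty trace")
    return trace.beta * (trace.mu + np.exp(-trace.mu))


def binomial_degree_tail(n: int, mean_degree: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, mean_degree / n).

    The degree-tail computation used to judge the plausibility of a
    Bernoulli random graph: with m - 1 = n potential neighbours and average
    degree ``mean_degree``, how likely is a node with >= k neighbours?
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < mean_degree < n:
        raise ValueError("mean_degree must lie in (0, n)")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, mean_degree / n))


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _log_gamma_prior(x: float, a: float, b: float) -> float:
    return (a - 1.0) * math.log(x) - b * x


class MwgSampler:
    """Mutable sampler state plus component updates for the PA model.

    Holds the current (beta, mu, gamma, order, graph) with cached likelihood
    pieces: L4 (tree log-probability), E (total exposure, giving the times
    term), L6 (graph-given-order log density), earlier-neighbour counts and
    the censored-Poisson tables for the current mu.
    """

    def __init__(
        self,
        ep: Epidemic,
        priors: PriorSpec | None = None,
        config: McmcConfig | None = None,
        obs: GraphObservation | None = None,
    ):
        bad = validate_epidemic(ep)
        if bad:
            raise ValueError("invalid epidemic: " + "; ".join(bad))
        self.ep = ep
        self.priors = priors or PriorSpec()
        self.config = config or McmcConfig()
        m = ep.m
        self.m = m
        self.times = np.ascontiguousarray(ep.times, dtype=float)
        obs = obs if obs is not None else GraphObservation.tree_only(ep)
        if obs.m != m:
            raise ValueError("observation size differs from epidemic")
        obs = GraphObservation(obs.status.copy())
        for i, j in ep.tree_pairs():
            obs.set_status(i, j, KNOWN_PRESENT)
        obs.check_consistent(ep)
        self.obs = obs
        self.free_pairs = obs.free_pairs0()
        self.rng = np.random.default_rng(self.config.seed)

        # initial state: entry order = epidemic order; graph = all known-
        # present pairs (tree edges included); this always has finite
        # posterior density because each node's infector precedes it.
        self.order = np.arange(m, dtype=np.int64)
        self.adj = (obs.status == KNOWN_PRESENT).astype(np.uint8)
        self.ecount = self._earlier_counts()
        self.E = self._exposure()
        self.L4 = self._tree_logprob()
        cfg = self.config
        self.beta = (
            cfg.init_beta if cfg.init_beta is not None else (m - 1) / self.E
        )
        self.mu = cfg.init_mu if cfg.init_mu is not None else 1.0
        if cfg.gamma_fixed is not None:
            self.gamma = cfg.gamma_fixed
        else:
            self.gamma = cfg.init_gamma if cfg.init_gamma is not None else 0.5
        self.sd_mu = cfg.proposal_sd_mu
        self.sd_gamma = cfg.proposal_sd_gamma
        self.tables = _cpois_tables(self.mu, m)
        self.L6 = self._graph_loglik()
        if not np.isfinite(self.L6):
            raise ValueError("initial state has zero posterior support")
        self.acc = {"mu": [0, 0], "gamma": [0, 0], "sigma": [0, 0], "edges": [0, 0]}

    # -- cached-quantity recomputation ------------------------------------
    def _earlier_counts(self) -> np.ndarray:
        c = np.array(
            [int(self.adj[j, :j].sum()) for j in range(self.m)], dtype=np.int64
        )
        if (c[1:] == 0).any():
            raise ValueError("some node has no earlier-infected neighbour")
        return c

    def _exposure(self) -> float:
        gaps = np.abs(self.times[:, None] - self.times[None, :])
        return float((gaps * self.adj).sum() / 2.0)

    def _tree_logprob(self) -> float:
        return float(-np.log(self.ecount[1:].astype(float)).sum())

    def _graph_loglik(self, order=None, gamma=None, tables=None) -> float:
        order = self.order if order is None else order
        gamma = self.gamma if gamma is None else gamma
        logpmf, logtail, log1mass = self.tables if tables is None else tables
        return float(
            _kernels.pa_order_loglik(
                self.adj, order, gamma, logpmf, logtail, log1mass
            )
        )

    def log_posterior(self) -> float:
        pr = self.priors
        L5 = (self.m - 1) * math.log(self.beta) - self.beta * self.E
        return (
            self.L4
            + L5
            + self.L6
            + _log_gamma_prior(self.beta, pr.a_beta, pr.b_beta)
            + _log_gamma_prior(self.mu, pr.a_mu, pr.b_mu)
        )

    # -- component updates -------------------------------------------------
    def step_beta(self) -> float:
        """Conjugate Gibbs draw of the infection rate."""
        if self.E <= 0:
            raise ValueError("zero exposure: cannot update beta")
        pr = self.priors
        self.beta = float(
            self.rng.gamma(pr.a_beta + self.m - 1, 1.0 / (pr.b_beta + self.E))
        )
        return self.beta

    def step_mu(self) -> bool:
        """Random-walk Metropolis update of the censored-Poisson mean."""
        z = self.rng.normal()
        u = self.rng.random()
        prop = self.mu + self.sd_mu * z
        self.acc["mu"][1] += 1
        if prop <= 0:
            return False
        tables = _cpois_tables(prop, self.m)
        L6p = self._graph_loglik(tables=tables)
        pr = self.priors
        delta = (
            L6p
            - self.L6
            + _log_gamma_prior(prop, pr.a_mu, pr.b_mu)
            - _log_gamma_prior(self.mu, pr.a_mu, pr.b_mu)
        )
        if math.log(u) < delta:
            self.mu = prop
            self.tables = tables
            self.L6 = L6p
            self.acc["mu"][0] += 1
            return True
        return False

    def step_gamma(self) -> bool:
        """Random-walk Metropolis update of the PA mixture parameter."""
        if self.config.gamma_fixed is not None:
            raise ValueError("gamma is fixed; update_gamma must not be called")
        z = self.rng.normal()
        u = self.rng.random()
        prop = self.gamma + self.sd_gamma * z
        self.acc["gamma"][1] += 1
        if not 0.0 <= prop <= 1.0:
            return False
        L6p = self._graph_loglik(gamma=prop)
        if math.log(u) < L6p - self.L6:
            self.gamma = prop
            self.L6 = L6p
            self.acc["gamma"][0] += 1
            return True
        return False

    def step_sigma(self) -> bool:
        """Propose a random transposition of the entry order."""
        a = int(self.rng.integers(self.m))
        b = int(self.rng.integers(self.m))
        u = self.rng.random()
        self.acc["sigma"][1] += 1
        if a == b:
            self.acc["sigma"][0] += 1
            return True
        self.order[a], self.order[b] = self.order[b], self.order[a]
        L6p = self._graph_loglik()
        if math.log(u) < L6p - self.L6:
            self.L6 = L6p
            self.acc["sigma"][0] += 1
            return True
        self.order[a], self.order[b] = self.order[b], self.order[a]
        return False

    def step_edges(self) -> int:
        """One pass of delayed-acceptance Metropolis flips over unknown pairs."""
        nfree = self.free_pairs.shape[0]
        if nfree == 0:
            return 0
        k = self.config.edges_per_iter
        if k is None:
            pairs = self.free_pairs[self.rng.permutation(nfree)]
        else:
            pairs = self.free_pairs[self.rng.integers(0, nfree, size=k)]
        logu = np.log(self.rng.random((pairs.shape[0], 2)))
        logpmf, logtail, log1mass = self.tables
        L6, dL4, dE, nacc = _kernels.pa_edge_sweep(
            self.adj,
            self.order,
            np.ascontiguousarray(pairs),
            logu,
            self.beta,
            self.gamma,
            self.times,
            self.ecount,
            logpmf,
            logtail,
            log1mass,
            self.L6,
        )
        self.L6 = float(L6)
        self.L4 += float(dL4)
        self.E += float(dE)
        self.acc["edges"][0] += int(nacc)
        self.acc["edges"][1] += pairs.shape[0]
        return int(nacc)

    # conventional names for the component updates
    update_beta = step_beta
    update_mu = step_mu
    update_gamma = step_gamma
    update_sigma = step_sigma
    update_edges = step_edges

    # -- main loop ---------------------------------------------------------
    def run(self) -> Trace:
        cfg = self.config
        m = self.m
        n_sigma = cfg.sigma_moves_per_iter if cfg.sigma_moves_per_iter is not None else m
        n_kept = (cfg.n_iter - cfg.n_burnin + cfg.thin - 1) // cfg.thin
        beta_s = np.empty(n_kept)
        mu_s = np.empty(n_kept)
        gamma_s = np.empty(n_kept)
        lp_s = np.empty(n_kept)
        edge_freq = np.zeros((m, m))
        sigma_s = np.empty((n_kept, m), dtype=np.int64) if cfg.store_sigma else None
        pair_idx = [(i - 1, j - 1) for i, j in cfg.track_pairs]
        pair_s = {ij: np.empty(n_kept, dtype=np.int8) for ij in cfg.track_pairs}
        batch_acc = {"mu": 0, "gamma": 0}
        kept = 0
        for it in range(1, cfg.n_iter + 1):
            self.step_beta()
            before = self.acc["mu"][0]
            self.step_mu()
            batch_acc["mu"] += self.acc["mu"][0] - before
            if cfg.gamma_fixed is None:
                before = self.acc["gamma"][0]
                self.step_gamma()
                batch_acc["gamma"] += self.acc["gamma"][0] - before
            for _ in range(n_sigma):
                self.step_sigma()
            self.step_edges()
            # adapt proposal scales during burn-in only
            if cfg.adapt and it <= cfg.n_burnin and it % _ADAPT_BATCH == 0:
                bidx = it // _ADAPT_BATCH
                rate = batch_acc["mu"] / _ADAPT_BATCH
                self.sd_mu *= math.exp((rate - _TARGET_ACCEPT) / math.sqrt(bidx))
                if cfg.gamma_fixed is None:
                    rate = batch_acc["gamma"] / _ADAPT_BATCH
                    self.sd_gamma *= math.exp(
                        (rate - _TARGET_ACCEPT) / math.sqrt(bidx)
                    )
                batch_acc = {"mu": 0, "gamma": 0}
            if it % _REFRESH_EVERY == 0:
                # guard against float drift in the incremental caches
                self.ecount = self._earlier_counts()
                self.E = self._exposure()
                self.L4 = self._tree_logprob()
            if it > cfg.n_burnin and (it - cfg.n_burnin - 1) % cfg.thin == 0:
                beta_s[kept] = self.beta
                mu_s[kept] = self.mu
                gamma_s[kept] = self.gamma
                lp_s[kept] = self.log_posterior()
                edge_freq += self.adj
                if sigma_s is not None:
                    sigma_s[kept] = self.order
                for (i, j), (i0, j0) in zip(cfg.track_pairs, pair_idx):
                    pair_s[(i, j)][kept] = self.adj[i0, j0]
                kept += 1
        edge_freq /= max(kept, 1)
        return Trace(
            model="pa",
            beta=beta_s,
            mu=mu_s,
            gamma=gamma_s,
            logpost=lp_s,
            edge_freq=edge_freq,
            accept={k: (v[0], v[1]) for k, v in self.acc.items()},
            m=m,
            n_burnin=cfg.n_burnin,
            sigma=sigma_s,
            pair_series=pair_s,
        )


class BrgSampler:
    """Gibbs/Metropolis sampler for the Bernoulli-random-graph comparison model."""

    def __init__(
        self,
        ep: Epidemic,
        priors: PriorSpec | None = None,
        config: McmcConfig | None = None,
        obs: GraphObservation | None = None,
    ):
        bad = validate_epidemic(ep)
        if bad:
            raise ValueError("invalid epidemic: " + "; ".join(bad))
        self.ep = ep
        self.priors = priors or PriorSpec()
        self.config = config or McmcConfig()
        m = ep.m
        self.m = m
        self.times = np.ascontiguousarray(ep.times, dtype=float)
        obs = obs if obs is not None else GraphObservation.tree_only(ep)
        obs = GraphObservation(obs.status.copy())
        for i, j in ep.tree_pairs():
            obs.set_status(i, j, KNOWN_PRESENT)
        obs.check_consistent(ep)
        self.obs = obs
        self.free_pairs = obs.free_pairs0()
        self.rng = np.random.default_rng(self.config.seed)
        self.adj = (obs.status == KNOWN_PRESENT).astype(np.uint8)
        self.ecount = np.array(
            [int(self.adj[j, :j].sum()) for j in range(m)], dtype=np.int64
        )
        if (self.ecount[1:] == 0).any():
            raise ValueError("some node has no earlier-infected neighbour")
        gaps = np.abs(self.times[:, None] - self.times[None, :])
        self.E = float((gaps * self.adj).sum() / 2.0)
        self.edge_cnt = int(self.adj.sum()) // 2
        self.n_pairs = m * (m - 1) // 2
        self.beta = (m - 1) / self.E
        self.p = max(self.edge_cnt / self.n_pairs, 1.0 / self.n_pairs)
        self.acc = {"edges": [0, 0]}

    def step_beta(self) -> float:
        pr = self.priors
        self.beta = float(
            self.rng.gamma(pr.a_beta + self.m - 1, 1.0 / (pr.b_beta + self.E))
        )
        return self.beta

    def step_p(self) -> float:
        """Conjugate Beta draw of the edge-inclusion probability given G."""
        pr = self.priors
        self.p = float(
            self.rng.beta(
                pr.a_p + self.edge_cnt, pr.b_p + self.n_pairs - self.edge_cnt
            )
        )
        return self.p

    def step_edges(self) -> int:
        nfree = self.free_pairs.shape[0]
        if nfree == 0:
            return 0
        k = self.config.edges_per_iter
        if k is None:
            pairs = self.free_pairs[self.rng.permutation(nfree)]
        else:
            pairs = self.free_pairs[self.rng.integers(0, nfree, size=k)]
        logu = np.log(self.rng.random(pairs.shape[0]))
        dL4, dE, dcnt, nacc = _kernels.brg_edge_sweep(
            self.adj,
            np.ascontiguousarray(pairs),
            logu,
            self.beta,
            math.log(self.p) - math.log1p(-self.p),
            self.times,
            self.ecount,
        )
        self.E += float(dE)
        self.edge_cnt += int(dcnt)
        self.acc["edges"][0] += int(nacc)
        self.acc["edges"][1] += pairs.shape[0]
        return int(nacc)

    def log_posterior(self) -> float:
        pr = self.priors
        L4 = float(-np.log(self.ecount[1:].astype(float)).sum())
        L5 = (self.m - 1) * math.log(self.beta) - self.beta * self.E
        LG = self.edge_cnt * math.log(self.p) + (
            self.n_pairs - self.edge_cnt
        ) * math.log1p(-self.p)
        return (
            L4
            + L5
            + LG
            + _log_gamma_prior(self.beta, pr.a_beta, pr.b_beta)
            + (pr.a_p - 1) * math.log(self.p)
            + (pr.b_p - 1) * math.log1p(-self.p)
        )

    def run(self) -> Trace:
        cfg = self.config
        m = self.m
        n_kept = (cfg.n_iter - cfg.n_burnin + cfg.thin - 1) // cfg.thin
        beta_s = np.empty(n_kept)
        p_s = np.empty(n_kept)
        lp_s = np.empty(n_kept)
        edge_freq = np.zeros((m, m))
        kept = 0
        for it in range(1, cfg.n_iter + 1):
            self.step_beta()
            self.step_p()
            self.step_edges()
            if it % _REFRESH_EVERY == 0:
                self.ecount = np.array(
                    [int(self.adj[j, :j].sum()) for j in range(m)], dtype=np.int64
                )
                gaps = np.abs(self.times[:, None] - self.times[None, :])
                self.E = float((gaps * self.adj).sum() / 2.0)
                self.edge_cnt = int(self.adj.sum()) // 2
            if it > cfg.n_burnin and (it - cfg.n_burnin - 1) % cfg.thin == 0:
                beta_s[kept] = self.beta
                p_s[kept] = self.p
                lp_s[kept] = self.log_posterior()
                edge_freq += self.adj
                kept += 1
        edge_freq /= max(kept, 1)
        return Trace(
            model="brg",
            beta=beta_s,
            p=p_s,
            logpost=lp_s,
            edge_freq=edge_freq,
            accept={k: (v[0], v[1]) for k, v in self.acc.items()},
            m=m,
            n_burnin=cfg.n_burnin,
        )


def run_mwg(
    ep: Epidemic,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    obs: GraphObservation | None = None,
) -> Trace:
    """Run the full Metropolis-within-Gibbs chain for the PA model."""
    return MwgSampler(ep, priors, config, obs).run()


def run_brg_mwg(
    ep: Epidemic,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    obs: GraphObservation | None = None,
) -> Trace:
    """Run the sampler for the Bernoulli-random-graph comparison model."""
    return BrgSampler(ep, priors, config, obs).run()


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class TraceSummary:
    """Posterior means/SDs, the key correlation and acceptance rates."""

    model: str
    mean: dict[str, float]
    sd: dict[str, float]
    correlation: float  # corr(beta, mu*) for PA, corr(beta, p) for BRG
    accept_rate: dict[str, float]
    edge_freq: np.ndarray

    def to_text(self) -> str:
        lines = [f"model: {self.model}"]
        lines.append(f"{'parameter':<10}{'mean':>12}{'sd':>12}")
        for k in self.mean:
            sd = self.sd[k]
            sd_txt = f"{sd:>12.4g}" if np.isfinite(sd) else f"{'nan':>12}"
            lines.append(f"{k:<10}{self.mean[k]:>12.4g}{sd_txt}")
        label = "corr(beta, mu*)" if self.model == "pa" else "corr(beta, p)"
        lines.append(f"{label}: {self.correlation:.3f}"
                     if np.isfinite(self.correlation)
                     else f"{label}: nan")
        for k, v in self.accept_rate.items():
            lines.append(f"acceptance[{k}]: {v:.3f}")
        return "\n".join(lines)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def summarize(trace: Trace) -> TraceSummary:
    """Posterior summary in the layout of the reported parameter tables."""
    if trace.n_kept == 0:
        raise ValueError("empty trace")
    mean: dict[str, float] = {"beta": float(trace.beta.mean())}
    sd: dict[str, float] = {"beta": float(trace.beta.std(ddof=1))
                            if trace.n_kept > 1 else float("nan")}

    def put(name, arr):
        mean[name] = float(arr.mean())
        sd[name] = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")

    if trace.model == "pa":
        put("mu", trace.mu)
        put("gamma", trace.gamma)
        put("alpha", alpha_trace(trace))
        ms = trace.mu + np.exp(-trace.mu)
        corr = _corr(trace.beta, ms)
    else:
        put("p", trace.p)
        corr = _corr(trace.beta, trace.p)
    rates = {
        k: (a / n if n else float("nan")) for k, (a, n) in trace.accept.items()
    }
    return TraceSummary(
        model=trace.model,
        mean=mean,
        sd=sd,
        correlation=corr,
        accept_rate=rates,
        edge_freq=trace.edge_freq,
    )
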