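"""Model/Results interface for fitting latent-network SI epidemics.

Usage mirrors the fitting workflow of statistical modelling packages: build
a model object from the observed epidemic (plus any partial knowledge of the
contact network), call :meth:`fit` to run the Metropolis-within-Gibbs
sampler, and read estimates, uncertainties and diagnostics off the returned
results object::

    model = PAEpidemicModel(epidemic)            # gamma fixed at 0
    res = model.fit(n_iter=20000, n_burnin=10000, seed=1)
    print(res.summary())
    res.edge_probabilities          # posterior edge-inclusion matrix
    res.predict_cumulative_counts(time_grid)

``PAEpidemicModel.simulate`` draws synthetic data from the generative model
(network growth + SI epidemic) and is the synthetic-fixture generator used
throughout the test-suite and the simulation-study harness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .graphs import Epidemic, Graph, GraphObservation, NetworkOrder
from .mcmc import (
    McmcConfig,
    PriorSpec,
    Trace,
    alpha_trace,
    run_brg_mwg,
    run_mwg,
    summarize,
)
from .pa import PaParams, generate_pa_network, mu_star
from .si import predictive_counts, simulate_si

__all__ = [
    "SimulatedEpidemic",
    "PAEpidemicModel",
    "PAEpidemicResults",
    "BRGEpidemicModel",
    "BRGEpidemicResults",
]


@dataclass(frozen=True)
class SimulatedEpidemic:
    """Synthetic epidemic in epidemic-order labels, with ground truth."""

    epidemic: Epidemic
    graph: Graph  # true contact network (epidemic labels)
    order: NetworkOrder  # true entry order (epidemic labels)
    beta: float
    mu: float
    gamma: float


class _BaseModel:
    def __init__(
        self,
        epidemic: Epidemic,
        observation: GraphObservation | None = None,
        priors: PriorSpec | None = None,
    ):
        self.epidemic = epidemic
        self.observation = observation
        self.priors = priors or PriorSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        """Build from a node/infector/time table (see :mod:`netsi.io`)."""
        from .io import epidemic_from_frame

        return cls(epidemic_from_frame(df), **kwargs)

    @classmethod
    def from_files(cls, epidemic_path, edge_status_path=None, **kwargs):
        from .io import read_edge_status, read_epidemic

        ep = read_epidemic(epidemic_path)
        obs = (
            read_edge_status(edge_status_path, ep.m)
            if edge_status_path is not None
            else None
        )
        return cls(ep, observation=obs, **kwargs)


class PAEpidemicModel(_BaseModel):
    """SI epidemic on a latent preferential-attachment contact network.

    Parameters
    ----------
    epidemic
        Transmission tree and infection times (epidemic-order labels).
    observation
        Optional partial knowledge of the contact network; transmission
        pairs are always treated as known-present.
    priors
        Gamma priors on beta and mu (vague defaults), U[0,1] on gamma,
        uniform on the entry order.
    gamma
        Value at which the PA mixture parameter is fixed (default 0, the
        pure preferential-attachment rule), or ``None`` to estimate it.
    """

    def __init__(
        self,
        epidemic: Epidemic,
        observation: GraphObservation | None = None,
        priors: PriorSpec | None = None,
        gamma: float | None = 0.0,
    ):
        super().__init__(epidemic, observation, priors)
        self.gamma = gamma

    def fit(
        self,
        n_iter: int = 20000,
        n_burnin: int = 10000,
        seed: int = 0,
        chains: int = 1,
        **config_kwargs,
    ) -> "PAEpidemicResults":
        """Run the sampler; multiple chains use consecutive seed offsets."""
        cfg = McmcConfig(
            n_iter=n_iter,
            n_burnin=n_burnin,
            seed=seed,
            gamma_fixed=self.gamma,
            **config_kwargs,
        )
        traces = [
            run_mwg(
                self.epidemic,
                self.priors,
                replace(cfg, seed=seed + c),
                self.observation,
            )
            for c in range(chains)
        ]
        return PAEpidemicResults(self, traces)

    @staticmethod
    def simulate(
        m: int,
        beta: float,
        mu: float,
        gamma: float = 0.0,
        seed: int | np.random.Generator = 0,
    ) -> SimulatedEpidemic:
        """Draw a network from the PA model and an SI epidemic on it.

        Everything is relabelled into epidemic order, so the returned graph
        and entry order are directly comparable with inference output.
        """
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        g, order = generate_pa_network(m, PaParams(mu, gamma), rng)
        sim = simulate_si(g, beta, rng)
        return SimulatedEpidemic(
            epidemic=sim.epidemic,
            graph=sim.relabel_graph(g),
            order=sim.relabel_order(order),
            beta=beta,
            mu=mu,
            gamma=gamma,
        )


class _BaseResults:
    def __init__(self, model, traces: list[Trace]):
        self.model = model
        self.traces = traces
        self.trace = self._pool(traces)
        self._summary = summarize(self.trace)

    @staticmethod
    def _pool(traces: list[Trace]) -> Trace:
        if len(traces) == 1:
            return traces[0]
        first = traces[0]
        pooled = Trace(
            model=first.model,
            beta=np.concatenate([t.beta for t in traces]),
            logpost=np.concatenate([t.logpost for t in traces]),
            edge_freq=np.mean([t.edge_freq for t in traces], axis=0),
            accept={
                k: (
                    sum(t.accept[k][0] for t in traces),
                    sum(t.accept[k][1] for t in traces),
                )
                for k in first.accept
            },
            m=first.m,
            n_burnin=first.n_burnin,
            mu=(
                np.concatenate([t.mu for t in traces])
                if first.mu is not None
                else None
            ),
            gamma=(
                np.concatenate([t.gamma for t in traces])
                if first.gamma is not None
                else None
            ),
            p=(
                np.concatenate([t.p for t in traces])
                if first.p is not None
                else None
            ),
        )
        return pooled

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._summary.mean)

    @property
    def sd(self) -> pd.Series:
        return pd.Series(self._summary.sd)

    @property
    def edge_probabilities(self) -> pd.DataFrame:
        m = self.trace.m
        labels = range(1, m + 1)
        return pd.DataFrame(self.trace.edge_freq, index=labels, columns=labels)

    @property
    def acceptance_rates(self) -> dict[str, float]:
        return self._summary.accept_rate

    def summary(self) -> str:
        return self._summary.to_text()

    def to_inference_data(self):
        """Pooled scalar samples as an ArviZ InferenceData object."""
        import arviz as az

        data = {"beta": np.stack([t.beta for t in self.traces])}
        if self.trace.model == "pa":
            data["mu"] = np.stack([t.mu for t in self.traces])
            data["gamma"] = np.stack([t.gamma for t in self.traces])
            data["alpha"] = np.stack([alpha_trace(t) for t in self.traces])
        else:
            data["p"] = np.stack([t.p for t in self.traces])
        return az.from_dict(posterior=data)


class PAEpidemicResults(_BaseResults):
    """Posterior sample and summaries for the PA latent-network model."""

    @property
    def alpha(self) -> np.ndarray:
        """Posterior sample of the network scaled epidemic rate beta * mu*."""
        return alpha_trace(self.trace)

    @property
    def corr_beta_mu_star(self) -> float:
        return self._summary.correlation

    def predict_cumulative_counts(
        self,
        time_grid: np.ndarray,
        n_sims: int = 500,
        seed: int = 0,
        gamma: float = 0.0,
    ) -> dict[str, np.ndarray]:
        """95% posterior-predictive band for cumulative infection counts."""
        rng = np.random.default_rng(seed)
        return predictive_counts(
            self.trace.beta,
            self.trace.mu,
            self.trace.m,
            time_grid,
            n_sims,
            rng,
            gamma=gamma,
        )


class BRGEpidemicModel(_BaseModel):
    """SI epidemic on a latent Bernoulli random graph (comparison model)."""

    def fit(
        self,
        n_iter: int = 3000,
        n_burnin: int = 1000,
        seed: int = 0,
        chains: int = 1,
        **config_kwargs,
    ) -> "BRGEpidemicResults":
        cfg = McmcConfig(
            n_iter=n_iter, n_burnin=n_burnin, seed=seed, **config_kwargs
        )
        traces = [
            run_brg_mwg(
                self.epidemic,
                self.priors,
                replace(cfg, seed=seed + c),
                self.observation,
            )
            for c in range(chains)
        ]
        return BRGEpidemicResults(self, traces)


class BRGEpidemicResults(_BaseResults):
    """Posterior sample and summaries for the Bernoulli-graph model."""

    @property
    def corr_beta_p(self) -> float:
        return self._summary.correlation

    @property
    def mean_degree(self) -> float:
        """Posterior-mean average degree p * (m - 1)."""
        return float(self.trace.p.mean() * (self.trace.m - 1))
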