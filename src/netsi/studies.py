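"""Simulation-study harness.

Two factorial designs probe parameter recovery and identifiability:

* **Study 1** — m = 70, beta = 0.4, gamma in {0, 0.2, 0.5, 0.8, 1} crossed
  with mu in {4, 6, 8, 10}; the full sampler (gamma estimated) is applied
  with the graph latent, probing whether the scalar parameters can be
  recovered from the transmission tree and times alone.
* **Study 2** — gamma fixed at 0; m in {30, 50, 70} crossed with
  mu in {4, 6, 8, 10} and with the proportion of non-tree potential edges
  whose status is revealed in {0, 0.25, 0.5, 1}; probing how partial
  network knowledge restores identifiability of mu.

Each cell simulates one data set, runs one chain and records posterior
means/SDs of mu, gamma and alpha = beta * (mu + e^-mu).  ``scale="mini"``
divides chain lengths by 10 for quick smoke runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import make_observation
from .mcmc import alpha_trace, summarize
from .model import PAEpidemicModel
from .pa import mu_star

__all__ = ["run_study1", "run_study2", "STUDY_PRESETS"]

_FULL_ITER = 20000
_FULL_BURNIN = 10000


def _cell_row(res, m, beta, mu, gamma, proportion=None):
    tr = res.trace
    a = alpha_trace(tr)
    row = {
        "m": m,
        "beta_true": beta,
        "mu_true": mu,
        "gamma_true": gamma,
        "alpha_true": beta * mu_star(mu),
        "beta_mean": float(tr.beta.mean()),
        "beta_sd": float(tr.beta.std(ddof=1)),
        "mu_mean": float(tr.mu.mean()),
        "mu_sd": float(tr.mu.std(ddof=1)),
        "gamma_mean": float(tr.gamma.mean()),
        "gamma_sd": float(tr.gamma.std(ddof=1)),
        "alpha_mean": float(a.mean()),
        "alpha_sd": float(a.std(ddof=1)),
        "corr_beta_mu_star": summarize(tr).correlation,
    }
    if proportion is not None:
        row["proportion"] = proportion
    return row


def run_study1(
    m: int = 70,
    beta: float = 0.4,
    mus=(4.0, 6.0, 8.0, 10.0),
    gammas=(0.0, 0.2, 0.5, 0.8, 1.0),
    n_iter: int = _FULL_ITER,
    n_burnin: int = _FULL_BURNIN,
    seed: int = 1,
    estimate_gamma: bool = True,
) -> pd.DataFrame:
    """Scalar-parameter recovery with the graph latent (gamma estimated)."""
    rows = []
    cell = 0
    for gamma in gammas:
        for mu in mus:
            sim = PAEpidemicModel.simulate(m, beta, mu, gamma, seed=seed + cell)
            model = PAEpidemicModel(
                sim.epidemic, gamma=None if estimate_gamma else 0.0
            )
            res = model.fit(n_iter=n_iter, n_burnin=n_burnin, seed=seed + cell)
            rows.append(_cell_row(res, m, beta, mu, gamma))
            cell += 1
    return pd.DataFrame(rows)


def run_study2(
    ms=(30, 50, 70),
    beta: float = 0.4,
    mus=(4.0, 6.0, 8.0, 10.0),
    proportions=(0.0, 0.25, 0.5, 1.0),
    n_iter: int = _FULL_ITER,
    n_burnin: int = _FULL_BURNIN,
    seed: int = 1,
) -> pd.DataFrame:
    """Recovery of mu as a function of revealed network proportion (gamma = 0)."""
    rows = []
    cell = 0
    for m in ms:
        for mu in mus:
            sim = PAEpidemicModel.simulate(m, beta, mu, 0.0, seed=seed + cell)
            for prop in proportions:
                rng = np.random.default_rng(seed + 1000 + cell)
                obs = make_observation(sim.graph, sim.epidemic, prop, rng)
                model = PAEpidemicModel(sim.epidemic, observation=obs, gamma=0.0)
                res = model.fit(
                    n_iter=n_iter, n_burnin=n_burnin, seed=seed + cell
                )
                rows.append(_cell_row(res, m, beta, mu, 0.0, proportion=prop))
            cell += 1
    return pd.DataFrame(rows)


STUDY_PRESETS = {
    "study1": dict(fn=run_study1, n_iter=_FULL_ITER, n_burnin=_FULL_BURNIN),
    "study1-mini": dict(
        fn=lambda **kw: run_study1(
            m=30, mus=(4.0, 6.0), gammas=(0.0, 0.5), **kw
        ),
        n_iter=_FULL_ITER // 10,
        n_burnin=_FULL_BURNIN // 10,
    ),
    "study2": dict(fn=run_study2, n_iter=_FULL_ITER, n_burnin=_FULL_BURNIN),
    "study2-mini": dict(
        fn=lambda **kw: run_study2(
            ms=(30,), mus=(6.0,), proportions=(0.0, 0.5, 1.0), **kw
        ),
        n_iter=_FULL_ITER // 10,
        n_burnin=_FULL_BURNIN // 10,
    ),
}
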