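"""Plain-text file formats and observation construction.

All files are comma-delimited text with a header row; ``#`` lines are
comments.  Node labels are 1-based epidemic-order labels throughout, and
undirected pairs are written once with i < j.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import (
    Epidemic,
    Graph,
    GraphObservation,
    KNOWN_ABSENT,
    KNOWN_PRESENT,
    validate_epidemic,
)
from .mcmc import Trace

__all__ = [
    "read_epidemic",
    "write_epidemic",
    "epidemic_from_frame",
    "epidemic_to_frame",
    "read_graph",
    "write_graph",
    "read_edge_status",
    "write_edge_status",
    "write_trace",
    "read_trace_frame",
    "write_edge_probs",
    "make_observation",
]


def epidemic_to_frame(ep: Epidemic) -> pd.DataFrame:
    """Epidemic as a node/infector/time table (index case infector 0)."""
    rows = [(1, 0, float(ep.times[0]))]
    for j in range(2, ep.m + 1):
        rows.append((j, ep.parents[j], float(ep.times[j - 1])))
    return pd.DataFrame(rows, columns=["node", "infector", "time"])


def epidemic_from_frame(df: pd.DataFrame) -> Epidemic:
    """Build a validated epidemic from a node/infector/time table.

    Rows may use arbitrary node identifiers; nodes are relabelled 1..m in
    infection-time order and times are shifted so the index case is at 0.
    Ties in infection times and malformed trees raise with the offending row
    or node named.
    """
    req = {"node", "infector", "time"}
    if not req.issubset(df.columns):
        raise ValueError(f"epidemic table needs columns {sorted(req)}")
    df = df.copy()
    try:
        df["time"] = df["time"].astype(float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric time value: {e}") from None
    if df["node"].duplicated().any():
        dup = df.loc[df["node"].duplicated(), "node"].iloc[0]
        raise ValueError(f"duplicate row for node {dup!r}")
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    times = df["time"].to_numpy()
    if np.unique(times).size != times.size:
        t = times[pd.Series(times).duplicated().to_numpy()][0]
        raise ValueError(f"tied infection times at time {t}")
    label = {node: k + 1 for k, node in enumerate(df["node"])}
    parents: dict[int, int] = {}
    for row_i, row in df.iterrows():
        j = label[row["node"]]
        inf = row["infector"]
        is_root = (
            inf is None
            or (isinstance(inf, float) and math.isnan(inf))
            or (isinstance(inf, str) and inf.strip() == "")
            or (not isinstance(inf, str) and float(inf) == 0)
        )
        if j == 1:
            if not is_root:
                raise ValueError(
                    f"row {row_i}: earliest node {row['node']!r} must have no infector"
                )
            continue
        if is_root:
            raise ValueError(f"row {row_i}: multiple index cases (no infector)")
        if inf not in label:
            raise ValueError(f"row {row_i}: unknown infector {inf!r}")
        i = label[inf]
        if i >= j:
            raise ValueError(
                f"row {row_i}: infector {inf!r} infected no earlier than {row['node']!r}"
            )
        parents[j] = i
    ep = Epidemic(times - times[0], parents)
    bad = validate_epidemic(ep)
    if bad:
        raise ValueError("invalid epidemic: " + "; ".join(bad))
    return ep


def read_epidemic(path: str | Path) -> Epidemic:
    df = pd.read_csv(path, comment="#")
    return epidemic_from_frame(df)


def write_epidemic(ep: Epidemic, path: str | Path) -> None:
    epidemic_to_frame(ep).to_csv(path, index=False)


def read_graph(path: str | Path, m: int) -> Graph:
    df = pd.read_csv(path, comment="#")
    edges = [(int(r.i), int(r.j)) for r in df.itertuples()]
    return Graph.from_edges(m, edges)


def write_graph(g: Graph, path: str | Path) -> None:
    pd.DataFrame(g.edges(), columns=["i", "j"]).to_csv(path, index=False)


def read_edge_status(path: str | Path, m: int) -> GraphObservation:
    df = pd.read_csv(path, comment="#")
    obs = GraphObservation.unknown(m)
    seen: set[tuple[int, int]] = set()
    for row_i, r in enumerate(df.itertuples()):
        i, j = int(r.i), int(r.j)
        if not i < j:
            raise ValueError(f"row {row_i}: require i < j, got ({i},{j})")
        if (i, j) in seen:
            raise ValueError(f"row {row_i}: duplicate pair ({i},{j})")
        seen.add((i, j))
        if r.status not in ("present", "absent"):
            raise ValueError(f"row {row_i}: status must be present/absent")
        obs.set_status(i, j, KNOWN_PRESENT if r.status == "present" else KNOWN_ABSENT)
    return obs


def write_edge_status(obs: GraphObservation, path: str | Path) -> None:
    rows = []
    m = obs.m
    for i in range(1, m + 1):
        for j in range(i + 1, m + 1):
            s = obs.get_status(i, j)
            if s != 0:
                rows.append((i, j, "present" if s == KNOWN_PRESENT else "absent"))
    pd.DataFrame(rows, columns=["i", "j", "status"]).to_csv(path, index=False)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Per-kept-iteration scalar samples as CSV."""
    cols: dict[str, np.ndarray] = {"iter": np.arange(trace.n_kept)}
    cols["beta"] = trace.beta
    if trace.model == "pa":
        cols["mu"] = trace.mu
        cols["gamma"] = trace.gamma
    else:
        cols["p"] = trace.p
    cols["logpost"] = trace.logpost
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_edge_probs(trace: Trace, path: str | Path) -> None:
    rows = []
    m = trace.m
    for i in range(1, m + 1):
        for j in range(i + 1, m + 1):
            rows.append((i, j, trace.edge_freq[i - 1, j - 1]))
    pd.DataFrame(rows, columns=["i", "j", "prob"]).to_csv(path, index=False)


def make_observation(
    g_true: Graph,
    ep: Epidemic,
    proportion: float,
    rng: np.random.Generator,
) -> GraphObservation:
    """Reveal a random fraction of the non-tree potential pairs.

    Transmission pairs are always known-present; additionally,
    round(proportion x (C(m,2) - (m-1))) uniformly chosen other pairs get
    their true status (present or absent) revealed.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    m = g_true.m
    if m != ep.m:
        raise ValueError("graph and epidemic sizes differ")
    obs = GraphObservation.tree_only(ep)
    tree = set(ep.tree_pairs())
    free = [
        (i, j)
        for i in range(1, m + 1)
        for j in range(i + 1, m + 1)
        if (i, j) not in tree
    ]
    n_reveal = int(round(proportion * len(free)))
    idx = rng.choice(len(free), size=n_reveal, replace=False)
    for k in idx:
        i, j = free[k]
        obs.set_status(
            i, j, KNOWN_PRESENT if g_true.has_edge(i, j) else KNOWN_ABSENT
        )
    return obs
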