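"""Network context of affected genes against a random-gene resampling null.

The affected-gene subgraph of a protein-interaction network is summarized by
its degree-distribution power-law exponent, mean shortest-path betweenness
and edge density, and compared with replicates obtained by resampling the
same number of protein-coding genes uniformly at random.

The degree exponent is estimated, by default, with the exact discrete
power-law MLE (Hurwitz-zeta likelihood, x_min = 1, degree-0 nodes excluded).
The widely quoted closed-form approximation
``1 + n [Σ ln(d_i/(x_min − 0.5))]^{-1}`` is available as ``method="approx"``
but is strongly biased at x_min = 1 and should only be used with larger
x_min; a log–log least-squares fit on the degree histogram is available as
``method="loglog"``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = [
    "NetworkSummary",
    "NullDistribution",
    "betweenness_and_density",
    "compare_to_null",
    "fit_degree_exponent",
    "induced_subgraph",
    "random_null",
    "read_edge_list",
    "simplify",
    "summarize_network",
    "write_edge_list",
]

#: cap applied when the MLE diverges (e.g. all degrees equal to x_min)
GAMMA_MAX = 8.0

#: minimum number of degree>=1 nodes required for an exponent fit
MIN_FIT_NODES = 10


def simplify(graph: nx.Graph) -> nx.Graph:
    """Copy as a simple undirected graph: no self-loops, no multi-edges."""
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def induced_subgraph(network: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    """Subgraph on ``genes ∩ nodes`` with both-endpoint edges retained."""
    keep = set(genes) & set(network.nodes)
    return nx.Graph(network.subgraph(keep))


# ---------------------------------------------------------------------------
# degree-exponent estimation
# ---------------------------------------------------------------------------

def fit_degree_exponent(
    network: nx.Graph | Sequence[int],
    x_min: int = 1,
    method: str = "mle",
) -> float:
    """Power-law exponent of the degree distribution.

    ``network`` may be a graph or a raw degree sequence. Nodes with degree
    below ``x_min`` are excluded. Raises when fewer than ``MIN_FIT_NODES``
    usable degrees remain.
    """
    if isinstance(network, nx.Graph):
        degrees = [d for _, d in network.degree()]
    else:
        degrees = list(network)
    d = np.asarray([x for x in degrees if x >= x_min], dtype=float)
    if d.size < MIN_FIT_NODES:
        raise ValueError(
            f"need >= {MIN_FIT_NODES} nodes with degree >= {x_min}, got {d.size}"
        )
    if np.all(d == d[0]):
        warnings.warn("degenerate degree sequence; exponent capped at maximum")
        return GAMMA_MAX
    if method == "mle":
        log_d = np.log(d)
        n = d.size

        def nll(g: float) -> float:
            return n * float(np.log(zeta(g, x_min))) + g * float(log_d.sum())

        res = minimize_scalar(nll, bounds=(1.01, GAMMA_MAX), method="bounded")
        return float(res.x)
    if method == "approx":
        denom = np.log(d / (x_min - 0.5)).sum()
        if denom <= 0:
            warnings.warn("divergent approximate MLE; exponent capped at maximum")
            return GAMMA_MAX
        return min(1.0 + d.size / float(denom), GAMMA_MAX)
    if method == "loglog":
        counts = Counter(int(x) for x in d)
        xs = np.array(sorted(counts))
        ys = np.array([counts[x] for x in xs], dtype=float)
        if xs.size < 2:
            warnings.warn("degenerate histogram; exponent capped at maximum")
            return GAMMA_MAX
        slope, _ = np.polyfit(np.log(xs), np.log(ys), 1)
        return float(-slope)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    degree_histogram: dict[int, int]
    gamma: float | None
    mean_betweenness: float | None
    edge_density: float

    def metric(self, name: str) -> float | None:
        return getattr(self, name)


def betweenness_and_density(network: nx.Graph) -> tuple[float, float]:
    """Exact unweighted shortest-path betweenness averaged over nodes, and
    edge density |E| / (|V| choose 2)."""
    if network.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    bc = nx.betweenness_centrality(network, normalized=False)
    return float(np.mean(list(bc.values()))), float(nx.density(network))


def summarize_network(
    network: nx.Graph,
    x_min: int = 1,
    method: str = "mle",
    with_betweenness: bool = True,
) -> NetworkSummary:
    """Full :class:`NetworkSummary`; gamma is ``None`` when too few nodes
    have nonzero degree, betweenness optionally skipped for speed."""
    g = simplify(network)
    degrees = [d for _, d in g.degree()]
    hist = dict(sorted(Counter(degrees).items()))
    try:
        gamma = fit_degree_exponent(degrees, x_min=x_min, method=method)
    except ValueError:
        gamma = None
    if with_betweenness and g.number_of_nodes() >= 2:
        mean_bc, density = betweenness_and_density(g)
    else:
        mean_bc = None
        density = float(nx.density(g)) if g.number_of_nodes() >= 2 else 0.0
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree_histogram=hist,
        gamma=gamma,
        mean_betweenness=mean_bc,
        edge_density=density,
    )


# ---------------------------------------------------------------------------
# resampling null
# ---------------------------------------------------------------------------

_METRICS = ("gamma", "mean_betweenness", "edge_density")


@dataclass
class NullDistribution:
    replicates: list[NetworkSummary]
    seed: int
    k: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def random_null(
    network: nx.Graph,
    k: int,
    n_replicates: int,
    candidate_pool: Sequence[str],
    seed: int,
    x_min: int = 1,
    method: str = "mle",
    with_betweenness: bool = True,
) -> NullDistribution:
    """Summaries of ``n_replicates`` induced subgraphs on uniform samples of
    ``k`` genes from the candidate pool, reproducible given the seed."""
    pool = sorted(set(candidate_pool))
    if k > len(pool):
        raise ValueError(f"sample size {k} exceeds candidate pool of {len(pool)}")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        sample = rng.choice(pool, size=k, replace=False)
        sub = induced_subgraph(network, sample)
        reps.append(
            summarize_network(
                sub, x_min=x_min, method=method, with_betweenness=with_betweenness
            )
        )
    null = NullDistribution(replicates=reps, seed=seed, k=k)
    for m in _METRICS:
        vals = [r.metric(m) for r in reps if r.metric(m) is not None]
        if len(vals) >= 2:
            null.mean[m] = float(np.mean(vals))
            null.sd[m] = float(np.std(vals, ddof=1))
    return null


def compare_to_null(
    observed: NetworkSummary, null: NullDistribution
) -> dict[str, dict[str, float | None]]:
    """Per-metric z-score and two-sided add-one empirical p-value.

    ``p = (1 + #{|replicate − mean| ≥ |observed − mean|}) / (n + 1)``; the
    z-score is absent when the null standard deviation is zero.
    """
    out: dict[str, dict[str, float | None]] = {}
    for m in _METRICS:
        obs = observed.metric(m)
        if obs is None or m not in null.mean:
            continue
        vals = np.array(
            [r.metric(m) for r in null.replicates if r.metric(m) is not None]
        )
        mean, sd = null.mean[m], null.sd[m]
        z = (obs - mean) / sd if sd > 0 else None
        extreme = int(np.sum(np.abs(vals - mean) >= abs(obs - mean)))
        p = (1 + extreme) / (len(vals) + 1)
        out[m] = {"observed": float(obs), "null_mean": mean, "null_sd": sd,
                  "z_score": z, "empirical_p": float(p)}
    return out


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV of gene ids (optional ``#``-prefixed header), loaded
    as a simple undirected graph."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            a, b = fields[0], fields[1]
            if a != b:
                g.add_edge(a, b)
            else:
                g.add_node(a)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
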