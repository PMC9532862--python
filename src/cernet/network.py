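"""ceRNA network assembly: correlation filters, sponge test, triples, ranking.

The inference core: candidate (miRNA, target) pairs from seed matching
are kept only if negatively coexpressed (Spearman rank correlation
< -0.7); circRNA-mRNA pairs sharing a predicted miRNA are kept only if
positively coexpressed (Pearson correlation > 0.9); and each surviving
circRNA-mRNA pair must share significantly more miRNA regulators than
chance under a one-sided hypergeometric test (p < 0.05).  Triples passing
all filters are assembled into a typed network; hub nodes are ranked by
degree and a top-k sub-network can be extracted.

All threshold comparisons are strict, exactly as stated: < -0.7, > 0.9,
p < 0.05.  Undefined correlations (constant vectors) never pass.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .targets import InteractionCandidate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation kernels
# ---------------------------------------------------------------------------

def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    return x, y


def spearman(x, y) -> float:
    """Spearman rank correlation (midranks for ties); NaN if either is constant."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def pearson(x, y) -> float:
    """Pearson product-moment correlation; NaN if either vector is constant."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# hypergeometric kernel and sponge test
# ---------------------------------------------------------------------------

def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via log-binomial sums.

    N objects, K marked, n drawn; k = 0 returns exactly 1.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k <= 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1, dtype=float)
    lp = _log_choose(K, i) + _log_choose(N - K, n - i) - _log_choose(N, n)
    p = float(np.exp(logsumexp(lp)))
    return min(1.0, max(p, np.finfo(float).tiny))


@dataclasses.dataclass(frozen=True)
class SpongeResult:
    """Shared-miRNA sponge test for one (circRNA, mRNA) pair."""

    shared: int        # k: miRNAs shared by the two target sets
    circ_set: int      # K
    mrna_set: int      # n
    universe: int      # N
    p: float
    passed: bool


def sponge_test(circ_mirnas: set, mrna_mirnas: set, universe: set,
                alpha: float = 0.05) -> SpongeResult:
    """One-sided hypergeometric test of shared miRNA regulators."""
    if not universe:
        raise ValueError("empty miRNA universe")
    if not circ_mirnas <= universe or not mrna_mirnas <= universe:
        raise ValueError("target sets must be subsets of the universe")
    k = len(circ_mirnas & mrna_mirnas)
    p = hypergeom_sf(k, len(circ_mirnas), len(mrna_mirnas), len(universe))
    return SpongeResult(k, len(circ_mirnas), len(mrna_mirnas), len(universe),
                        p, passed=(p < alpha and k >= 1))


# ---------------------------------------------------------------------------
# correlation filters
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CorrelationEdge:
    node_a: str   # miRNA for miR-target kinds; circRNA for circ-mRNA
    node_b: str
    kind: str     # miRNA-mRNA | circRNA-miRNA | circRNA-mRNA
    coefficient: float
    method: str   # spearman | pearson
    n_samples: int
    passed: bool


def filter_negative_pairs(candidates: Sequence[InteractionCandidate],
                          mirna_expr: pd.DataFrame,
                          target_expr: pd.DataFrame,
                          threshold: float = -0.7) -> list[CorrelationEdge]:
    """Keep (miRNA, target) candidates with Spearman rho strictly below threshold.

    Expression frames are features x samples over the comparison's sample
    set (same columns).  Undefined correlations are dropped with a warning.
    """
    kind = ("circRNA-miRNA" if candidates and
            candidates[0].target_layer == "circRNA" else "miRNA-mRNA")
    edges: list[CorrelationEdge] = []
    n = mirna_expr.shape[1]
    for c in candidates:
        if c.mirna not in mirna_expr.index:
            raise KeyError(f"unknown miRNA {c.mirna!r}")
        if c.target not in target_expr.index:
            raise KeyError(f"unknown target {c.target!r}")
        rho = spearman(mirna_expr.loc[c.mirna].to_numpy(),
                       target_expr.loc[c.target].to_numpy())
        if math.isnan(rho):
            logger.warning("undefined correlation for (%s, %s); dropped",
                           c.mirna, c.target)
            continue
        if rho < threshold:
            edges.append(CorrelationEdge(c.mirna, c.target, kind, rho,
                                         "spearman", n, True))
    return edges


def derive_circ_mrna_candidates(circ_mir_edges: Sequence[CorrelationEdge],
                                mir_mrna_edges: Sequence[CorrelationEdge]
                                ) -> list[tuple[str, str]]:
    """(circRNA, mRNA) pairs sharing >= 1 miRNA across the passed edges."""
    circs_by_mir: dict[str, set[str]] = {}
    for e in circ_mir_edges:
        circs_by_mir.setdefault(e.node_a, set()).add(e.node_b)
    pairs: set[tuple[str, str]] = set()
    for e in mir_mrna_edges:
        for circ in circs_by_mir.get(e.node_a, ()):
            pairs.add((circ, e.node_b))
    return sorted(pairs)


def filter_positive_pairs(pairs: Sequence[tuple[str, str]],
                          circ_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                          threshold: float = 0.9) -> list[CorrelationEdge]:
    """Keep (circRNA, mRNA) pairs with Pearson r strictly above threshold."""
    edges: list[CorrelationEdge] = []
    n = circ_expr.shape[1]
    for circ, gene in pairs:
        if circ not in circ_expr.index:
            raise KeyError(f"unknown circRNA {circ!r}")
        if gene not in mrna_expr.index:
            raise KeyError(f"unknown mRNA {gene!r}")
        r = pearson(circ_expr.loc[circ].to_numpy(),
                    mrna_expr.loc[gene].to_numpy())
        if math.isnan(r):
            logger.warning("undefined correlation for (%s, %s); dropped",
                           circ, gene)
            continue
        if r > threshold:
            edges.append(CorrelationEdge(circ, gene, "circRNA-mRNA", r,
                                         "pearson", n, True))
    return edges


# ---------------------------------------------------------------------------
# triple assembly and network
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CeRNATriple:
    circ: str
    mirna: str
    mrna: str
    shared_mirna_count: int
    circ_mirna_set_size: int
    mrna_mirna_set_size: int
    universe_size: int
    sponge_p: float
    scc_circ_mirna: float
    scc_mirna_mrna: float
    pcc_circ_mrna: float


def assemble_triples(mir_mrna_edges: Sequence[CorrelationEdge],
                     circ_mir_edges: Sequence[CorrelationEdge],
                     circ_mrna_edges: Sequence[CorrelationEdge],
                     sponge_results: Mapping[tuple[str, str], SpongeResult]
                     ) -> list[CeRNATriple]:
    """Emit (circ, miR, mRNA) triples passing every filter, in sorted order."""
    mm = {}
    for e in mir_mrna_edges:
        mm[(e.node_a, e.node_b)] = e
    cm = {}
    for e in circ_mir_edges:
        cm[(e.node_a, e.node_b)] = e  # keyed (miRNA, circRNA)
    cg = {(e.node_a, e.node_b): e for e in circ_mrna_edges}

    triples: dict[tuple[str, str, str], CeRNATriple] = {}
    for (mir, circ), e_cm in cm.items():
        for (mir2, gene), e_mm in mm.items():
            if mir2 != mir:
                continue
            e_cg = cg.get((circ, gene))
            if e_cg is None:
                continue
            sponge = sponge_results.get((circ, gene))
            if sponge is None or not sponge.passed:
                continue
            key = (circ, mir, gene)
            triples[key] = CeRNATriple(
                circ, mir, gene, sponge.shared, sponge.circ_set,
                sponge.mrna_set, sponge.universe, sponge.p,
                e_cm.coefficient, e_mm.coefficient, e_cg.coefficient)
    return [triples[k] for k in sorted(triples)]


NODE_TYPES = ("circRNA", "miRNA", "mRNA")


@dataclasses.dataclass
class CeRNANetwork:
    """Typed undirected network over circRNA / miRNA / mRNA nodes."""

    graph: nx.Graph

    @property
    def node_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in NODE_TYPES}
        for _, d in self.graph.nodes(data=True):
            counts[d["node_type"]] += 1
        return counts

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary_line(self) -> str:
        c = self.node_counts
        return (f"{c['circRNA']} circRNA nodes, {c['miRNA']} miRNA nodes, "
                f"{c['mRNA']} mRNA nodes, and {self.n_edges} edges")

    def degree_table(self) -> pd.DataFrame:
        rows = [{"node": n, "node_type": d["node_type"],
                 "degree": self.graph.degree[n]}
                for n, d in self.graph.nodes(data=True)]
        return (pd.DataFrame(rows, columns=["node", "node_type", "degree"])
                .sort_values(["degree", "node"], ascending=[False, True])
                .reset_index(drop=True))


def build_network(triples: Iterable[CeRNATriple],
                  include_circ_mrna: bool = False) -> CeRNANetwork:
    """Assemble the circ-miR and miR-mRNA edges of the triples into a graph."""
    g = nx.Graph()
    for t in triples:
        if t.circ == t.mirna or t.mirna == t.mrna or t.circ == t.mrna:
            raise ValueError(f"self-loop in triple {t}")
        g.add_node(t.circ, node_type="circRNA")
        g.add_node(t.mirna, node_type="miRNA")
        g.add_node(t.mrna, node_type="mRNA")
        _add_edge(g, t.circ, t.mirna, "circRNA-miRNA", t.scc_circ_mirna,
                  t.sponge_p)
        _add_edge(g, t.mirna, t.mrna, "miRNA-mRNA", t.scc_mirna_mrna,
                  t.sponge_p)
        if include_circ_mrna:
            _add_edge(g, t.circ, t.mrna, "circRNA-mRNA", t.pcc_circ_mrna,
                      t.sponge_p)
    return CeRNANetwork(g)


def _add_edge(g: nx.Graph, u: str, v: str, kind: str, coefficient: float,
              sponge_p: float) -> None:
    if g.has_edge(u, v):
        # keep the strongest sponge evidence for shared edges
        if sponge_p < g.edges[u, v]["sponge_p"]:
            g.edges[u, v]["sponge_p"] = sponge_p
        return
    g.add_edge(u, v, kind=kind, coefficient=float(coefficient),
               sponge_p=float(sponge_p))


def hub_rank(network: CeRNANetwork) -> list[str]:
    """Nodes by degree descending, ties broken lexicographically by id."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    return sorted(network.graph.nodes,
                  key=lambda n: (-network.graph.degree[n], n))


def top_edges(network: CeRNANetwork, k: int = 50) -> CeRNANetwork:
    """Induced sub-network of the k best edges.

    Ranking key: sponge p ascending, then |coefficient| descending, then
    endpoint ids.  k beyond the edge count returns the full network.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = sorted(network.graph.edges(data=True),
                   key=lambda e: (e[2]["sponge_p"], -abs(e[2]["coefficient"]),
                                  tuple(sorted((e[0], e[1])))))
    keep = edges[:k]
    g = nx.Graph()
    for u, v, d in keep:
        for n in (u, v):
            g.add_node(n, **network.graph.nodes[n])
        g.add_edge(u, v, **d)
    return CeRNANetwork(g)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_graphml(network: CeRNANetwork, path) -> None:
    nx.write_graphml(network.graph, str(path))


def write_sif(network: CeRNANetwork, path) -> None:
    """Cytoscape SIF: `source<TAB>kind<TAB>target`, one edge per line."""
    lines = [f"{u}\t{d['kind']}\t{v}"
             for u, v, d in sorted(network.graph.edges(data=True))]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def triples_to_frame(triples: Sequence[CeRNATriple]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in triples],
                        columns=[f.name for f in
                                 dataclasses.fields(CeRNATriple)])
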