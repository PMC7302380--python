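"""Core-OTU co-occurrence networks and the observed/random incidence ratio.

The pipeline stage mirrors a standard amplicon co-occurrence analysis:
abundant, ubiquitous ("core") OTUs are selected from a fixed-depth OTU
table; all pairwise Spearman rank correlations of per-sample relative
abundances are tested; positive, strong (rho > 0.6), FDR-significant
(BH q < 0.01) correlations become the edges of an undirected simple
graph whose nodes carry lineage labels.

The association between a methanogen group and a candidate partner
lineage is then summarised by the O/R incidence ratio: the observed
number of cross-lineage edges divided by the number expected under a
null in which the same number of edges is placed at random. Three nulls
are provided — a closed-form Erdos–Renyi expectation (``analytic_er``),
a Monte-Carlo uniform-random-graph null (``permutation_er``, which also
yields a permutation p-value), and a degree-preserving rewiring null
(``degree_preserving``). O/R > 1 indicates a non-random association.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

NULL_MODELS = ("analytic_er", "permutation_er", "degree_preserving")

__all__ = [
    "OtuTable",
    "CoreFilterParams",
    "NetworkParams",
    "CooccurrenceNetwork",
    "IncidenceRatioResult",
    "NetworkSummary",
    "filter_core_otus",
    "build_network",
    "network_summary",
    "incidence_ratio",
    "or_screen",
]


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Samples x OTUs count matrix with lineage labels.

    ``counts`` has samples as rows and OTUs as columns; every OTU must
    appear in ``lineage_map``; ``methanogen_lineages`` flags which
    lineage labels are methanogens.
    """

    counts: pd.DataFrame
    lineage_map: Mapping[str, str]
    methanogen_lineages: frozenset = frozenset()

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("counts: duplicate sample ids")
        if c.columns.has_duplicates:
            raise ValidationError("counts: duplicate OTU ids")
        arr = c.to_numpy()
        if arr.size and ((arr < 0).any() or not np.issubdtype(arr.dtype, np.integer)):
            raise ValidationError("counts: must be nonnegative integers")
        missing = [o for o in c.columns if o not in self.lineage_map]
        if missing:
            raise ValidationError(f"lineage_map: missing OTUs {missing[:5]}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValidationError("counts: sample with zero total reads")
        return self.counts.div(totals, axis=0)


@dataclass(frozen=True)
class CoreFilterParams:
    """Core-OTU selection: pooled relative abundance strictly above
    ``min_pooled_rel_abundance`` (default 0.001%) and nonzero counts in
    at least ``min_occurrence`` samples (default 2, i.e. more than one).
    """

    min_pooled_rel_abundance: float = 1e-5
    min_occurrence: int = 2

    def __post_init__(self):
        if not (0.0 <= self.min_pooled_rel_abundance < 1.0):
            raise ValidationError("min_pooled_rel_abundance: must be in [0, 1)")
        if self.min_occurrence < 1:
            raise ValidationError("min_occurrence: must be >= 1")


@dataclass(frozen=True)
class NetworkParams:
    """Edge criteria for the co-occurrence graph.

    ``q_max=None`` disables the FDR gate (edges filtered on rho alone);
    this is intended for null-calibration experiments, not for
    inference, and is documented as such.
    """

    rho_min: float = 0.6
    q_max: float | None = 0.01
    positive_only: bool = True
    fdr_method: str = "fdr_bh"
    p_method: str = "t_approx"

    def __post_init__(self):
        if not (0.0 < self.rho_min <= 1.0):
            raise ValidationError("rho_min: must be in (0, 1]")
        if self.q_max is not None and not (0.0 < self.q_max < 1.0):
            raise ValidationError("q_max: must be in (0, 1) or None")
        if self.p_method not in ("t_approx", "exact"):
            raise ValidationError("p_method: must be 't_approx' or 'exact'")


@dataclass
class CooccurrenceNetwork:
    """Undirected simple graph of OTUs; edges carry (rho, p, q)."""

    graph: nx.Graph
    params: NetworkParams | None = None

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def lineage_of(self, node) -> str:
        return self.graph.nodes[node]["lineage"]

    def nodes_in_lineages(self, lineages: Iterable[str]) -> set:
        want = set(lineages)
        return {n for n, d in self.graph.nodes(data=True) if d["lineage"] in want}

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d["rho"], d["p"], d["q"])
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "q"])


@dataclass(frozen=True)
class IncidenceRatioResult:
    """Observed vs expected cross-lineage edge count and their ratio."""

    lineage_a: str
    lineage_b: str
    observed: int
    expected: float
    or_ratio: float
    null_model: str
    perm_p: float | None = None
    n_permutations: int | None = None
    retained: bool | None = None


@dataclass(frozen=True)
class NetworkSummary:
    node_count: int
    edge_count: int
    nodes_by_lineage: dict
    edges_by_lineage_pair: dict


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def filter_core_otus(table: OtuTable, params: CoreFilterParams | None = None) -> OtuTable:
    """Keep OTUs whose pooled relative abundance strictly exceeds the
    threshold AND that are nonzero in at least ``min_occurrence``
    samples. Samples and OTU order are preserved; idempotent.
    """
    params = params or CoreFilterParams()
    pooled = table.counts.sum(axis=0)
    grand = pooled.sum()
    if grand == 0:
        raise ValidationError("empty table")
    occurrence = (table.counts > 0).sum(axis=0)
    keep = (pooled / grand > params.min_pooled_rel_abundance) & (
        occurrence >= params.min_occurrence
    )
    kept = [o for o in table.otu_ids if keep[o]]
    return OtuTable(
        counts=table.counts[kept],
        lineage_map={o: table.lineage_map[o] for o in kept},
        methanogen_lineages=table.methanogen_lineages,
    )


def _spearman_matrix(rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p (t approximation) for all column pairs."""
    n, p = rel.shape
    if p == 1:
        return np.ones((1, 1)), np.zeros((1, 1))
    res = stats.spearmanr(rel, axis=0)
    rho = np.atleast_2d(res.statistic)
    pval = np.atleast_2d(res.pvalue)
    if rho.shape != (p, p):  # scipy collapses the 2-column case to scalars
        r = float(res.statistic)
        q = float(res.pvalue)
        rho = np.array([[1.0, r], [r, 1.0]])
        pval = np.array([[0.0, q], [q, 0.0]])
    return rho, pval


@functools.lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations, cached per n (int8: n is small)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _exact_spearman_pvals(rel: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Exact two-sided Spearman p-values by full permutation
    enumeration; intended for small sample counts (n <= 10).

    The null distribution of rho for pair (i, j) is the correlation of
    the fixed ranks of column i with every permutation of the ranks of
    column j (ties kept, average ranks).
    """
    n, p = rel.shape
    if n > 10:
        raise ValidationError("p_method 'exact': needs <= 10 samples")
    ranks = stats.rankdata(rel, axis=0)
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    perms = _all_permutations(n)
    n_perm = len(perms)
    pvals = np.full((p, p), np.nan)
    for j in range(p):
        # null rho against column j, one dot product per permutation,
        # chunked to bound the gathered-rank matrix
        y = centered[:, j]
        for i in range(j):
            null_count = 0
            x = centered[:, i]
            denom = norms[i] * norms[j]
            thresh = abs(rho[i, j]) * denom - 1e-12
            for start in range(0, n_perm, 500_000):
                chunk = perms[start:start + 500_000]
                dots = y[chunk] @ x
                null_count += int((np.abs(dots) >= thresh).sum())
            pvals[i, j] = pvals[j, i] = null_count / n_perm
    np.fill_diagonal(pvals, 0.0)
    return pvals


def build_network(table: OtuTable, params: NetworkParams | None = None) -> CooccurrenceNetwork:
    """All-pairs Spearman network on per-sample relative abundances.

    Constant (all-tied) OTU vectors have undefined rank correlation;
    their pairs are excluded from testing and from the FDR family, with
    a logged warning. Isolated nodes stay in the node set. FDR
    adjustment (Benjamini–Hochberg by default) is applied jointly
    across all tested pairs. ``p_method='exact'`` replaces the
    large-sample t p-values with full-enumeration permutation p-values
    (sample counts up to 10).
    """
    params = params or NetworkParams()
    n, p = table.counts.shape
    if n < 4:
        raise ValidationError("at least 4 samples required")
    if p < 2:
        raise ValidationError("at least 2 OTUs required")

    rel = table.relative_abundance().to_numpy(dtype=float)
    otus = table.otu_ids
    variable = [j for j in range(p) if np.unique(rel[:, j]).size > 1]
    constant = [otus[j] for j in range(p) if j not in set(variable)]
    if constant:
        logger.warning(
            "excluding %d constant OTU vector(s) from correlation testing: %s",
            len(constant), constant[:10],
        )

    g = nx.Graph()
    for o in otus:
        g.add_node(o, lineage=table.lineage_map[o])

    if len(variable) >= 2:
        sub = rel[:, variable]
        rho, pval = _spearman_matrix(sub)
        if params.p_method == "exact":
            pval = _exact_spearman_pvals(sub, rho)
        iu, ju = np.triu_indices(len(variable), k=1)
        rho_flat = rho[iu, ju]
        p_flat = np.clip(pval[iu, ju], 0.0, 1.0)
        if params.q_max is not None:
            q_flat = multipletests(p_flat, method=params.fdr_method)[1]
        else:
            q_flat = np.full_like(p_flat, np.nan)
        for k in range(len(rho_flat)):
            r = rho_flat[k]
            if not np.isfinite(r):
                continue
            if r <= params.rho_min:
                continue
            if params.positive_only and r <= 0:
                continue
            if params.q_max is not None and not (q_flat[k] < params.q_max):
                continue
            a = otus[variable[iu[k]]]
            b = otus[variable[ju[k]]]
            g.add_edge(a, b, rho=float(r), p=float(p_flat[k]), q=float(q_flat[k]))
    return CooccurrenceNetwork(graph=g, params=params)


def network_summary(net: CooccurrenceNetwork) -> NetworkSummary:
    """Exact node/edge counts overall, per lineage, and per lineage pair."""
    nodes_by = {}
    for _, d in net.graph.nodes(data=True):
        nodes_by[d["lineage"]] = nodes_by.get(d["lineage"], 0) + 1
    edges_by = {}
    for u, v in net.graph.edges:
        key = tuple(sorted((net.lineage_of(u), net.lineage_of(v))))
        edges_by[key] = edges_by.get(key, 0) + 1
    return NetworkSummary(
        node_count=net.node_count,
        edge_count=net.edge_count,
        nodes_by_lineage=nodes_by,
        edges_by_lineage_pair=edges_by,
    )


def _count_cross_edges(graph: nx.Graph, set_a: set, set_b: set) -> int:
    return sum(
        1
        for u, v in graph.edges
        if (u in set_a and v in set_b) or (u in set_b and v in set_a)
    )


def _null_cross_counts_er(
    n_nodes: int, n_edges: int, n_cross_pairs: int, n_permutations: int, rng
) -> np.ndarray:
    """Cross-edge counts over uniformly random simple graphs with the
    same node and edge counts.

    Each null graph is a uniform ``m``-subset of the ``C(N,2)`` node
    pairs; only membership of a sampled pair in the cross set matters,
    so pairs are indexed with the ``K`` cross pairs first and the count
    is how many sampled indices fall below ``K``. Chunked to bound
    memory.
    """
    M = n_nodes * (n_nodes - 1) // 2
    out = np.empty(n_permutations, dtype=np.int64)
    done = 0
    chunk = max(1, min(n_permutations, int(4e6 / max(M, 1))))
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        u = rng.random((b, M))
        idx = np.argpartition(u, n_edges - 1, axis=1)[:, :n_edges]
        out[done:done + b] = (idx < n_cross_pairs).sum(axis=1)
        done += b
    return out


def _null_cross_counts_rewire(
    graph: nx.Graph, set_a: set, set_b: set, n_permutations: int, rng
) -> np.ndarray:
    m = graph.number_of_edges()
    out = np.empty(n_permutations, dtype=np.int64)
    for k in range(n_permutations):
        h = graph.copy()
        seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(h, nswap=4 * m, max_tries=100 * m, seed=seed)
        except nx.NetworkXError:
            pass  # too few swappable edges; graph stays as-is
        out[k] = _count_cross_edges(h, set_a, set_b)
    return out


def _incidence_ratio_sets(
    net: CooccurrenceNetwork,
    label_a: str,
    label_b: str,
    set_a: set,
    set_b: set,
    null_model: str,
    n_permutations: int,
    seed: int | None,
) -> IncidenceRatioResult:
    if null_model not in NULL_MODELS:
        raise ValidationError(f"null_model: must be one of {NULL_MODELS}")
    if not set_a or not set_b:
        raise ValidationError(
            f"lineage group empty: {'both' if not set_a and not set_b else (label_a if not set_a else label_b)}"
        )
    if set_a & set_b:
        raise ValidationError("lineage groups must be disjoint")

    g = net.graph
    N = g.number_of_nodes()
    m = g.number_of_edges()
    observed = _count_cross_edges(g, set_a, set_b)
    n_cross_pairs = len(set_a) * len(set_b)

    if m == 0:
        logger.warning("network has no edges; O/R undefined for (%s, %s)",
                       label_a, label_b)
        return IncidenceRatioResult(label_a, label_b, observed, 0.0,
                                    float("nan"), null_model)

    if null_model == "analytic_er":
        expected = m * n_cross_pairs / math.comb(N, 2)
        return IncidenceRatioResult(label_a, label_b, observed, expected,
                                    observed / expected, null_model)

    rng = np.random.default_rng(seed)
    if null_model == "permutation_er":
        null = _null_cross_counts_er(N, m, n_cross_pairs, n_permutations, rng)
    else:
        null = _null_cross_counts_rewire(g, set_a, set_b, n_permutations, rng)
    expected = float(null.mean())
    perm_p = (1 + int((null >= observed).sum())) / (1 + n_permutations)
    ratio = observed / expected if expected > 0 else float("nan")
    return IncidenceRatioResult(label_a, label_b, observed, expected, ratio,
                                null_model, perm_p, n_permutations)


def incidence_ratio(
    net: CooccurrenceNetwork,
    lineage_a: str,
    lineage_b: str,
    null_model: str = "analytic_er",
    n_permutations: int = 999,
    seed: int | None = None,
) -> IncidenceRatioResult:
    """Observed/expected cross-lineage edge count between two lineages.

    ``analytic_er`` uses the closed-form Erdos–Renyi expectation
    ``m * n_a * n_b / C(N, 2)``; the permutation nulls additionally
    return ``perm_p = (1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    if lineage_a == lineage_b:
        raise ValidationError("lineage_a and lineage_b must differ")
    set_a = net.nodes_in_lineages([lineage_a])
    set_b = net.nodes_in_lineages([lineage_b])
    return _incidence_ratio_sets(net, lineage_a, lineage_b, set_a, set_b,
                                 null_model, n_permutations, seed)


def or_screen(
    net: CooccurrenceNetwork,
    methanogen_lineages: Iterable[str],
    partner_lineages: Sequence[str],
    null_model: str = "analytic_er",
    n_permutations: int = 999,
    seed: int | None = None,
) -> list[IncidenceRatioResult]:
    """O/R of the pooled methanogen group against each partner lineage.

    Results are sorted by O/R descending (undefined last); ``retained``
    is True iff O/R > 1, the visualisation-retention rule.
    """
    meth = set(methanogen_lineages)
    set_a = net.nodes_in_lineages(meth)
    children = np.random.SeedSequence(seed).spawn(len(partner_lineages))
    results = []
    for partner, child in zip(partner_lineages, children):
        if partner in meth:
            raise ValidationError(f"partner lineage {partner!r} is a methanogen lineage")
        set_b = net.nodes_in_lineages([partner])
        res = _incidence_ratio_sets(
            net, "methanogens", partner, set_a, set_b, null_model,
            n_permutations, int(child.generate_state(1)[0] % 2**31),
        )
        results.append(replace(res, retained=bool(res.or_ratio > 1)))
    results.sort(
        key=lambda r: (math.isnan(r.or_ratio), -r.or_ratio if not math.isnan(r.or_ratio) else 0.0)
    )
    return results
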