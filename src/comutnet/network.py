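"""Pairwise co-occurrence testing and odds-ratio-weighted gene networks.

For every pair of genes altered in at least 1% of assayable tumors, a
two-sided Fisher's exact test is run on the 2x2 table of alteration
presence (counted over samples assayable for both genes).  The reported
odds ratio is the conditional maximum-likelihood estimate — the
noncentral-hypergeometric parameter psi at which the expected co-altered
count given the table margins equals the observed count, the estimator
classical exact-test software reports.  P-values are
Benjamini–Hochberg adjusted; pairs with q < 0.05 form an undirected
network whose edge weights are odds ratios (Haldane–Anscombe corrected
when a table cell is empty) and whose node strengths sum the absolute
odds ratios (OR if OR > 1, else 1/OR).

Gene modules are found by minimizing the two-level map equation — the
expected per-step description length of a random walk on the
edge-weight-proportional flow — with a deterministic greedy search
(single-node moves, then module merges, repeated to convergence).
Modules are labeled by their most frequent realized combination of
altered member genes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_model import GeneAlterationMatrix

__all__ = [
    "CoocPair",
    "GeneNetwork",
    "GeneModule",
    "eligible_genes",
    "conditional_mle_or",
    "fisher_exact_2x2",
    "bh_adjust",
    "cooc_proportion",
    "haldane_anscombe_or",
    "absolute_or",
    "test_all_pairs",
    "build_network",
    "map_equation_score",
    "detect_modules",
    "label_modules",
    "write_pairs_tsv",
    "write_network",
    "write_modules_tsv",
]

Q_SIGNIFICANT = 0.05
MIN_PAIR_PREVALENCE = 1.0  # percent


@dataclass
class CoocPair:
    """One gene pair's 2x2 counts and exact-test results.

    Counts are over samples assayable for both genes: n11 altered in
    both, n10 only in ``gene_a``, n01 only in ``gene_b``, n00 in
    neither.
    """

    gene_a: str
    gene_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    or_hat: float = math.nan       # conditional MLE; may be 0 or inf
    p_two_sided: float = math.nan
    q_bh: float = math.nan
    cooc_proportion: float = math.nan

    @property
    def complete_exclusivity(self) -> bool:
        return self.n11 == 0

    @property
    def n_eligible(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class GeneModule:
    module_id: int
    genes: list[str]
    label: str
    combination_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class GeneNetwork:
    """Odds-ratio-weighted co-occurrence/exclusivity network.

    ``graph`` is an undirected :class:`networkx.Graph`; each edge
    carries ``or_raw`` (zero-cell-corrected sample OR, the map-equation
    flow weight), ``weight`` (absolute OR used for node strength) and
    ``sign`` ("co-occurring" if OR > 1 else "exclusive"); each node
    carries ``degree`` and ``strength``.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self, gene: str) -> int:
        return int(self.graph.degree(gene))

    def strength(self, gene: str) -> float:
        return float(self.graph.nodes[gene]["strength"])


# ---------------------------------------------------------------------------
# exact 2x2 machinery
# ---------------------------------------------------------------------------

def _support(n11: int, n10: int, n01: int, n00: int) -> tuple[int, int, int, int, int]:
    r1, c1 = n11 + n10, n11 + n01
    n = n11 + n10 + n01 + n00
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return r1, c1, n, lo, hi


def conditional_mle_or(n11: int, n10: int, n01: int, n00: int) -> float:
    """Conditional-MLE odds ratio of a 2x2 table.

    Solves E_psi[X | margins] = n11 under Fisher's noncentral
    hypergeometric distribution by bracketed root-finding on log(psi).
    Returns 0.0 / inf when the observed count sits at the lower / upper
    end of the hypergeometric support, and NaN for degenerate margins.
    """
    r1, c1, n, lo, hi = _support(n11, n10, n01, n00)
    if lo == hi:  # degenerate margin: only one table possible
        return math.nan
    if n11 == lo:
        return 0.0
    if n11 == hi:
        return math.inf
    ks = np.arange(lo, hi + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - ks + 1)
        - gammaln(n - r1 - c1 + ks + 1)
    )

    def mean_minus_obs(logpsi: float) -> float:
        logterms = logw + ks * logpsi
        logterms -= logterms.max()
        w = np.exp(logterms)
        return float((ks * w).sum() / w.sum()) - n11

    lo_b, hi_b = -1.0, 1.0
    while mean_minus_obs(lo_b) > 0:
        lo_b *= 2.0
    while mean_minus_obs(hi_b) < 0:
        hi_b *= 2.0
    root = brentq(mean_minus_obs, lo_b, hi_b, xtol=1e-12, rtol=1e-12)
    return float(math.exp(root))


def fisher_exact_2x2(
    counts: Sequence[int] | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of a 2x2 table.

    ``counts`` is (n11, n10, n01, n00) or a 2x2 array.  Returns the
    conditional-MLE odds ratio and the two-sided p-value (sum of
    hypergeometric probabilities of tables no more probable than the
    observed one, with a 1e-7 relative tolerance guarding float ties).
    Degenerate margins give p = 1 and a NaN odds ratio.
    """
    arr = np.asarray(counts, dtype=int).reshape(4)
    n11, n10, n01, n00 = (int(x) for x in arr)
    if min(n11, n10, n01, n00) < 0:
        raise ValueError("counts must be non-negative")
    r1, c1, n, lo, hi = _support(n11, n10, n01, n00)
    if lo == hi:
        return math.nan, 1.0
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return conditional_mle_or(n11, n10, n01, n00), float(p)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cooc_proportion(n11: int, n10: int, n01: int, n00: int = 0) -> float:
    """Percent of tumors altered in both genes among those altered in either."""
    union = n11 + n10 + n01
    if union == 0:
        return 0.0
    return 100.0 * n11 / union


def haldane_anscombe_or(n11: int, n10: int, n01: int, n00: int) -> float:
    """Sample odds ratio with 0.5 added to every cell (always positive, finite)."""
    return ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))


def absolute_or(odds_ratio: float) -> float:
    """Symmetric association strength: OR if OR > 1, else its reciprocal."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    return odds_ratio if odds_ratio > 1.0 else 1.0 / odds_ratio


# ---------------------------------------------------------------------------
# cohort-level pair testing
# ---------------------------------------------------------------------------

def eligible_genes(
    matrix: GeneAlterationMatrix, threshold: float = MIN_PAIR_PREVALENCE
) -> list[str]:
    """Genes altered in at least ``threshold`` percent of assayable tumors."""
    return [g for g in matrix.genes if matrix.prevalence(g) >= threshold]


def test_all_pairs(
    matrix: GeneAlterationMatrix,
    min_prevalence: float = MIN_PAIR_PREVALENCE,
    genes: Sequence[str] | None = None,
) -> list[CoocPair]:
    """Fisher-test every eligible gene pair and BH-adjust across pairs.

    For each pair the 2x2 table is counted over samples assayable for
    both genes.
    """
    if genes is None:
        genes = eligible_genes(matrix, min_prevalence)
    pairs: list[CoocPair] = []
    for a, b in itertools.combinations(sorted(genes), 2):
        ok = matrix.gene_assayable(a) & matrix.gene_assayable(b)
        xa = matrix.gene_column(a)[ok]
        xb = matrix.gene_column(b)[ok]
        n11 = int(np.sum(xa & xb))
        n10 = int(np.sum(xa & ~xb))
        n01 = int(np.sum(~xa & xb))
        n00 = int(np.sum(~xa & ~xb))
        or_hat, p = fisher_exact_2x2((n11, n10, n01, n00))
        pairs.append(
            CoocPair(
                a, b, n11, n10, n01, n00,
                or_hat=or_hat,
                p_two_sided=p,
                cooc_proportion=cooc_proportion(n11, n10, n01, n00),
            )
        )
    if pairs:
        q = bh_adjust([p.p_two_sided for p in pairs])
        for pair, qi in zip(pairs, q):
            pair.q_bh = float(qi)
    return pairs


def build_network(
    pairs: Iterable[CoocPair],
    q_threshold: float = Q_SIGNIFICANT,
    tiers: Mapping[str, str] | None = None,
) -> GeneNetwork:
    """Build the OR-weighted network from significant pairs.

    Nodes are genes in at least one pair with q below ``q_threshold``.
    The edge flow weight is the conditional-MLE OR, replaced by the
    Haldane–Anscombe-corrected sample OR when it is 0, infinite, or
    undefined (weights must be positive and finite); node strength is
    the sum of incident absolute ORs.
    """
    graph = nx.Graph()
    for pair in pairs:
        if not (pair.q_bh < q_threshold):
            continue
        or_raw = pair.or_hat
        if not math.isfinite(or_raw) or or_raw <= 0.0:
            or_raw = haldane_anscombe_or(pair.n11, pair.n10, pair.n01, pair.n00)
        graph.add_edge(
            pair.gene_a,
            pair.gene_b,
            or_raw=float(or_raw),
            weight=absolute_or(or_raw),
            sign="co-occurring" if or_raw > 1.0 else "exclusive",
            q=float(pair.q_bh),
        )
    for node in graph.nodes:
        graph.nodes[node]["degree"] = int(graph.degree(node))
        graph.nodes[node]["strength"] = float(
            sum(d["weight"] for _, _, d in graph.edges(node, data=True))
        )
        if tiers is not None:
            graph.nodes[node]["tier"] = tiers.get(node, "pathogenic_unknown")
    return GeneNetwork(graph)


# ---------------------------------------------------------------------------
# map equation
# ---------------------------------------------------------------------------

def _plogp(x: float) -> float:
    return 0.0 if x <= 0.0 else x * math.log2(x)


def map_equation_score(
    graph: nx.Graph | GeneNetwork,
    partition: Mapping[Hashable, int],
    weight: str = "or_raw",
) -> float:
    """Two-level map equation L(M) in bits for an undirected weighted graph.

    Flow is edge-weight proportional: a node's visit rate is its strength
    over twice the total edge weight; a module's exit rate is its cut
    weight over twice the total edge weight.
    L(M) = q * H(Q) + sum_m p_m * H(P_m), written via the standard
    plogp expansion.  Modules named in ``partition`` must be non-empty
    over the graph's nodes; nodes with zero strength carry zero flow.
    """
    if isinstance(graph, GeneNetwork):
        graph = graph.graph
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("empty graph")
    if set(partition.keys()) != set(nodes):
        raise ValueError("partition must cover every graph node exactly once")
    modules = set(partition[u] for u in nodes)

    def w_of(d: dict) -> float:
        return float(d.get(weight, d.get("weight", 1.0)))

    strength = {u: 0.0 for u in nodes}
    total = 0.0
    cut = {m: 0.0 for m in modules}
    for u, v, d in graph.edges(data=True):
        w = w_of(d)
        if w < 0:
            raise ValueError("negative edge weight")
        if u == v:
            strength[u] += 2.0 * w
            total += 2.0 * w
            continue
        strength[u] += w
        strength[v] += w
        total += 2.0 * w
        if partition[u] != partition[v]:
            cut[partition[u]] += w
            cut[partition[v]] += w
    if total == 0.0:
        return 0.0

    p_node = {u: strength[u] / total for u in nodes}
    q_mod = {m: cut[m] / total for m in modules}
    p_mod_in = {m: 0.0 for m in modules}
    for u in nodes:
        p_mod_in[partition[u]] += p_node[u]

    q_total = sum(q_mod.values())
    L = _plogp(q_total)
    L -= 2.0 * sum(_plogp(q_mod[m]) for m in modules)
    L -= sum(_plogp(p_node[u]) for u in nodes)
    L += sum(_plogp(q_mod[m] + p_mod_in[m]) for m in modules)
    return L


def _renumber(partition: Mapping[Hashable, int], nodes: Sequence) -> dict:
    """Canonical module ids: 0, 1, ... in order of first appearance."""
    mapping: dict[int, int] = {}
    out = {}
    for u in nodes:
        m = partition[u]
        if m not in mapping:
            mapping[m] = len(mapping)
        out[u] = mapping[m]
    return out


def detect_modules(
    network: GeneNetwork | nx.Graph,
    seed: int = 0,
    weight: str = "or_raw",
) -> tuple[dict, float]:
    """Greedy two-level map-equation minimization.

    Starts from the all-singletons partition and repeatedly applies the
    single-node relocation giving the largest description-length
    decrease (ties broken by lowest node name, then lowest target
    module); when no node move improves, attempts the best whole-module
    merge, and alternates until neither phase improves.  Deterministic;
    ``seed`` is accepted for interface symmetry but the search uses no
    randomness.  Returns (partition, description length in bits).
    """
    graph = network.graph if isinstance(network, GeneNetwork) else network
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    partition = {u: i for i, u in enumerate(nodes)}
    best_L = map_equation_score(graph, partition, weight=weight)
    eps = 1e-12

    def candidate_modules(u) -> list[int]:
        neigh = {partition[v] for v in graph.neighbors(u) if v != u}
        free = max(partition.values()) + 1
        return sorted(neigh | {free})

    improved = True
    while improved:
        improved = False
        # phase 1: best single-node moves
        while True:
            best_move = None
            best_gain = eps
            for u in nodes:
                current = partition[u]
                for m in candidate_modules(u):
                    if m == current:
                        continue
                    partition[u] = m
                    L = map_equation_score(graph, partition, weight=weight)
                    partition[u] = current
                    gain = best_L - L
                    if gain > best_gain + eps:
                        best_gain, best_move = gain, (u, m, L)
            if best_move is None:
                break
            u, m, L = best_move
            partition[u] = m
            best_L = L
            improved = True
        # phase 2: best whole-module merge (aggregated-level move)
        while True:
            mods = sorted(set(partition.values()))
            best_merge = None
            best_gain = eps
            for a, b in itertools.combinations(mods, 2):
                trial = {
                    u: (a if partition[u] == b else partition[u]) for u in nodes
                }
                L = map_equation_score(graph, trial, weight=weight)
                gain = best_L - L
                if gain > best_gain + eps:
                    best_gain, best_merge = gain, (a, b, L)
            if best_merge is None:
                break
            a, b, L = best_merge
            for u in nodes:
                if partition[u] == b:
                    partition[u] = a
            best_L = L
            improved = True
    return _renumber(partition, nodes), best_L


# ---------------------------------------------------------------------------
# module labeling
# ---------------------------------------------------------------------------

def label_modules(
    partition: Mapping[str, int],
    matrix: GeneAlterationMatrix,
) -> list[GeneModule]:
    """Label each module by its most frequent altered-gene combination.

    For every module, each sample's altered set restricted to the
    module's member genes (non-empty sets only, singletons included) is
    a realized combination; the label is the gene(s) of the
    top-frequency combination(s), with ties joined as "A/B" in gene-name
    order.  A module with no altered samples is labeled "(none)".
    """
    modules: list[GeneModule] = []
    for mid in sorted(set(partition.values())):
        members = sorted(g for g, m in partition.items() if m == mid)
        cols = {g: matrix.gene_column(g) for g in members if g in matrix.genes}
        combo_counts: dict[tuple[str, ...], int] = {}
        if cols:
            stacked = np.column_stack([cols[g] for g in sorted(cols)])
            names = sorted(cols)
            for row in stacked:
                combo = tuple(n for n, flag in zip(names, row) if flag)
                if combo:
                    combo_counts[combo] = combo_counts.get(combo, 0) + 1
        if combo_counts:
            top = max(combo_counts.values())
            top_combos = sorted(c for c, k in combo_counts.items() if k == top)
            label_genes = sorted({g for combo in top_combos for g in combo})
            label = "/".join(label_genes)
        else:
            label = "(none)"
        modules.append(
            GeneModule(
                module_id=mid,
                genes=members,
                label=label,
                combination_counts={
                    "+".join(c): k for c, k in sorted(combo_counts.items())
                },
            )
        )
    return modules


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_pairs_tsv(pairs: Sequence[CoocPair], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "gene_a\tgene_b\tn11\tn10\tn01\tn00\tor_cmle\tp\tq_bh\t"
            "cooc_proportion\tcomplete_exclusivity\n"
        )
        for p in pairs:
            handle.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.n11}\t{p.n10}\t{p.n01}\t{p.n00}\t"
                f"{p.or_hat:.6g}\t{p.p_two_sided:.6g}\t{p.q_bh:.6g}\t"
                f"{p.cooc_proportion:.2f}\t{str(p.complete_exclusivity).lower()}\n"
            )


def write_network(network: GeneNetwork, edge_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    with Path(edge_path).open("w", encoding="utf-8") as handle:
        handle.write("gene_a\tgene_b\tor_raw\tabs_or\tsign\tq_bh\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            handle.write(
                f"{u}\t{v}\t{d['or_raw']:.6g}\t{d['weight']:.6g}\t"
                f"{d['sign']}\t{d['q']:.6g}\n"
            )
    if graphml_path is not None:
        nx.write_graphml(network.graph, graphml_path)


def write_modules_tsv(modules: Sequence[GeneModule], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("module_id\tlabel\tgenes\n")
        for m in modules:
            handle.write(f"{m.module_id}\t{m.label}\t{','.join(m.genes)}\n")
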