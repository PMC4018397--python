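"""miRNA-mRNA integration: DE-target intersection, enrichment, networks.

The integration stage joins three upstream results: the miRNA differential
table (only miRNAs with |log2 ratio| >= 3 enter, a deliberately strict
cut that keeps the networks readable), the predicted target sites, and the
differentially expressed gene (DEG) set.  A *DE target* is a gene that is
both a predicted target of a selected miRNA and itself differentially
expressed; the miRNA->gene pairs form a bipartite regulatory network whose
per-pathway restrictions mirror the published network figures.

Pathway enrichment of the DE-target genes is an upper-tail hypergeometric
test per pathway against an expressed-and-annotated background, with
Benjamini-Hochberg FDR across pathways (defaults P < 0.05, FDR <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats

from .diffexpr import DETestResult, bh_fdr
from .io import PathwayCollection
from .targets import TargetSite

__all__ = [
    "DETargetSet",
    "EnrichmentResult",
    "select_de_mirnas",
    "intersect_de_targets",
    "enrich_pathways",
    "hypergeom_upper_tail",
    "build_network",
    "significant_pathways",
    "INTEGRATION_ABS_LOG2",
]

INTEGRATION_ABS_LOG2 = 3.0
DEFAULT_ENRICH_P = 0.05
DEFAULT_ENRICH_FDR = 0.05


@dataclass(frozen=True)
class DETargetSet:
    """miRNA->gene edges with up/down directions on both endpoints."""

    edges: frozenset[tuple[str, str]]
    mirna_direction: Mapping[str, str]
    gene_direction: Mapping[str, str]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.edges)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of DE targets in one pathway."""

    pathway_id: str
    k: int  # DE targets in the pathway
    K: int  # background genes in the pathway
    n: int  # DE-target count (in background)
    N: int  # background size
    p: float
    fdr: float


def select_de_mirnas(
    de_table: Iterable[DETestResult], abs_log2_min: float = INTEGRATION_ABS_LOG2
) -> set[str]:
    """Differential miRNAs passing the |log2 ratio| >= abs_log2_min cut."""
    return {
        r.feature_id
        for r in de_table
        if r.de_class != "not_de" and abs(r.log2fc) >= abs_log2_min
    }


def intersect_de_targets(
    sites: Iterable[TargetSite],
    de_mirnas: Iterable[str],
    de_mirna_direction: Mapping[str, str],
    deg_direction: Mapping[str, str],
) -> DETargetSet:
    """DE targets: predicted targets of selected miRNAs that are DEGs.

    ``deg_direction`` maps each DEG to 'up' or 'down'; genes targeted but
    absent from it are simply not DE and are dropped.  Output is a set, so
    input ordering never matters.
    """
    mirnas = set(de_mirnas)
    edges = set()
    for site in sites:
        if site.mirna_id in mirnas and site.transcript_id in deg_direction:
            edges.add((site.mirna_id, site.transcript_id))
    return DETargetSet(
        edges=frozenset(edges),
        mirna_direction={m: de_mirna_direction[m] for m, _ in edges},
        gene_direction={g: deg_direction[g] for _, g in edges},
    )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) drawing n genes from N with K marked (the enrichment p)."""
    if not (0 <= k <= min(K, n) + 1 and 0 <= K <= N and 0 <= n <= N):
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    de_targets: Iterable[str],
    pathways: PathwayCollection,
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment with BH FDR, sorted by p.

    The universe is ``background``; ``de_targets`` must be a subset of it.
    Pathways with no background member are skipped.  P(X >= k) is computed
    with the hypergeometric survival function.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene set is empty")
    targets = set(de_targets) & bg
    if set(de_targets) - bg:
        raise ValueError("de_targets must be a subset of the background")
    N, n = len(bg), len(targets)
    rows = []
    for pid in sorted(pathways.pathways):
        members = pathways.pathways[pid] & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & targets)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((pid, k, K, p))
    fdrs = bh_fdr([p for _, _, _, p in rows])
    results = [
        EnrichmentResult(pid, k, K, n, N, min(p, 1.0), fdr)
        for (pid, k, K, p), fdr in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p, r.pathway_id))
    return results


def build_network(
    de_targets: DETargetSet, pathway_genes: Iterable[str] | None = None
) -> nx.Graph:
    """Bipartite miRNA-gene graph, optionally restricted to one pathway.

    Nodes carry ``kind`` ('mirna'/'gene') and ``direction`` attributes; the
    graph records the maximum-degree miRNA(s) under ``graph['hub_mirnas']``.
    """
    genes = None if pathway_genes is None else set(pathway_genes)
    g = nx.Graph()
    for mirna, gene in sorted(de_targets.edges):
        if genes is not None and gene not in genes:
            continue
        g.add_node(mirna, kind="mirna", direction=de_targets.mirna_direction[mirna])
        g.add_node(gene, kind="gene", direction=de_targets.gene_direction[gene])
        g.add_edge(mirna, gene)
    for u, v in g.edges:
        kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
        assert kinds == {"mirna", "gene"}, "network must stay bipartite"
    mirna_degrees = {
        node: deg for node, deg in g.degree if g.nodes[node]["kind"] == "mirna"
    }
    if mirna_degrees:
        top = max(mirna_degrees.values())
        g.graph["hub_mirnas"] = sorted(
            node for node, deg in mirna_degrees.items() if deg == top
        )
        g.graph["hub_degree"] = top
    else:
        g.graph["hub_mirnas"] = []
        g.graph["hub_degree"] = 0
    return g


def significant_pathways(
    results: Sequence[EnrichmentResult],
    p_max: float = DEFAULT_ENRICH_P,
    fdr_max: float = DEFAULT_ENRICH_FDR,
) -> list[EnrichmentResult]:
    """Pathways meeting both the raw-p and FDR thresholds."""
    return [r for r in results if r.p < p_max and r.fdr <= fdr_max]
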