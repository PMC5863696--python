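"""Comparison of annotation sets: Jaccard indices and Wang semantic similarity.

Two annotation results, each a (P, G, GO) triplet, are compared with three
indices: the Jaccard coefficient on gene-term pairs and on gene sets (both
structure-free) and a structure-based score that averages, over genes
annotated by both results, the Wang semantic similarity of their two term
sets.  Wang's method propagates an S-value up the ontology from each term
(1 at the term itself, attenuated by a relation-specific weight per edge,
taking the maximum over paths) and scores two terms by the summed S-values of
their shared ancestors relative to their total S-values.  Term sets are
combined by best-match averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .formats_io import AnnotationSet

__all__ = [
    "OntologyDag",
    "SimilarityReport",
    "DEFAULT_EDGE_WEIGHTS",
    "jaccard",
    "wang_term_similarity",
    "gene_semantic_similarity",
    "pipeline_similarity",
]

#: Canonical contribution factors of Wang's method.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyDag:
    """A GO/PO-style DAG: typed child->parent edges, a namespace per term."""

    def __init__(
        self,
        graph: nx.DiGraph,
        edge_weights: Mapping[str, float] | None = None,
    ):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.graph = graph
        self.edge_weights = dict(edge_weights or DEFAULT_EDGE_WEIGHTS)
        for rel, w in self.edge_weights.items():
            if not (0 < w < 1):
                raise ValueError(f"edge weight for {rel!r} must be in (0,1), got {w}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        namespaces: Mapping[str, str] | None = None,
        edge_weights: Mapping[str, float] | None = None,
    ) -> "OntologyDag":
        """Build from (child, parent, relation) triples."""
        g = nx.DiGraph()
        for child, parent, rel in edges:
            g.add_edge(child, parent, relation=rel)
        for t, ns in (namespaces or {}).items():
            g.add_node(t, namespace=ns)
        return cls(g, edge_weights)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term: str) -> list[tuple[str, str]]:
        return [(p, self.graph.edges[term, p]["relation"]) for p in self.graph.successors(term)]

    def s_values(self, term: str) -> dict[str, float]:
        """Wang S-values of ``term`` over itself and all its ancestors.

        S(term) = 1; walking upward, each ancestor receives the maximum over
        its incoming paths of the product of edge weights along the path.
        """
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        s: dict[str, float] = {term: 1.0}
        # process in topological order restricted to term's ancestor closure
        closure = {term} | nx.descendants(self.graph, term)  # edges point child->parent
        for node in nx.topological_sort(self.graph.subgraph(closure)):
            if node == term:
                continue
            best = 0.0
            for child in self.graph.predecessors(node):
                if child in s:
                    w = self.edge_weights.get(self.graph.edges[child, node]["relation"])
                    if w is not None:
                        best = max(best, w * s[child])
            if best > 0:
                s[node] = best
        return s


@dataclass
class SimilarityReport:
    jaccard_pairs: float
    jaccard_genes: float
    semantic_mean: float | None
    per_gene_semantic: dict[str, float]
    skipped_genes: list[str]


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|, defined as 1 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def wang_term_similarity(dag: OntologyDag, term_a: str, term_b: str) -> float:
    """Wang similarity between two terms of the same namespace."""
    ns_a, ns_b = dag.namespace(term_a), dag.namespace(term_b)
    if ns_a != ns_b:
        raise ValueError(
            f"cross-namespace comparison: {term_a} ({ns_a}) vs {term_b} ({ns_b})"
        )
    sa = dag.s_values(term_a)
    sb = dag.s_values(term_b)
    shared = set(sa) & set(sb)
    denom = sum(sa.values()) + sum(sb.values())
    return sum(sa[t] + sb[t] for t in shared) / denom


def gene_semantic_similarity(
    dag: OntologyDag, terms_a: Iterable[str], terms_b: Iterable[str]
) -> float:
    """Best-match average similarity between two term sets of one gene."""
    ta, tb = list(set(terms_a)), list(set(terms_b))
    if not ta or not tb:
        raise ValueError("term sets must be non-empty")
    sim = {
        (x, y): wang_term_similarity(dag, x, y) for x in ta for y in tb
    }
    forward = sum(max(sim[(x, y)] for y in tb) for x in ta) / len(ta)
    backward = sum(max(sim[(x, y)] for x in ta) for y in tb) / len(tb)
    return (forward + backward) / 2.0


def pipeline_similarity(
    ann_a: AnnotationSet,
    ann_b: AnnotationSet,
    dag: OntologyDag,
    namespace: str | None = None,
    gene_scope: str = "intersection",
) -> SimilarityReport:
    """Compare two annotation results with all three indices.

    Pairs are restricted to ``namespace`` (when given) before the Jaccard on
    pairs; the semantic mean averages gene-wise Wang similarity over genes in
    both gene sets (``gene_scope='union'`` scores genes annotated by only one
    result as 0).  When no gene qualifies the semantic mean is None.
    """

    def restrict(ann: AnnotationSet) -> set[tuple[str, str]]:
        return {
            (g, t)
            for g, t in ann.pairs
            if t in dag and (namespace is None or dag.namespace(t) == namespace)
        }

    pairs_a, pairs_b = restrict(ann_a), restrict(ann_b)
    genes_a = {g for g, _ in pairs_a}
    genes_b = {g for g, _ in pairs_b}
    terms_by_gene_a: dict[str, set[str]] = {}
    terms_by_gene_b: dict[str, set[str]] = {}
    for g, t in pairs_a:
        terms_by_gene_a.setdefault(g, set()).add(t)
    for g, t in pairs_b:
        terms_by_gene_b.setdefault(g, set()).add(t)

    if gene_scope == "intersection":
        scope = genes_a & genes_b
    elif gene_scope == "union":
        scope = genes_a | genes_b
    else:
        raise ValueError(f"gene_scope must be 'intersection' or 'union', got {gene_scope!r}")

    def by_namespace(terms: set[str]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for t in terms:
            out.setdefault(dag.namespace(t), set()).add(t)
        return out

    per_gene: dict[str, float] = {}
    skipped: list[str] = []
    for g in sorted(scope):
        ta = by_namespace(terms_by_gene_a.get(g, set()))
        tb = by_namespace(terms_by_gene_b.get(g, set()))
        shared_ns = sorted(set(ta) & set(tb))
        if not shared_ns:
            if gene_scope == "union":
                per_gene[g] = 0.0
            else:
                skipped.append(g)
            continue
        # Wang similarity is defined within one namespace; a gene annotated
        # in several is scored namespace-wise and averaged
        per_gene[g] = sum(
            gene_semantic_similarity(dag, ta[ns], tb[ns]) for ns in shared_ns
        ) / len(shared_ns)

    semantic_mean = (
        sum(per_gene.values()) / len(per_gene) if per_gene else None
    )
    return SimilarityReport(
        jaccard_pairs=jaccard(pairs_a, pairs_b),
        jaccard_genes=jaccard(genes_a, genes_b),
        semantic_mean=semantic_mean,
        per_gene_semantic=per_gene,
        skipped_genes=skipped,
    )
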