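"""Ontology parsing and DAG-based semantic similarity between terms.

Gene Ontology terms live in three directed acyclic graphs (biological
process, molecular function, cellular component) whose edges encode
``is_a`` and ``part_of`` relations.  The similarity between two terms is
computed from *S-values*: the semantic contribution of each ancestor of a
term decays multiplicatively along the path that connects them, with a
per-relation decay factor (0.8 for ``is_a``, 0.6 for ``part_of``).  Two
terms are similar when their ancestor sets overlap and the shared
ancestors carry large S-values from both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Decay factor per edge relation; contributions shrink by this factor
#: for every edge walked from the focus term toward the root.
DEFAULT_EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

NAMESPACES = ("BP", "MF", "CC")

_NS_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


def canonical_namespace(tag: str) -> str | None:
    """Map a namespace spelling (OBO long form or short tag) to BP/MF/CC."""
    return _NS_ALIASES.get(tag.strip())


@dataclass(frozen=True)
class TermAncestry:
    """The focus term, its ancestor closure and the S-value of each member.

    ``s_value[t]`` is the semantic contribution of ancestor ``t`` to the
    focus term: 1 for the focus term itself, and for every other member the
    maximum over its children inside the closure of (edge weight x child's
    S-value).  ``sv_total`` is the sum of all S-values (>= 1).
    """

    focus: str
    s_value: dict[str, float]
    sv_total: float

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.s_value)


class OntologyDAG:
    """One namespace of an ontology: terms plus typed child->parent edges.

    Parameters
    ----------
    namespace:
        One of ``BP``, ``MF``, ``CC``.
    edges:
        Iterable of ``(child, parent, relation)`` triples with relation in
        ``{"is_a", "part_of"}``.
    terms:
        Optional explicit term set; edge endpoints are always included.
    edge_weights:
        Relation -> decay factor map; values must lie in (0, 1).
    """

    def __init__(
        self,
        namespace: str,
        edges: list[tuple[str, str, str]],
        terms: set[str] | None = None,
        edge_weights: dict[str, float] | None = None,
    ) -> None:
        self.namespace = namespace
        self.edge_weights = dict(edge_weights or DEFAULT_EDGE_WEIGHTS)
        for rel, w in self.edge_weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"edge weight for {rel!r} must be in (0,1), got {w}")

        self._graph = nx.DiGraph()  # edges point child -> parent
        if terms:
            self._graph.add_nodes_from(terms)
        for child, parent, rel in edges:
            if rel not in self.edge_weights:
                raise ValueError(f"unsupported relation {rel!r}")
            self._graph.add_edge(child, parent, relation=rel)

        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")

        self._ancestry_cache: dict[str, TermAncestry] = {}
        self._sim_cache: dict[frozenset[str], float] = {}

    # -- introspection -------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def parents(self, term: str) -> list[tuple[str, str]]:
        """``(parent, relation)`` pairs for a term."""
        return [
            (p, self._graph.edges[term, p]["relation"])
            for p in self._graph.successors(term)
        ]

    # -- S-values ------------------------------------------------------

    def term_ancestry(self, term: str) -> TermAncestry:
        """S-values of ``term`` and all of its ancestors.

        The focus term has S-value 1; every ancestor ``t`` gets
        ``max over children t' of t within the closure of w_e(t->t') * S(t')``,
        evaluated by dynamic programming in topological order (children
        before parents), which equals the best decayed path from the focus
        term to ``t``.
        """
        if term not in self._graph:
            raise KeyError(f"term {term!r} not in {self.namespace} ontology")
        cached = self._ancestry_cache.get(term)
        if cached is not None:
            return cached

        closure = {term} | nx.descendants(self._graph, term)  # child->parent edges
        sub = self._graph.subgraph(closure)
        s_value: dict[str, float] = {term: 1.0}
        for node in nx.topological_sort(sub):
            if node == term:
                continue
            best = 0.0
            for child, _, data in sub.in_edges(node, data=True):
                if child in s_value:
                    cand = self.edge_weights[data["relation"]] * s_value[child]
                    if cand > best:
                        best = cand
            s_value[node] = best
        ancestry = TermAncestry(term, s_value, sum(s_value.values()))
        self._ancestry_cache[term] = ancestry
        return ancestry

    def sim(self, a: str, b: str) -> float:
        """Semantic similarity between two terms of this namespace.

        Sum of ``S_A(t) + S_B(t)`` over the shared ancestor closure,
        divided by ``SV(A) + SV(B)``.  Symmetric, in [0, 1], and 1 for
        ``a == b``.
        """
        if a == b:
            if a not in self._graph:
                raise KeyError(f"term {a!r} not in {self.namespace} ontology")
            return 1.0
        key = frozenset((a, b))
        cached = self._sim_cache.get(key)
        if cached is not None:
            return cached
        anc_a = self.term_ancestry(a)
        anc_b = self.term_ancestry(b)
        shared = anc_a.terms & anc_b.terms
        num = sum(anc_a.s_value[t] + anc_b.s_value[t] for t in shared)
        value = num / (anc_a.sv_total + anc_b.sv_total)
        self._sim_cache[key] = value
        return value


def sim_go(dag: OntologyDAG, a: str, b: str) -> float:
    """Module-level alias for :meth:`OntologyDAG.sim`."""
    return dag.sim(a, b)


def term_ancestry(dag: OntologyDAG, term: str) -> TermAncestry:
    """Module-level alias for :meth:`OntologyDAG.term_ancestry`."""
    return dag.term_ancestry(term)


def load_obo(
    path: str, edge_weights: dict[str, float] | None = None
) -> dict[str, OntologyDAG]:
    """Parse an OBO file into one :class:`OntologyDAG` per namespace.

    Only ``is_a`` and ``part_of`` relations are kept; any other relation
    (``regulates``, ...) is dropped and counted.  Obsolete terms are
    excluded.  Raises on a missing file or a cyclic term graph.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)

    per_ns_edges: dict[str, list[tuple[str, str, str]]] = {ns: [] for ns in NAMESPACES}
    per_ns_terms: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
    dropped = 0

    node_ns: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns = canonical_namespace(data.get("namespace", ""))
        if ns is None:
            logger.warning("term %s has no recognised namespace; skipped", node)
            continue
        node_ns[node] = ns
        per_ns_terms[ns].add(node)

    for child, parent, rel in graph.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            dropped += 1
            continue
        ns = node_ns.get(child)
        if ns is None or node_ns.get(parent) != ns:
            logger.warning("edge %s->%s crosses namespaces; skipped", child, parent)
            continue
        per_ns_edges[ns].append((child, parent, rel))

    if dropped:
        logger.warning("dropped %d edges with unsupported relations", dropped)

    return {
        ns: OntologyDAG(ns, per_ns_edges[ns], per_ns_terms[ns], edge_weights)
        for ns in NAMESPACES
        if per_ns_terms[ns]
    }
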