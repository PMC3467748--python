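"""Shared test utilities: independent brute-force oracles and random DAGs."""

from __future__ import annotations

import numpy as np

from pudi.ontology import OntologyDAG


def brute_s_values(dag: OntologyDAG, term: str) -> dict[str, float]:
    """S-values by exhaustive enumeration of every upward path.

    Independent of the package's dynamic-programming recursion: walks all
    root-directed paths from the focus term and records, per visited
    ancestor, the maximum product of edge weights along any path.
    """
    best: dict[str, float] = {}

    def walk(node: str, value: float) -> None:
        if value > best.get(node, 0.0):
            best[node] = value
        for parent, rel in dag.parents(node):
            walk(parent, value * dag.edge_weights[rel])

    walk(term, 1.0)
    return best


def brute_sim(dag: OntologyDAG, a: str, b: str) -> float:
    sa = brute_s_values(dag, a)
    sb = brute_s_values(dag, b)
    shared = set(sa) & set(sb)
    return sum(sa[t] + sb[t] for t in shared) / (sum(sa.values()) + sum(sb.values()))


def random_dag(rng: np.random.Generator, n_terms: int, namespace: str = "BP") -> OntologyDAG:
    """Random rooted DAG: each non-root term links to 1-2 earlier terms."""
    terms = [f"T{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.4 and i >= 2)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.3 else "is_a"
            edges.append((terms[i], terms[int(p)], rel))
    return OntologyDAG(namespace, edges, set(terms))


def chain_dag(relations: list[str], namespace: str = "BP") -> OntologyDAG:
    """Chain R <- T1 <- T2 ... with the given child->parent relations."""
    terms = ["R"] + [f"T{i}" for i in range(1, len(relations) + 1)]
    edges = [
        (terms[i], terms[i - 1], rel) for i, rel in enumerate(relations, start=1)
    ]
    return OntologyDAG(namespace, edges, set(terms))
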