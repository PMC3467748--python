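"""Discriminative feature selection between the positive and unlabeled sets.

Every domain / ontology feature is scored by how asymmetrically it occurs
in the positive gene set P versus the unlabeled set U.  A feature's
*affinity frequency* in a gene set aggregates its association score over
the set's genes (maximal term similarity for ontology features, binary
membership for domains).  The *discrimination ability* score is large when
one affinity frequency is large and the other small, and small when both
are large or both small; the top N features per category are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .features import FeatureSpace, GeneRecord
from .ontology import NAMESPACES, OntologyDAG

logger = logging.getLogger(__name__)

CATEGORIES = ("D", "MF", "BP", "CC")


@dataclass(frozen=True)
class FeatureScore:
    feature: str
    category: str
    af_p: float
    af_u: float
    da: float


def association_score(
    gene: GeneRecord, feature: str, category: str, dag: OntologyDAG | None = None
) -> float:
    """Association between one gene and one feature.

    Ontology categories use the maximal term similarity between the
    feature term and the gene's annotated terms in that namespace; the
    domain category uses binary membership.
    """
    if category == "D":
        return 1.0 if feature in gene.domains else 0.0
    if category in NAMESPACES:
        if dag is None:
            raise ValueError("ontology category requires a dag")
        ann = [t for t in gene.fun_terms.get(category, ()) if t in dag]
        if not ann:
            return 0.0
        return max(dag.sim(t, feature) for t in ann)
    raise ValueError(f"unknown feature category {category!r}")


def affinity_frequency(
    genes: list[GeneRecord],
    feature: str,
    category: str,
    dag: OntologyDAG | None = None,
    normalize: bool = True,
) -> float:
    """Aggregate association of a feature with a gene set.

    Sum of per-gene association scores, divided by the set size when
    ``normalize`` is on (default), so that sets of unequal size remain
    comparable.
    """
    if not genes:
        logger.warning("affinity frequency of %s over an empty gene set", feature)
        return 0.0
    total = sum(association_score(g, feature, category, dag) for g in genes)
    return total / len(genes) if normalize else total


def discrimination_score(af_p: float, af_u: float) -> float:
    """Discrimination ability of a feature from its two affinity frequencies.

    ``max(af_p, af_u) * |af_p - af_u| / (af_p + af_u)``, with 0 for the
    degenerate all-zero case.  Large when one frequency is large and the
    other small; small when both are large or both are small.
    """
    if af_p < 0 or af_u < 0:
        raise ValueError("affinity frequencies must be non-negative")
    tot = af_p + af_u
    if tot == 0.0:
        return 0.0
    return max(af_p, af_u) * abs(af_p - af_u) / tot


def score_features(
    records: dict[str, GeneRecord],
    p_ids: list[str],
    u_ids: list[str],
    space: FeatureSpace,
    dags: dict[str, OntologyDAG],
    normalize: bool = True,
) -> pd.DataFrame:
    """Score every feature of the space; returns a tidy frame with columns
    feature / category / af_p / af_u / da."""
    p_genes = [records.get(g) or GeneRecord(g) for g in p_ids]
    u_genes = [records.get(g) or GeneRecord(g) for g in u_ids]
    rows = []
    category_features = [("D", space.domains, None)] + [
        (ns, space.terms[ns], dags.get(ns)) for ns in NAMESPACES
    ]
    for category, feats, dag in category_features:
        for f in feats:
            af_p = affinity_frequency(p_genes, f, category, dag, normalize)
            af_u = affinity_frequency(u_genes, f, category, dag, normalize)
            rows.append((f, category, af_p, af_u, discrimination_score(af_p, af_u)))
    return pd.DataFrame(rows, columns=["feature", "category", "af_p", "af_u", "da"])


def select_top_n(scores: pd.DataFrame, space: FeatureSpace, n: int) -> FeatureSpace:
    """Keep the N best-discriminating features per category.

    Categories are ranked independently by descending score, ties broken
    by feature id so the selection is deterministic and order-invariant;
    the four PPI features are always retained.  When a category holds
    fewer than N features they are all kept.
    """
    if n < 1:
        raise ValueError("n must be >= 1")

    def top(category: str, available: tuple[str, ...]) -> tuple[str, ...]:
        sub = scores[scores["category"] == category]
        sub = sub.sort_values(["da", "feature"], ascending=[False, True])
        if len(sub) < n:
            logger.info("category %s has %d < %d features; keeping all",
                        category, len(sub), n)
        chosen = sub["feature"].head(n).tolist()
        keep = set(chosen)
        return tuple(f for f in available if f in keep)

    return FeatureSpace(
        domains=top("D", space.domains),
        terms={ns: top(ns, space.terms[ns]) for ns in NAMESPACES},
        ppi_features=space.ppi_features,
    )
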