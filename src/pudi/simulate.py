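"""Synthetic disease-gene study generator.

Emulates the five inputs of a disease-gene identification study — an
ontology per namespace, gene-term annotations, gene-domain memberships, a
PPI network, and positive/unlabeled gene lists — with a planted signal:

* each namespace gets a random tree-like DAG with ``is_a``/``part_of``
  edges and a hidden *disease-term* subset;
* planted disease genes draw their annotations and domains from the
  disease subsets with configurable enrichment odds;
* disease-gene pairs receive extra PPI edges (disease proteins cluster);
* a fraction rho of the planted positives is relabeled into the unlabeled
  set U as *hidden positives*, recorded in a truth list for evaluation.

All outputs are written as plain-text files in the formats the readers in
:mod:`pudi.features` and :mod:`pudi.ontology` consume; regeneration with
the same parameters and seed is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .ontology import NAMESPACES

_OBO_NS_NAME = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass(frozen=True)
class SyntheticParams:
    """Generation parameters for a synthetic study.

    ``n_positives`` is the size of the visible positive list P after
    contamination; ``round(contamination/(1-contamination) * n_positives)``
    additional planted disease genes are hidden inside U and listed in the
    truth file.  ``enrichment_odds`` is the sampling-weight ratio of
    disease terms/domains versus background for planted disease genes
    (1.0 = no signal); ``ppi_positive_bias`` is the extra edge probability
    between two planted disease genes (0.0 = no signal).
    """

    n_genes: int = 600
    n_positives: int = 100
    contamination: float = 0.3
    n_terms_per_ns: int = 60
    n_disease_terms: int = 8
    n_domains: int = 50
    n_disease_domains: int = 10
    mean_annotations: float = 5.0
    mean_domains: float = 2.0
    enrichment_odds: float = 6.0
    ppi_mean_degree: float = 6.0
    ppi_positive_bias: float = 0.05
    second_parent_prob: float = 0.2
    part_of_prob: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must be in [0, 1)")
        if self.n_disease_terms >= self.n_terms_per_ns:
            raise ValueError("disease-term subset must be smaller than the namespace")
        if self.n_disease_domains > self.n_domains:
            raise ValueError("disease-domain subset exceeds the domain pool")
        n_hidden = round(self.contamination / (1 - self.contamination) * self.n_positives)
        if self.n_positives + n_hidden >= self.n_genes:
            raise ValueError("planted positives exceed the gene universe")


@dataclass
class SyntheticStudy:
    """File paths and ground truth of one generated study."""

    params: SyntheticParams
    seed: int
    obo_path: str
    annotation_path: str
    domain_path: str
    ppi_path: str
    positive_path: str
    unlabeled_path: str
    truth_path: str
    positives: list[str] = field(default_factory=list)
    unlabeled: list[str] = field(default_factory=list)
    hidden_positives: list[str] = field(default_factory=list)
    disease_terms: dict[str, list[str]] = field(default_factory=dict)
    disease_domains: list[str] = field(default_factory=list)


def _generate_dag(
    ns: str, n_terms: int, params: SyntheticParams, rng: np.random.Generator
) -> tuple[list[str], list[tuple[str, str, str]]]:
    """Random rooted tree-like DAG: every non-root term has one parent
    among earlier terms, plus occasionally a second parent."""
    terms = [f"{ns}:{i:07d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = int(rng.integers(0, i))
        rel = "part_of" if rng.random() < params.part_of_prob else "is_a"
        edges.append((terms[i], terms[parent], rel))
        if i >= 2 and rng.random() < params.second_parent_prob:
            second = int(rng.integers(0, i))
            if second != parent:
                rel2 = "part_of" if rng.random() < params.part_of_prob else "is_a"
                edges.append((terms[i], terms[second], rel2))
    return terms, edges


def _weighted_choice(
    rng: np.random.Generator,
    items: list[str],
    k: int,
    hot: set[str],
    odds: float,
) -> list[str]:
    """Sample k distinct items, up-weighting the *hot* subset by *odds*."""
    weights = np.array([odds if it in hot else 1.0 for it in items])
    weights /= weights.sum()
    k = min(k, len(items))
    idx = rng.choice(len(items), size=k, replace=False, p=weights)
    return [items[i] for i in sorted(idx)]


def generate_synthetic_study(
    params: SyntheticParams, seed: int, out_dir: str
) -> SyntheticStudy:
    """Generate a complete study into *out_dir* and return its description."""
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)

    # --- ontologies -------------------------------------------------------
    all_terms: dict[str, list[str]] = {}
    all_edges: dict[str, list[tuple[str, str, str]]] = {}
    disease_terms: dict[str, list[str]] = {}
    for ns in NAMESPACES:
        terms, edges = _generate_dag(ns, params.n_terms_per_ns, params, rng)
        all_terms[ns], all_edges[ns] = terms, edges
        pick = rng.choice(
            np.arange(1, len(terms)), size=params.n_disease_terms, replace=False
        )
        disease_terms[ns] = [terms[i] for i in sorted(pick)]

    # --- genes ------------------------------------------------------------
    gene_ids = [f"g{i:05d}" for i in range(params.n_genes)]
    n_hidden = round(params.contamination / (1 - params.contamination) * params.n_positives)
    n_planted = params.n_positives + n_hidden
    planted = [gene_ids[i] for i in sorted(
        rng.choice(params.n_genes, size=n_planted, replace=False))]
    order = rng.permutation(n_planted)
    positives = sorted(planted[i] for i in order[: params.n_positives])
    hidden = sorted(planted[i] for i in order[params.n_positives:])
    planted_set = set(planted)
    unlabeled = [g for g in gene_ids if g not in set(positives)]

    # --- annotations ------------------------------------------------------
    domains = [f"PF{i:05d}" for i in range(params.n_domains)]
    disease_domains = domains[: params.n_disease_domains]
    hot_domains = set(disease_domains)

    ann_rows: list[tuple[str, str, str]] = []
    dom_rows: list[tuple[str, str]] = []
    for gene in gene_ids:
        is_disease = gene in planted_set
        odds = params.enrichment_odds if is_disease else 1.0
        for ns in NAMESPACES:
            k = 1 + int(rng.poisson(params.mean_annotations - 1))
            chosen = _weighted_choice(
                rng, all_terms[ns], k, set(disease_terms[ns]), odds
            )
            ann_rows.extend((gene, t, ns) for t in chosen)
        k_dom = 1 + int(rng.poisson(params.mean_domains - 1))
        chosen_dom = _weighted_choice(rng, domains, k_dom, hot_domains, odds)
        dom_rows.extend((gene, d) for d in chosen_dom)

    # --- PPI network ------------------------------------------------------
    p0 = min(1.0, params.ppi_mean_degree / max(params.n_genes - 1, 1))
    ppi_rows: list[tuple[str, str]] = []
    n = params.n_genes
    iu, ju = np.triu_indices(n, k=1)
    base = rng.random(iu.size) < p0
    is_planted = np.array([g in planted_set for g in gene_ids])
    both_pos = is_planted[iu] & is_planted[ju]
    extra = (rng.random(iu.size) < params.ppi_positive_bias) & both_pos
    for a, b in zip(iu[base | extra], ju[base | extra]):
        ppi_rows.append((gene_ids[a], gene_ids[b]))

    # --- write files ------------------------------------------------------
    obo_path = os.path.join(out_dir, "ontology.obo")
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for ns in NAMESPACES:
            parents: dict[str, list[tuple[str, str]]] = {}
            for child, parent, rel in all_edges[ns]:
                parents.setdefault(child, []).append((parent, rel))
            for term in all_terms[ns]:
                fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
                fh.write(f"namespace: {_OBO_NS_NAME[ns]}\n")
                for parent, rel in parents.get(term, []):
                    if rel == "is_a":
                        fh.write(f"is_a: {parent}\n")
                    else:
                        fh.write(f"relationship: part_of {parent}\n")

    annotation_path = os.path.join(out_dir, "annotations.tsv")
    with open(annotation_path, "w") as fh:
        for gene, term, ns in ann_rows:
            fh.write(f"{gene}\t{term}\t{ns}\n")

    domain_path = os.path.join(out_dir, "domains.tsv")
    with open(domain_path, "w") as fh:
        for gene, dom in dom_rows:
            fh.write(f"{gene}\t{dom}\n")

    ppi_path = os.path.join(out_dir, "ppi.tsv")
    with open(ppi_path, "w") as fh:
        for a, b in ppi_rows:
            fh.write(f"{a}\t{b}\n")

    positive_path = os.path.join(out_dir, "positives.txt")
    with open(positive_path, "w") as fh:
        fh.write("".join(f"{g}\n" for g in positives))

    unlabeled_path = os.path.join(out_dir, "unlabeled.txt")
    with open(unlabeled_path, "w") as fh:
        fh.write("".join(f"{g}\n" for g in unlabeled))

    truth_path = os.path.join(out_dir, "hidden_positives.txt")
    with open(truth_path, "w") as fh:
        fh.write("".join(f"{g}\n" for g in hidden))

    return SyntheticStudy(
        params=params,
        seed=seed,
        obo_path=obo_path,
        annotation_path=annotation_path,
        domain_path=domain_path,
        ppi_path=ppi_path,
        positive_path=positive_path,
        unlabeled_path=unlabeled_path,
        truth_path=truth_path,
        positives=positives,
        unlabeled=unlabeled,
        hidden_positives=hidden,
        disease_terms=disease_terms,
        disease_domains=disease_domains,
    )
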