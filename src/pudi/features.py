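"""Per-gene feature vectors from annotations, domains and PPI topology.

Each gene is represented as the concatenation of five blocks:

* ``D``  — binary indicators over a fixed list of protein-domain accessions;
* ``MF``/``BP``/``CC`` — for every ontology feature term, the maximal
  semantic similarity between that term and any of the gene's annotated
  terms in the same namespace (zero when the gene has no annotations
  there);
* ``PPI`` — four topological features of the gene in the protein
  interaction network: degree, the fraction of direct neighbours that are
  known disease genes (1N), the same fraction over the radius-2
  neighbourhood (2N), and the clustering coefficient.

The domain and ontology blocks are naturally in [0, 1]; the PPI block is
min-max scaled to [0, 1] using ranges fitted on training genes only, so
that Euclidean distances between vectors weigh all blocks commensurately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import NAMESPACES, OntologyDAG, canonical_namespace

logger = logging.getLogger(__name__)

PPI_FEATURE_NAMES = ("degree", "1N", "2N", "Cluster")


@dataclass
class GeneRecord:
    """A gene's raw annotations: ontology terms per namespace and domains."""

    gene_id: str
    fun_terms: dict[str, set[str]] = field(
        default_factory=lambda: {ns: set() for ns in NAMESPACES}
    )
    domains: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class FeatureSpace:
    """Frozen, ordered feature lists; all vectors built against one
    FeatureSpace are positionally comparable."""

    domains: tuple[str, ...]
    terms: dict[str, tuple[str, ...]]  # namespace -> ordered term ids
    ppi_features: tuple[str, ...] = PPI_FEATURE_NAMES

    def __len__(self) -> int:
        return (
            len(self.domains)
            + sum(len(self.terms[ns]) for ns in NAMESPACES)
            + len(self.ppi_features)
        )

    @property
    def feature_names(self) -> list[str]:
        names = [f"D:{d}" for d in self.domains]
        for ns in NAMESPACES:
            names.extend(f"{ns}:{t}" for t in self.terms[ns])
        names.extend(f"PPI:{f}" for f in self.ppi_features)
        return names

    @classmethod
    def from_data(
        cls,
        records: dict[str, GeneRecord],
        dags: dict[str, OntologyDAG],
        gene_ids: list[str] | None = None,
    ) -> "FeatureSpace":
        """Build the full space from observed domains and annotated terms
        (restricted to terms present in the loaded ontology)."""
        if gene_ids is None:
            gene_ids = list(records)
        domains: set[str] = set()
        terms: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
        skipped = 0
        for gid in gene_ids:
            rec = records.get(gid)
            if rec is None:
                continue
            domains |= rec.domains
            for ns in NAMESPACES:
                dag = dags.get(ns)
                for t in rec.fun_terms.get(ns, ()):
                    if dag is not None and t in dag:
                        terms[ns].add(t)
                    else:
                        skipped += 1
        if skipped:
            logger.warning("%d annotated terms absent from the ontology; skipped", skipped)
        return cls(
            domains=tuple(sorted(domains)),
            terms={ns: tuple(sorted(terms[ns])) for ns in NAMESPACES},
        )


@dataclass
class GeneVector:
    """Concatenated (D, MF, BP, CC, PPI) feature vector for one gene."""

    gene_id: str
    d: np.ndarray
    mf: np.ndarray
    bp: np.ndarray
    cc: np.ndarray
    ppi: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.d, self.mf, self.bp, self.cc, self.ppi])

    @property
    def nonzero_fraction(self) -> float:
        v = self.vector
        return float(np.count_nonzero(v)) / v.size if v.size else 0.0


# ---------------------------------------------------------------------------
# readers


def read_annotations(path: str) -> dict[str, GeneRecord]:
    """Read a ``gene_id<TAB>term_id<TAB>namespace`` table into GeneRecords.

    Rows with an unrecognised namespace tag are skipped with a warning;
    an empty file is fatal.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "term", "namespace"],
        dtype=str, comment="#",
    )
    if df.empty:
        raise ValueError(f"annotation file {path} is empty")
    records: dict[str, GeneRecord] = {}
    skipped = 0
    for gene, term, ns_tag in df.itertuples(index=False):
        if not isinstance(gene, str) or not isinstance(term, str) or not isinstance(ns_tag, str):
            skipped += 1
            continue
        ns = canonical_namespace(ns_tag)
        if ns is None:
            skipped += 1
            continue
        rec = records.get(gene)
        if rec is None:
            rec = records[gene] = GeneRecord(gene)
        rec.fun_terms[ns].add(term)
    if skipped:
        logger.warning("skipped %d malformed annotation rows", skipped)
    return records


def read_domains(path: str, records: dict[str, GeneRecord]) -> dict[str, GeneRecord]:
    """Merge a ``gene_id<TAB>domain_accession`` table into *records*
    (in place); unseen genes get a fresh record with empty annotations."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "domain"],
                     dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"domain file {path} is empty")
    skipped = 0
    for gene, dom in df.itertuples(index=False):
        if not isinstance(gene, str) or not isinstance(dom, str):
            skipped += 1
            continue
        rec = records.get(gene)
        if rec is None:
            rec = records[gene] = GeneRecord(gene)
        rec.domains.add(dom)
    if skipped:
        logger.warning("skipped %d malformed domain rows", skipped)
    return records


def read_ppi(path: str) -> nx.Graph:
    """Read an undirected PPI edge list (2-column TSV, or 3-column SIF
    whose middle column is the interaction type).  Self-loops are removed
    and duplicate edges collapse."""
    net = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0] == "":
                continue
            if len(parts) >= 3:
                a, b = parts[0], parts[2]  # SIF: source, relation, target
            elif len(parts) == 2:
                a, b = parts
            else:
                continue
            n_rows += 1
            if a and b and a != b:
                net.add_edge(a, b)
    if n_rows == 0:
        raise ValueError(f"PPI file {path} is empty")
    return net


def read_gene_list(path: str) -> list[str]:
    """One gene id per line; blank lines ignored; order preserved."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return genes


# ---------------------------------------------------------------------------
# feature blocks


def go_component(
    gene: GeneRecord,
    namespace: str,
    feature_terms: tuple[str, ...],
    dag: OntologyDAG,
) -> np.ndarray:
    """Ontology block: entry j is the max similarity between feature term j
    and any of the gene's annotated terms in the namespace (0 if none)."""
    ann = [t for t in gene.fun_terms.get(namespace, ()) if t in dag]
    out = np.zeros(len(feature_terms))
    if not ann:
        return out
    for j, ft in enumerate(feature_terms):
        out[j] = max(dag.sim(t, ft) for t in ann)
    return out


def domain_component(gene: GeneRecord, domain_space: tuple[str, ...]) -> np.ndarray:
    """Binary membership indicator over the ordered domain accessions."""
    return np.array([1.0 if d in gene.domains else 0.0 for d in domain_space])


def ppi_topology(
    net: nx.Graph, gene_id: str, known_positives: set[str]
) -> tuple[float, float, float, float]:
    """(degree, 1N, 2N, clustering coefficient) for one gene.

    1N is the fraction of direct neighbours that are known positives; 2N
    the same fraction over all nodes at distance 1 or 2 (the gene itself
    excluded).  Genes absent from the network get (0, 0, 0, 0).
    """
    if gene_id not in net:
        return (0.0, 0.0, 0.0, 0.0)
    neigh = set(net[gene_id])
    degree = float(len(neigh))
    if not neigh:
        return (0.0, 0.0, 0.0, 0.0)
    one_n = len(neigh & known_positives) / len(neigh)
    radius2 = set(neigh)
    for n in neigh:
        radius2 |= set(net[n])
    radius2.discard(gene_id)
    two_n = len(radius2 & known_positives) / len(radius2) if radius2 else 0.0
    cluster = nx.clustering(net, gene_id) if degree >= 2 else 0.0
    return (degree, one_n, two_n, float(cluster))


class PPIScaler:
    """Min-max scaler for the raw PPI block, fitted on training genes only.

    Transformed values are clipped to [0, 1]; a constant column maps to 0.
    """

    def __init__(self) -> None:
        self.lo: np.ndarray | None = None
        self.span: np.ndarray | None = None

    def fit(self, raw: np.ndarray) -> "PPIScaler":
        raw = np.asarray(raw, dtype=float)
        self.lo = raw.min(axis=0)
        span = raw.max(axis=0) - self.lo
        span[span == 0.0] = np.inf  # constant column -> 0 after transform
        self.span = span
        return self

    def transform(self, raw: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("PPIScaler not fitted")
        return np.clip((np.asarray(raw, dtype=float) - self.lo) / self.span, 0.0, 1.0)


def assemble_vector(
    gene: GeneRecord,
    space: FeatureSpace,
    dags: dict[str, OntologyDAG],
    net: nx.Graph,
    known_positives: set[str],
    ppi_scaler: PPIScaler | None = None,
) -> GeneVector:
    """Assemble one gene's vector in the fixed (D, MF, BP, CC, PPI) order."""
    blocks = {}
    for ns in NAMESPACES:
        dag = dags.get(ns)
        if dag is None or not space.terms[ns]:
            blocks[ns] = np.zeros(len(space.terms[ns]))
        else:
            blocks[ns] = go_component(gene, ns, space.terms[ns], dag)
    raw_ppi = np.array(ppi_topology(net, gene.gene_id, known_positives))
    ppi = ppi_scaler.transform(raw_ppi[None, :])[0] if ppi_scaler else raw_ppi
    return GeneVector(
        gene_id=gene.gene_id,
        d=domain_component(gene, space.domains),
        mf=blocks["MF"],
        bp=blocks["BP"],
        cc=blocks["CC"],
        ppi=ppi,
    )


def fit_ppi_scaler(
    net: nx.Graph, gene_ids: list[str], known_positives: set[str]
) -> PPIScaler:
    raw = np.array([ppi_topology(net, g, known_positives) for g in gene_ids])
    return PPIScaler().fit(raw)


def build_feature_matrix(
    records: dict[str, GeneRecord],
    gene_ids: list[str],
    space: FeatureSpace,
    dags: dict[str, OntologyDAG],
    net: nx.Graph,
    known_positives: set[str],
    ppi_scaler: PPIScaler | None = None,
) -> np.ndarray:
    """Stack gene vectors into an (n_genes, n_features) matrix; genes
    without a record contribute an annotation-free vector."""
    rows = []
    for gid in gene_ids:
        rec = records.get(gid) or GeneRecord(gid)
        rows.append(
            assemble_vector(rec, space, dags, net, known_positives, ppi_scaler).vector
        )
    return np.array(rows)
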