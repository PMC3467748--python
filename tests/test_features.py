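"""Gene feature vectors: readers, GO/domain blocks, PPI topology, assembly."""

import networkx as nx
import numpy as np
import pytest
from helpers import chain_dag

from pudi.features import (
    FeatureSpace,
    GeneRecord,
    PPIScaler,
    assemble_vector,
    build_feature_matrix,
    domain_component,
    fit_ppi_scaler,
    go_component,
    ppi_topology,
    read_annotations,
    read_domains,
    read_gene_list,
    read_ppi,
)


class TestReaders:
    def test_annotation_rows_merge_by_gene(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g1\tGO:1\tBP\ng1\tGO:2\tMF\n")
        records = read_annotations(str(path))
        assert records["g1"].fun_terms["BP"] == {"GO:1"}
        assert records["g1"].fun_terms["MF"] == {"GO:2"}

    def test_long_namespace_names_accepted(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g1\tGO:1\tbiological_process\n")
        assert read_annotations(str(path))["g1"].fun_terms["BP"] == {"GO:1"}

    def test_unknown_namespace_row_skipped(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g1\tGO:1\tBP\ng1\tGO:2\tWEIRD\n")
        records = read_annotations(str(path))
        assert records["g1"].fun_terms["MF"] == set()

    def test_empty_annotation_file_fatal(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(Exception):
            read_annotations(str(path))

    def test_domain_row_for_unseen_gene_creates_record(self, tmp_path):
        path = tmp_path / "dom.tsv"
        path.write_text("gX\tPF00001\n")
        records = read_domains(str(path), {})
        assert records["gX"].domains == {"PF00001"}
        assert records["gX"].fun_terms["BP"] == set()

    def test_duplicate_ppi_edges_collapse(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("a\tb\nb\ta\na\ta\n")
        net = read_ppi(str(path))
        assert net.number_of_edges() == 1
        assert not any(u == v for u, v in net.edges)

    def test_sif_three_column_format(self, tmp_path):
        path = tmp_path / "ppi.sif"
        path.write_text("a\tpp\tb\nb\tpp\tc\n")
        net = read_ppi(str(path))
        assert set(net.edges) == {("a", "b"), ("b", "c")}

    def test_gene_list_preserves_order(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("g2\n\ng1\n")
        assert read_gene_list(str(path)) == ["g2", "g1"]


class TestGoComponent:
    def test_exact_annotation_gives_one(self):
        dag = chain_dag(["is_a"])
        gene = GeneRecord("g", fun_terms={"BP": {"T1"}, "MF": set(), "CC": set()})
        vec = go_component(gene, "BP", ("T1", "R"), dag)
        assert vec[0] == pytest.approx(1.0)

    def test_no_annotations_gives_zeros(self):
        dag = chain_dag(["is_a"])
        gene = GeneRecord("g")
        assert np.all(go_component(gene, "MF", ("T1",), dag) == 0)

    def test_similarity_to_ancestor_feature(self):
        dag = chain_dag(["is_a"])
        gene = GeneRecord("g", fun_terms={"BP": {"T1"}, "MF": set(), "CC": set()})
        vec = go_component(gene, "BP", ("R",), dag)
        assert vec[0] == pytest.approx(1.8 / 2.8)


class TestDomainComponent:
    @pytest.mark.parametrize(
        "domains,space,expected",
        [
            ({"PF00001"}, ("PF00001", "PF00002"), [1.0, 0.0]),
            (set(), ("PF00001", "PF00002"), [0.0, 0.0]),
            ({"PF00001"}, (), []),
        ],
    )
    def test_membership_indicator(self, domains, space, expected):
        gene = GeneRecord("g", domains=domains)
        assert domain_component(gene, space).tolist() == expected


class TestPpiTopology:
    def test_triangle_is_fully_clustered(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert ppi_topology(net, "a", set()) == (2.0, 0.0, 0.0, 1.0)

    def test_star_center_neighbour_fractions(self):
        net = nx.Graph([("hub", f"l{i}") for i in range(4)])
        degree, one_n, two_n, cluster = ppi_topology(net, "hub", {"l0"})
        assert degree == 4.0
        assert one_n == pytest.approx(0.25)
        assert two_n == pytest.approx(0.25)  # radius-2 set is the 4 leaves
        assert cluster == 0.0

    def test_radius_two_includes_indirect_neighbours(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        # from a: direct {b}, indirect {c}; c is positive
        _, one_n, two_n, _ = ppi_topology(net, "a", {"c"})
        assert one_n == 0.0
        assert two_n == pytest.approx(0.5)

    def test_absent_gene_gets_zeros(self):
        net = nx.Graph([("a", "b")])
        assert ppi_topology(net, "zz", {"a"}) == (0.0, 0.0, 0.0, 0.0)


class TestAssembly:
    def _space(self):
        return FeatureSpace(
            domains=("PF00001",),
            terms={"BP": ("T1",), "MF": (), "CC": ()},
        )

    def test_vector_length_is_sum_of_blocks(self, toy_data):
        from pudi.features import FeatureSpace

        space = FeatureSpace.from_data(toy_data.records, toy_data.dags)
        gid = toy_data.positives[0]
        vec = assemble_vector(
            toy_data.records[gid], space, toy_data.dags, toy_data.net,
            set(toy_data.positives),
        )
        assert vec.vector.size == len(space)
        assert vec.vector.size == (
            len(space.domains)
            + sum(len(space.terms[ns]) for ns in ("BP", "MF", "CC"))
            + 4
        )

    def test_gene_with_no_data_is_all_zero(self):
        dag = chain_dag(["is_a"])
        gene = GeneRecord("ghost")
        vec = assemble_vector(gene, self._space(), {"BP": dag}, nx.Graph(), set())
        assert np.all(vec.vector == 0)
        assert vec.nonzero_fraction == 0.0

    def test_scaled_ppi_block_hits_unit_range_at_training_max(self):
        net = nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("d", "b")])
        scaler = fit_ppi_scaler(net, ["a", "b", "c", "d"], set())
        raw = np.array([ppi_topology(net, "b", set())])  # max degree = 3
        assert scaler.transform(raw)[0][0] == pytest.approx(1.0)

    def test_scaler_clips_out_of_range_targets(self):
        scaler = PPIScaler().fit(np.array([[0.0, 0, 0, 0], [2.0, 1, 1, 1]]))
        out = scaler.transform(np.array([[5.0, 0.5, 0.5, 0.5]]))
        assert out[0][0] == 1.0

    def test_identical_records_give_identical_vectors(self):
        dag = chain_dag(["is_a"])
        kwargs = dict(
            fun_terms={"BP": {"T1"}, "MF": set(), "CC": set()},
            domains={"PF00001"},
        )
        v1 = assemble_vector(GeneRecord("g1", **kwargs), self._space(),
                             {"BP": dag}, nx.Graph(), set())
        v2 = assemble_vector(GeneRecord("g2", **kwargs), self._space(),
                             {"BP": dag}, nx.Graph(), set())
        assert np.array_equal(v1.vector, v2.vector)

    def test_matrix_rows_match_per_gene_vectors(self, toy_data):
        space = FeatureSpace.from_data(toy_data.records, toy_data.dags)
        ids = toy_data.positives[:3]
        known = set(toy_data.positives)
        x = build_feature_matrix(toy_data.records, ids, space, toy_data.dags,
                                 toy_data.net, known)
        for i, gid in enumerate(ids):
            vec = assemble_vector(toy_data.records[gid], space, toy_data.dags,
                                  toy_data.net, known)
            assert np.array_equal(x[i], vec.vector)
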