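import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antplantnet import (
    InteractionMatrix,
    filter_rare_interactions,
    from_edge_list,
    read_attributes,
    read_matrix,
    to_edge_list,
    write_matrix,
)
from antplantnet.datasets import load_ant_attributes, load_plant_attributes
from antplantnet.matrix_io import MatrixParseError, MatrixValidationError

from conftest import make_matrix

count_matrices = st.integers(2, 4).flatmap(
    lambda nr: st.integers(2, 4).flatmap(
        lambda nc: st.lists(
            st.lists(st.integers(0, 9), min_size=nc, max_size=nc),
            min_size=nr,
            max_size=nr,
        )
    )
).map(np.array).filter(lambda w: w.sum(1).all() and w.sum(0).all())


class TestReadWrite:
    def test_round_trip_preserves_everything(self, tiny, tmp_path):
        for suffix in (".csv", ".tsv"):
            path = tmp_path / f"m{suffix}"
            write_matrix(tiny, path)
            back = read_matrix(path)
            assert back.plant_labels == tiny.plant_labels
            assert back.ant_labels == tiny.ant_labels
            assert np.array_equal(back.weights, tiny.weights)
            assert back.n_links == 3 and back.total_frequency == 6

    def test_ants_rows_orientation_is_transposed(self, tiny, tmp_path):
        path = tmp_path / "t.csv"
        write_matrix(tiny, path)
        flipped = read_matrix(path, orientation="ants_rows")
        assert flipped.plant_labels == tiny.ant_labels
        assert np.array_equal(flipped.weights, tiny.weights.T)

    @pytest.mark.parametrize(
        "body,err",
        [
            ("s,A1,A2\nP1,2,-1\nP2,0,3\n", MatrixParseError),
            ("s,A1,A2\nP1,2,1.5\nP2,0,3\n", MatrixParseError),
            ("s,A1,A2\nP1,2,x\nP2,0,3\n", MatrixParseError),
            ("s,A1,A1\nP1,2,1\nP2,0,3\n", MatrixValidationError),  # duplicate ant
            ("s,A1,A2\nP1,0,0\nP2,1,3\n", MatrixValidationError),  # empty plant
        ],
    )
    def test_bad_files_rejected_with_location(self, tmp_path, body, err):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(err):
            read_matrix(path)

    def test_parse_error_names_coordinates(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("s,A1,A2\nP1,2,-1\nP2,0,3\n")
        with pytest.raises(MatrixParseError, match="P1.*A2"):
            read_matrix(path)


class TestFilterRare:
    def test_filter_drops_rare_cells_and_empty_species(self):
        m = make_matrix([[1, 2], [3, 5]])
        out = filter_rare_interactions(m, min_count=3)
        assert out.plant_labels == ("P2",)
        assert out.ant_labels == ("A1", "A2")
        assert np.array_equal(out.weights, [[3, 5]])

    def test_min_count_one_is_identity(self, tiny):
        out = filter_rare_interactions(tiny, min_count=1)
        assert np.array_equal(out.weights, tiny.weights)

    def test_empty_result_raises(self):
        with pytest.raises(MatrixValidationError, match="no interactions survive"):
            filter_rare_interactions(make_matrix([[2, 2], [2, 2]]), min_count=3)

    def test_input_untouched(self, tiny):
        filter_rare_interactions(tiny, min_count=3)
        assert tiny.total_frequency == 6

    @given(w=count_matrices)
    @settings(max_examples=50, deadline=None)
    def test_idempotent_at_fixed_threshold(self, w):
        m = make_matrix(w)
        try:
            once = filter_rare_interactions(m, min_count=3)
        except MatrixValidationError:
            return
        twice = filter_rare_interactions(once, min_count=3)
        assert np.array_equal(once.weights, twice.weights)
        assert once.plant_labels == twice.plant_labels


class TestEdgeList:
    def test_edge_count_equals_links(self, tiny):
        edges = to_edge_list(tiny)
        assert len(edges) == tiny.n_links
        assert all(w > 0 for *_, w in edges)

    def test_round_trip(self, tiny):
        back = from_edge_list(to_edge_list(tiny))
        assert to_edge_list(back) == to_edge_list(tiny)


@given(w=count_matrices)
@settings(max_examples=50, deadline=None)
def test_links_and_frequency_match_bruteforce_recount(w):
    m = make_matrix(w)
    assert m.n_links == sum(1 for x in w.flat if x > 0)
    assert m.total_frequency == sum(int(x) for x in w.flat)


class TestAttributes:
    def test_bundled_ant_table_row(self):
        attrs = load_ant_attributes()
        row = attrs.table.loc["Camponotus planatus"]
        assert row["invasive"] == "NO"
        assert row["dominance"] == "C"
        assert row["head_length"] == pytest.approx(1.198)

    def test_bundled_plant_table_row(self):
        attrs = load_plant_attributes()
        row = attrs.table.loc["Arundo donax"]
        assert row["cover"] == pytest.approx(151.66)
        assert row["habitat"] == "O"
        assert row["efn_distribution"] == "C"

    def test_unknown_level_rejected(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("species,habitat\nP1,X\nP2,O\n")
        with pytest.raises(MatrixValidationError, match="'X'"):
            read_attributes(path, "plant")

    def test_join_mismatch_is_labeled(self, tiny, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("species,habitat\nP1,O\n")
        attrs = read_attributes(path, "plant")
        with pytest.raises(MatrixValidationError, match="P2"):
            attrs.aligned_to(list(tiny.plant_labels))
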