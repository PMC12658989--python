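"""ISSR band-matrix analysis: classification, polymorphism, distances, UPGMA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alliumtox.issr import (
    BandMatrix,
    classify_bands,
    distance_matrix,
    polymorphism_report,
    polymorphism_vs_control,
    read_band_matrix,
    total_polymorphism,
    upgma,
    write_band_matrix,
)


def make_matrix(presence, sample_ids=None, weights=None):
    presence = np.asarray(presence)
    n_loci, n_samples = presence.shape
    if sample_ids is None:
        sample_ids = ["neg_control"] + [f"single_{i + 1}" for i in range(n_samples - 1)]
    if weights is None:
        weights = np.linspace(3000, 200, n_loci)
    return BandMatrix(
        primer="test", weights_bp=weights, sample_ids=sample_ids, presence=presence
    )


class TestClassifyBands:
    def test_fixture_examples(self, band_matrices):
        hb12 = classify_bands(band_matrices["HB12"])
        assert hb12[2] == "monomorphic"  # 889.46 bp present in all 8 lanes
        p418 = classify_bands(band_matrices["418"])
        assert p418[0] == "unique"  # 3076.61 bp present only in the SB lane

    def test_all_zero_locus_flagged_absent(self):
        m = make_matrix([[1, 1], [0, 0]])
        assert classify_bands(m) == ["monomorphic", "absent"]

    def test_sb_only_band_is_unique_by_definition(self, band_matrices):
        # The source table prints some single-lane bands as polymorphic; the
        # definitional label (present in exactly one sample) is used here.
        labels = classify_bands(band_matrices["UBC-811"])
        assert labels[3] == "unique"  # 884.98 bp, SB lane only


class TestPolymorphismVsControl:
    def test_one_gained_band_over_union_of_eight(self, band_matrices):
        div = polymorphism_vs_control(band_matrices["HB12"], "single_21.5")
        assert div.percent == pytest.approx(12.5)
        assert len(div.lost) == 0 and len(div.gained) == 1

    def test_positive_control_418(self, band_matrices):
        div = polymorphism_vs_control(band_matrices["418"], "pos_control")
        assert len(div.lost) == 4 and len(div.gained) == 5
        assert div.percent == pytest.approx(90.0)

    def test_identical_columns_are_zero(self):
        m = make_matrix([[1, 1], [0, 0], [1, 1]])
        assert polymorphism_vs_control(m, "single_1").percent == 0.0

    def test_lost_and_gained_carry_weights(self, band_matrices):
        div = polymorphism_vs_control(band_matrices["HB12"], "single_64.5")
        assert {lid for lid, _ in div.lost} == {10, 11}
        assert dict(div.lost)[11] == pytest.approx(221.34)

    def test_control_vs_itself_rejected(self, band_matrices):
        with pytest.raises(ValueError):
            polymorphism_vs_control(band_matrices["HB12"], "neg_control")

    def test_all_28_printed_percentages(self, band_matrices, printed_polymorphism):
        checked = 0
        for primer, matrix in band_matrices.items():
            printed = printed_polymorphism[
                printed_polymorphism["primer"] == primer
            ].set_index("sample")["percent"]
            for sid in matrix.sample_ids:
                if sid == matrix.control_id:
                    continue
                got = polymorphism_vs_control(matrix, sid).percent
                assert got == pytest.approx(printed[sid], abs=0.02), (primer, sid)
                checked += 1
        assert checked == 28

    def test_equals_jaccard_distance(self, band_matrices):
        for matrix in band_matrices.values():
            d = distance_matrix(matrix, metric="jaccard")
            for sid in matrix.sample_ids:
                if sid == matrix.control_id:
                    continue
                assert polymorphism_vs_control(matrix, sid).percent == pytest.approx(
                    100.0 * d.loc[matrix.control_id, sid]
                )


class TestTotalPolymorphism:
    def test_printed_totals(self, band_matrices):
        assert total_polymorphism(band_matrices["HB12"]) == pytest.approx(81.81, abs=0.02)
        assert total_polymorphism(band_matrices["418"]) == pytest.approx(100.0)
        assert total_polymorphism(band_matrices["MAO"]) == pytest.approx(84.61, abs=0.02)

    def test_ubc811_printed_total_is_a_typo(self, band_matrices):
        from alliumtox.published import KNOWN_DISCREPANCIES

        got = total_polymorphism(band_matrices["UBC-811"])
        assert got == pytest.approx(83.33, abs=0.02)  # 10 of 12 loci, not 83.83
        assert ("UBC-811", "total_polymorphism") in KNOWN_DISCREPANCIES

    def test_all_ones_matrix_is_zero(self):
        assert total_polymorphism(make_matrix(np.ones((4, 3)))) == 0.0

    def test_invariant_to_sample_order(self, band_matrices):
        m = band_matrices["HB12"]
        perm = list(reversed(range(len(m.sample_ids))))
        shuffled = BandMatrix(
            primer=m.primer, weights_bp=m.weights_bp,
            sample_ids=[m.sample_ids[i] for i in perm],
            presence=m.presence[:, perm], locus_ids=list(m.locus_ids),
        )
        assert total_polymorphism(shuffled) == total_polymorphism(m)

    def test_adding_monomorphic_locus_decreases_it(self, band_matrices):
        m = band_matrices["HB12"]
        extended = BandMatrix(
            primer=m.primer,
            weights_bp=np.append(m.weights_bp, 150.0),
            sample_ids=list(m.sample_ids),
            presence=np.vstack([m.presence, np.ones((1, len(m.sample_ids)))]),
        )
        assert total_polymorphism(extended) < total_polymorphism(m)


class TestDistanceMatrix:
    def test_diagonal_zero_and_symmetry(self, band_matrices):
        d = distance_matrix(band_matrices["MAO"])
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_complementary_columns_are_disjoint(self):
        m = make_matrix([[1, 0], [0, 1], [1, 0]])
        d = distance_matrix(m, metric="jaccard")
        assert d.loc["neg_control", "single_1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["jaccard", "dice", "simple_matching"])
    def test_metrics_available(self, band_matrices, metric):
        d = distance_matrix(band_matrices["HB12"], metric=metric)
        assert (d.to_numpy() >= 0).all() and (d.to_numpy() <= 1).all()

    def test_empty_sample_rejected_for_jaccard(self):
        m = make_matrix([[1, 0], [1, 0]])
        with pytest.raises(ValueError):
            distance_matrix(m, metric="jaccard")

    @given(st.data())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_jaccard_metric_axioms(self, data):
        n_loci = data.draw(st.integers(3, 8))
        n_samples = data.draw(st.integers(3, 6))
        presence = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 1), min_size=n_samples, max_size=n_samples),
                    min_size=n_loci, max_size=n_loci,
                )
            )
        )
        # every sample needs at least one band for jaccard to be defined
        presence[0, :] = 1
        d = distance_matrix(make_matrix(presence), metric="jaccard").to_numpy()
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        for i, j, k in itertools.combinations(range(n_samples), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestUpgma:
    def test_two_leaves_split_the_distance(self):
        d = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]], index=["a", "b"], columns=["a", "b"])
        tree = upgma(d)
        depths = tree.leaf_depths()
        assert depths["a"] == pytest.approx(0.3)
        assert depths["b"] == pytest.approx(0.3)

    def test_three_point_hand_agglomeration(self):
        # d(a,b)=2, d(a,c)=d(b,c)=4: merge (a,b) at height 1, then join c at 2.
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], index=list("abc"), columns=list("abc"),
            dtype=float,
        )
        tree = upgma(d)
        coph = tree.cophenetic()
        assert coph.loc["a", "b"] == pytest.approx(2.0)
        assert coph.loc["a", "c"] == pytest.approx(4.0)
        assert coph.loc["b", "c"] == pytest.approx(4.0)
        assert tree.leaf_depths() == pytest.approx({"a": 2.0, "b": 2.0, "c": 2.0})

    def test_ultrametricity_on_fixture_trees(self, band_matrices):
        for matrix in band_matrices.values():
            tree = upgma(distance_matrix(matrix))
            depths = np.array(list(tree.leaf_depths().values()))
            assert np.ptp(depths) <= 1e-9

    def test_newick_parses_and_is_ultrametric(self, band_matrices):
        dendropy = pytest.importorskip("dendropy")
        tree = upgma(distance_matrix(band_matrices["418"]))
        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        tips = {
            leaf.taxon.label: leaf.distance_from_root() for leaf in t.leaf_node_iter()
        }
        assert len(tips) == 8
        assert max(tips.values()) - min(tips.values()) <= 1e-9

    def test_sample_order_permutation_same_cophenetics(self, band_matrices):
        m = band_matrices["MAO"]
        d = distance_matrix(m)
        perm = list(reversed(m.sample_ids))
        coph_a = upgma(d).cophenetic()
        coph_b = upgma(d.loc[perm, perm]).cophenetic()
        for x in m.sample_ids:
            for y in m.sample_ids:
                assert coph_a.loc[x, y] == pytest.approx(coph_b.loc[x, y])

    def test_nan_distances_rejected(self):
        d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            upgma(d)


class TestIO:
    def test_round_trip(self, band_matrices, tmp_path):
        m = band_matrices["HB12"]
        path = tmp_path / "hb12.csv"
        write_band_matrix(m, path)
        back = read_band_matrix(path, primer="HB12")
        assert back.sample_ids == m.sample_ids
        assert np.array_equal(back.presence, m.presence)
        assert np.allclose(back.weights_bp, m.weights_bp)
        assert back.locus_ids == m.locus_ids

    def test_non_binary_entry_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("locus,weight_bp,neg_control,single_1\n1,500,1,2\n")
        with pytest.raises(ValueError):
            read_band_matrix(path)

    def test_duplicate_locus_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "locus,weight_bp,neg_control,single_1\n1,500,1,0\n1,400,0,1\n"
        )
        with pytest.raises(ValueError):
            read_band_matrix(path)

    def test_fixture_bundle_loads_all_four_primers(self, band_matrices):
        assert set(band_matrices) == {"HB12", "418", "UBC-811", "MAO"}
        for m in band_matrices.values():
            assert len(m.sample_ids) == 8
            assert (m.weights_bp >= 193).all() and (m.weights_bp <= 3077).all()
        assert sum(m.n_loci for m in band_matrices.values()) == 49
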