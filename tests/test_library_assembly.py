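import itertools

import numpy as np
import pandas as pd
import pytest

from peplib.library_assembly import (
    build_libraries,
    cluster_markers,
    intersection_counts,
    min_max_scale_rows,
    presence_sets,
    unique_markers,
)
from peplib.proteome_io import ProteinRecord
from peplib.proteotypicity import build_index

from oracles import brute_force_complete_linkage


class TestIntersections:
    def test_nested_sets_example(self):
        sets = {"A": {"a", "b", "c"}, "B": {"b", "c"}, "C": {"c"}}
        summary = intersection_counts(sets)
        nonzero = {s: c for s, c in summary.counts.items() if c}
        assert nonzero == {("A",): 1, ("A", "B"): 1, ("A", "B", "C"): 1}
        assert summary.core == 1
        assert summary.unique("A") == 1
        assert summary.unique("B") == 0

    def test_disjoint_sets(self):
        sets = {"A": {"a"}, "B": {"b"}, "C": {"c", "d"}}
        summary = intersection_counts(sets)
        nonzero = {s: c for s, c in summary.counts.items() if c}
        assert nonzero == {("A",): 1, ("B",): 1, ("C",): 2}

    def test_identical_sets(self):
        sets = {"A": {"x", "y"}, "B": {"x", "y"}}
        summary = intersection_counts(sets)
        assert summary.counts[("A", "B")] == 2
        assert summary.core == 2
        assert sum(c for s, c in summary.counts.items() if s != ("A", "B")) == 0

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(5)
        universe = [f"p{i}" for i in range(60)]
        sets = {
            f"T{k}": {p for p in universe if rng.random() < 0.4}
            for k in range(4)
        }
        summary = intersection_counts(sets)
        assert summary.total == len(set().union(*sets.values()))
        assert all(c >= 0 for c in summary.counts.values())
        assert len(summary.counts) == 2 ** 4 - 1

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(17)
        universe = [f"p{i}" for i in range(40)]
        sets = {
            f"T{k}": {p for p in universe if rng.random() < 0.5}
            for k in range(3)
        }
        summary = intersection_counts(sets)
        labels = list(sets)
        for r in range(1, 4):
            for subset in itertools.combinations(labels, r):
                expected = sum(
                    1
                    for p in set().union(*sets.values())
                    if all((p in sets[t]) == (t in subset) for t in labels)
                )
                assert summary.counts[tuple(subset)] == expected

    def test_permuting_order_keeps_counts(self):
        sets = {"A": {"a", "b"}, "B": {"b"}, "C": {"a", "c"}}
        fwd = intersection_counts(sets)
        rev = intersection_counts(dict(reversed(list(sets.items()))))
        assert {frozenset(s): c for s, c in fwd.counts.items()} == {
            frozenset(s): c for s, c in rev.counts.items()
        }

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            intersection_counts({})


class TestUniqueMarkers:
    SETS = {"A": {"a", "b", "c"}, "B": {"b", "c"}, "C": {"c"}}

    def test_target_with_unique(self):
        assert unique_markers(self.SETS, "A") == ["a"]

    def test_subset_target_empty(self):
        assert unique_markers(self.SETS, "C") == []

    def test_predicate_filters(self):
        assert unique_markers(self.SETS, "A", predicate=lambda acc: False) == []

    def test_unknown_target_raises(self):
        with pytest.raises(ValueError):
            unique_markers(self.SETS, "Z")


class TestMinMaxScaling:
    def test_row_example(self):
        m = pd.DataFrame([[2.0, 4.0, 6.0]], index=["p"], columns=list("xyz"))
        assert list(min_max_scale_rows(m).iloc[0]) == [0.0, 0.5, 1.0]

    def test_zero_range_row_maps_to_zero(self):
        m = pd.DataFrame([[3.0, 3.0, 3.0]], index=["p"], columns=list("xyz"))
        assert list(min_max_scale_rows(m).iloc[0]) == [0.0, 0.0, 0.0]

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((15, 5)) * 100)
        scaled = min_max_scale_rows(m)
        assert ((scaled >= 0) & (scaled <= 1)).all().all()


class TestClusterMarkers:
    def _matrix(self, values, labels=None):
        values = np.asarray(values, dtype=float)
        labels = labels or [f"p{i}" for i in range(values.shape[0])]
        return pd.DataFrame(values, index=labels,
                            columns=[f"c{j}" for j in range(values.shape[1])])

    def test_two_rows_single_merge(self):
        m = self._matrix([[0.0, 1.0], [1.0, 0.0]])
        result = cluster_markers(m)
        assert len(result.merges) == 1
        a, b, h = result.merges[0]
        assert (a, b) == (0, 1)
        # scaled rows are [0,1] and [1,0]: distance sqrt(2)
        assert h == pytest.approx(np.sqrt(2))

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            cluster_markers(self._matrix([[1.0, 2.0]]))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        m = self._matrix(rng.random((12, 4)))
        heights = [h for _, _, h in cluster_markers(m).merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(10)
        m = self._matrix(rng.random((9, 5)))
        result = cluster_markers(m)
        assert sorted(result.leaf_order) == sorted(m.index)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = self._matrix(rng.random((10, 5)))
        result = cluster_markers(m)
        expected = brute_force_complete_linkage(
            min_max_scale_rows(m).to_numpy()
        )
        assert len(result.merges) == len(expected)
        for (a, b, h), (ea, eb, eh) in zip(result.merges, expected):
            assert (a, b) == (ea, eb)
            assert h == pytest.approx(eh, abs=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.random((8, 4))
        labels = [f"p{i}" for i in range(8)]
        m = self._matrix(values, labels)
        perm = rng.permutation(8)
        mp = m.iloc[perm]
        a = cluster_markers(m)
        b = cluster_markers(mp)
        heights_a = sorted(h for _, _, h in a.merges)
        heights_b = sorted(h for _, _, h in b.merges)
        assert np.allclose(heights_a, heights_b)
        # same partition structure: leaf order agrees up to relabeling
        assert sorted(a.leaf_order) == sorted(b.leaf_order)


class TestBuildLibraries:
    @pytest.fixture
    def toy(self):
        proteome = [
            ProteinRecord("P1", "alpha protein", "MKLNGTESTVIRAAAKALMNTPEVK",
                          gene_symbol="Gna"),
            ProteinRecord("P2", "beta protein", "MRLNGTESTVIRCCCHHHWWYYFFDDEEK",
                          gene_symbol="Gnb"),
            ProteinRecord("P3", "gamma protein", "MKAGTSLDNVKGGGKAVLDNTESK",
                          gene_symbol="Gnc"),
        ]
        index = build_index(proteome)
        counts = pd.DataFrame({
            "cell_type": ["c1", "c1", "c2", "c2"],
            "accession": ["P1", "P3", "P2", "P3"],
            "spectral_count": [10, 20, 30, 5],
        })
        evidence = pd.DataFrame(
            [
                ("c1", "ALMNTPEVK", "P1"),
                ("c1", "LNGTESTVIR", "P1"),  # shared, not proteotypic
                ("c1", "AGTSLDNVK", "P3"),
                ("c1", "AVLDNTESK", "P3"),
                ("c2", "LNGTESTVIR", "P2"),
                ("c2", "AGTSLDNVK", "P3"),
            ],
            columns=["cell_type", "peptide", "accession"],
        )
        return proteome, index, counts, evidence

    def test_one_library_per_cell_type(self, toy):
        proteome, index, counts, evidence = toy
        libs = build_libraries(counts, evidence, (), proteome, index)
        assert sorted(libs) == ["c1", "c2"]
        assert sorted(libs["c1"].proteins["accession"]) == ["P1", "P3"]
        assert sorted(libs["c2"].proteins["accession"]) == ["P2", "P3"]

    def test_proteotypic_peptide_counts(self, toy):
        proteome, index, counts, evidence = toy
        libs = build_libraries(counts, evidence, (), proteome, index)
        c1 = libs["c1"].proteins.set_index("accession")
        assert c1.loc["P1", "n_proteotypic_peptides"] == 1  # shared excluded
        assert c1.loc["P3", "n_proteotypic_peptides"] == 2
        c2 = libs["c2"].proteins.set_index("accession")
        assert c2.loc["P2", "n_proteotypic_peptides"] == 0

    def test_nsaf_joined(self, toy):
        proteome, index, counts, evidence = toy
        libs = build_libraries(counts, evidence, (), proteome, index)
        c1 = libs["c1"].proteins.set_index("accession")
        # saf: P1 10/25, P3 20/24 -> normalized
        saf1, saf3 = 10 / 25, 20 / 24
        assert c1.loc["P1", "nsaf"] == pytest.approx(saf1 / (saf1 + saf3))

    def test_scores_and_mz_columns(self, toy):
        proteome, index, counts, evidence = toy
        libs = build_libraries(counts, evidence, (), proteome, index)
        peps = libs["c1"].peptides.set_index("sequence")
        assert {"mz_z2", "mz_z3", "mz_z4", "total"} <= set(peps.columns)
        # every observed peptide has c1 = 1; shared peptide loses c2
        assert (peps["c1"] == 1).all()
        assert peps.loc["ALMNTPEVK", "c2"] == 1
        assert peps.loc["LNGTESTVIR", "c2"] == 0

    def test_empty_ptms_ok(self, toy):
        proteome, index, counts, evidence = toy
        libs = build_libraries(counts, evidence, (), proteome, index)
        assert libs["c1"].ptm_sites.empty

    def test_unknown_accession_raises(self, toy):
        proteome, index, counts, evidence = toy
        bad = pd.concat([
            evidence,
            pd.DataFrame([("c1", "AAAAAAK", "P9")], columns=evidence.columns),
        ])
        with pytest.raises(ValueError, match="P9"):
            build_libraries(counts, bad, (), proteome, index)

    def test_annotations_passthrough(self, toy):
        proteome, index, counts, evidence = toy
        libs = build_libraries(counts, evidence, (), proteome, index,
                               annotations={"P1": ["R-MMU-1", "GO:0001"]})
        c1 = libs["c1"].proteins.set_index("accession")
        assert c1.loc["P1", "annotations"] == "R-MMU-1;GO:0001"
        assert c1.loc["P3", "annotations"] == ""


def test_presence_sets_requires_proteotypic(two_parent_proteome):
    index = build_index(two_parent_proteome)
    evidence = pd.DataFrame(
        [("c1", "TESTR", "P1")], columns=["cell_type", "peptide", "accession"]
    )
    assert presence_sets(evidence, index) == {}
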