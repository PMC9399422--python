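"""DMG calling, labelling, the Pearson network, and sample clustering."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist

from extremophen.burden_matrix import GeneMutationMatrix, group_rates
from extremophen.dmg_network import (
    DMGLabel,
    EdgeSign,
    average_linkage,
    call_dmgs,
    cluster_samples,
    correlation_matrix,
    jaccard_distance_matrix,
    label_dmgs,
    pearson_network,
    pearson_pvalue,
)
from extremophen.io_core import CohortDesign


def _rates_from(values: dict[str, list[int]], design: CohortDesign):
    genes = sorted(values)
    m = GeneMutationMatrix(
        genes=genes,
        samples=design.samples,
        values=np.array([values[g] for g in genes], dtype=np.int8),
        provenance={},
    )
    return m, group_rates(m, design)


@pytest.fixture
def small_design():
    return CohortDesign.from_items(
        [("DM", [f"m{i}" for i in range(5)]), ("DR", [f"r{i}" for i in range(5)])]
    )


class TestCallDmgs:
    def test_large_difference_called_and_oriented(self, small_design):
        _, r = _rates_from({"G": [1, 0, 0, 0, 0, 1, 1, 1, 1, 1]}, small_design)
        (rec,) = call_dmgs(r, [("DR", "DM")])
        assert rec.enriched_in == "DR"
        assert rec.abs_diff == pytest.approx(0.8)

    def test_sub_threshold_difference_not_called(self, small_design):
        _, r = _rates_from({"G": [1, 1, 0, 0, 0, 1, 1, 1, 1, 0]}, small_design)
        assert call_dmgs(r, [("DR", "DM")]) == []

    def test_exact_boundary_is_inclusive(self, small_design):
        # 3/5 vs 0/5: difference exactly 0.6 passes a 0.6 cut
        _, r = _rates_from({"G": [0, 0, 0, 0, 0, 1, 1, 1, 0, 0]}, small_design)
        (rec,) = call_dmgs(r, [("DR", "DM")], diff_min=0.6)
        assert rec.abs_diff == pytest.approx(0.6)

    def test_boundary_exact_across_unequal_group_sizes(self):
        # 3/5 - 0/6 = 0.6 exactly; no float drift allowed
        design = CohortDesign.from_items(
            [("DM", [f"m{i}" for i in range(6)]), ("DR", [f"r{i}" for i in range(5)])]
        )
        _, r = _rates_from({"G": [0] * 6 + [1, 1, 1, 0, 0]}, design)
        assert len(call_dmgs(r, [("DR", "DM")], diff_min=0.6)) == 1

    def test_antisymmetry_in_group_order(self, small_design):
        _, r = _rates_from(
            {"G1": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0], "G2": [0, 0, 0, 0, 0, 1, 1, 1, 1, 0]},
            small_design,
        )
        fwd = call_dmgs(r, [("DR", "DM")])
        rev = call_dmgs(r, [("DM", "DR")])
        assert {x.gene for x in fwd} == {x.gene for x in rev}
        for a, b in zip(fwd, rev):
            assert a.abs_diff == b.abs_diff
            assert a.enriched_in == b.enriched_in  # enrichment is group-intrinsic

    def test_unknown_group_rejected(self, small_design):
        _, r = _rates_from({"G": [0] * 10}, small_design)
        with pytest.raises(KeyError):
            call_dmgs(r, [("DR", "NOPE")])


class TestLabelDmgs:
    def test_case_control_mapping(self, small_design):
        _, r = _rates_from(
            {"SUS": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1], "PRO": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]},
            small_design,
        )
        recs = label_dmgs(call_dmgs(r, [("DR", "DM")]), {"DR"}, "DM")
        labels = {x.gene: x.label for x in recs}
        assert labels == {"SUS": DMGLabel.SUSCEPTIBLE, "PRO": DMGLabel.PROTECTIVE}

    def test_enrichment_outside_known_groups_unlabeled(self):
        design = CohortDesign.from_items(
            [(g, [f"{g}{i}" for i in range(2)]) for g in ("A", "B", "C")]
        )
        _, r = _rates_from({"G": [0, 0, 0, 0, 1, 1]}, design)
        recs = label_dmgs(call_dmgs(r, [("C", "A")]), {"B"}, "A")
        assert recs[0].label is DMGLabel.UNLABELED


class TestPearsonNetwork:
    def _matrix(self, rows: list[list[int]]) -> GeneMutationMatrix:
        return GeneMutationMatrix(
            genes=[f"g{i}" for i in range(len(rows))],
            samples=[f"s{j}" for j in range(len(rows[0]))],
            values=np.array(rows, dtype=np.int8),
            provenance={},
        )

    def test_identical_vectors_give_perfect_positive_edge(self):
        v = [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1]
        (edge,) = pearson_network(self._matrix([v, v]))
        assert edge.r == pytest.approx(1.0)
        assert edge.p == 0.0
        assert edge.sign is EdgeSign.POSITIVE

    def test_complementary_vectors_give_negative_edge(self):
        v = [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1]
        w = [1 - x for x in v]
        (edge,) = pearson_network(self._matrix([v, w]))
        assert edge.r == pytest.approx(-1.0)
        assert edge.sign is EdgeSign.NEGATIVE

    def test_r_and_p_match_scipy_oracle(self):
        rng = np.random.default_rng(17)
        rows = (rng.random((6, 15)) < 0.5).astype(int).tolist()
        rows = [r for r in rows if 0 < sum(r) < 15]
        m = self._matrix(rows)
        edges = pearson_network(m, r_min=0.0, p_max=1.01)
        by_pair = {(e.gene_i, e.gene_j): e for e in edges}
        for i, j in itertools.combinations(range(len(rows)), 2):
            r_ref, p_ref = sps.pearsonr(rows[i], rows[j])
            e = by_pair[(f"g{i}", f"g{j}")]
            assert e.r == pytest.approx(r_ref, abs=1e-12)
            assert e.p == pytest.approx(p_ref, abs=1e-12)

    def test_threshold_decision_matches_enumeration(self):
        rng = np.random.default_rng(23)
        rows = (rng.random((8, 15)) < 0.4).astype(int).tolist()
        m = self._matrix(rows)
        edges = {(e.gene_i, e.gene_j) for e in pearson_network(m)}
        expected = set()
        for i, j in itertools.combinations(range(len(rows)), 2):
            if np.std(rows[i]) == 0 or np.std(rows[j]) == 0:
                continue
            r_ref, p_ref = sps.pearsonr(rows[i], rows[j])
            if abs(r_ref) >= 0.8 and p_ref < 0.05:
                expected.add((f"g{i}", f"g{j}"))
        assert edges == expected

    def test_correlation_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(31)
        rows = (rng.random((5, 12)) < 0.5).astype(int)
        m = self._matrix(rows.tolist())
        c = correlation_matrix(m).to_numpy()
        valid = rows.std(axis=1) > 0
        assert np.allclose(c[np.ix_(valid, valid)], c[np.ix_(valid, valid)].T)
        assert np.allclose(np.diag(c)[valid], 1.0)
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-12

    def test_zero_variance_gene_yields_no_edges(self):
        m = self._matrix([[1, 1, 1, 1, 1], [1, 0, 1, 0, 1]])
        assert pearson_network(m, r_min=0.0, p_max=1.01) == []

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_network(self._matrix([[0, 1], [1, 0]]))

    def test_pvalue_transform_against_direct_formula(self):
        for r, n in [(0.5, 15), (-0.9, 10), (0.83, 15)]:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            expected = 2 * sps.t.sf(abs(t), n - 2)
            assert pearson_pvalue(r, n) == pytest.approx(expected, abs=1e-15)


def reference_upgma(dist: np.ndarray) -> np.ndarray:
    """Naive UPGMA reference keeping explicit member lists; ties broken by
    the smallest (i, j) cluster-id pair."""
    n = dist.shape[0]
    clusters: list[tuple[int, list[int]]] = [(i, [i]) for i in range(n)]
    z = []
    nid = n
    while len(clusters) > 1:
        options = []
        for (ida, ma), (idb, mb) in itertools.combinations(clusters, 2):
            d = math.fsum(dist[x, y] for x in ma for y in mb) / (len(ma) * len(mb))
            lo, hi = min(ida, idb), max(ida, idb)
            options.append((d, lo, hi, ma + mb if ida < idb else mb + ma))
        d, lo, hi, merged = min(options, key=lambda o: (o[0], o[1], o[2]))
        clusters = [c for c in clusters if c[0] not in (lo, hi)] + [(nid, merged)]
        z.append([lo, hi, d, len(merged)])
        nid += 1
    return np.array(z)


class TestClustering:
    def _matrix(self, profiles: np.ndarray) -> GeneMutationMatrix:
        # profiles: samples x genes
        return GeneMutationMatrix(
            genes=[f"g{i}" for i in range(profiles.shape[1])],
            samples=[f"s{j}" for j in range(profiles.shape[0])],
            values=profiles.T.astype(np.int8),
            provenance={},
        )

    def test_identical_samples_merge_first_at_zero(self):
        profiles = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        res = cluster_samples(self._matrix(profiles))
        assert list(res.sample_linkage[0][:3]) == [0, 1, 0.0]

    def test_forced_merge_order(self):
        # pairwise distances ~ (0.1, high, high): closest pair merges first
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        z = average_linkage(d)
        assert (z[0][0], z[0][1]) == (0, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linkage_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        profiles = (rng.random((6, 10)) < 0.5).astype(int)
        d = jaccard_distance_matrix(profiles)
        assert np.allclose(average_linkage(d), reference_upgma(d))

    def test_linkage_matches_scipy_on_tie_free_fixture(self):
        rng = np.random.default_rng(4)
        profiles = rng.random((7, 12))  # continuous -> ties have measure zero
        d = np.zeros((7, 7))
        cond = pdist(profiles, metric="euclidean")
        k = 0
        for i in range(7):
            for j in range(i + 1, 7):
                d[i, j] = d[j, i] = cond[k]
                k += 1
        ours = average_linkage(d)
        ref = scipy_linkage(cond, method="average")
        assert np.allclose(np.sort(ours[:, 2]), np.sort(ref[:, 2]))
        assert np.allclose(ours[:, 2], ref[:, 2])

    def test_jaccard_distance_all_zero_pair_is_zero(self):
        d = jaccard_distance_matrix(np.zeros((2, 4), dtype=int))
        assert d[0, 1] == 0.0

    def test_single_sample_trivial_tree(self):
        m = self._matrix(np.array([[1, 0]]))
        res = cluster_samples(m)
        assert res.sample_linkage.shape == (0, 4)
        assert res.sample_order == ["s0"]

    def test_planted_identical_carriers_form_positive_edge(self, study_design):
        # two genes mutated in exactly the same samples always correlate
        carriers = np.zeros(15, dtype=np.int8)
        carriers[[1, 4, 7, 9, 12]] = 1
        m = GeneMutationMatrix(
            ["d1", "d2"], study_design.samples,
            np.vstack([carriers, carriers]), {},
        )
        (edge,) = pearson_network(m)
        assert edge.sign is EdgeSign.POSITIVE and edge.r == pytest.approx(1.0)
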