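"""Parameter-map analyses: network transfer, zones, correlations, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmfm.hierarchy import (ROIMap, ZoneAssignment, assign_zones,
                            correlate_maps, fdr_bh, hemispheric_average,
                            transfer_to_networks, zone_activation_profile)


def brute_force_zones(values, areas, labels, n_zones):
    """Enumerate every contiguous partition of the sorted ROIs and return
    the assignment minimizing sum of squared area deviations from the
    equal share. Independent oracle for the dynamic program."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], labels[i]))
    target = sum(areas) / n_zones
    best_cost, best_bounds = None, None
    for bounds in itertools.combinations(range(1, n), n_zones - 1):
        edges = (0,) + bounds + (n,)
        cost = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            cost += (sum(areas[order[i]] for i in range(a, b)) - target) ** 2
        if best_cost is None or cost < best_cost:
            best_cost, best_bounds = cost, edges
    zones = [0] * n
    for z, (a, b) in enumerate(zip(best_bounds[:-1], best_bounds[1:]), start=1):
        for i in range(a, b):
            zones[order[i]] = z
    return np.array(zones)


def brute_force_bh(pvals, q):
    """Step-up definition evaluated literally."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p)
    k_max = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= q * k / n:
            k_max = k
    reject = np.zeros(n, bool)
    reject[order[:k_max]] = True
    return reject


class TestTransferToNetworks:
    def test_identity_weights_pass_through(self):
        m = ROIMap([1.0, 2.0, 3.0], ["a", "b", "c"])
        w = pd.DataFrame(np.eye(3), index=["a", "b", "c"], columns=list("xyz"))
        np.testing.assert_allclose(transfer_to_networks(m, w).values, m.values)

    def test_uniform_weights_give_global_mean(self):
        m = ROIMap([1.0, 2.0, 6.0], ["a", "b", "c"])
        w = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"], columns=["n1", "n2"])
        np.testing.assert_allclose(transfer_to_networks(m, w).values, 3.0)

    def test_weighted_mean_arithmetic(self):
        m = ROIMap([1.0, 3.0], ["a", "b"])
        w = pd.DataFrame({"net": [1.0, 3.0]}, index=["a", "b"])
        assert transfer_to_networks(m, w)["net"] == pytest.approx(2.5)

    def test_commutes_with_positive_rescaling(self):
        rng = np.random.default_rng(0)
        m = ROIMap(rng.uniform(0, 1, 6))
        w = pd.DataFrame(rng.uniform(0, 2, (6, 3)), index=m.roi_labels)
        a = transfer_to_networks(m, w)
        b = transfer_to_networks(ROIMap(3.0 * m.values, m.roi_labels), w)
        np.testing.assert_allclose(3.0 * a.values, b.values)

    def test_zero_weight_network_rejected(self):
        m = ROIMap([1.0, 2.0], ["a", "b"])
        w = pd.DataFrame({"dead": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero total weight"):
            transfer_to_networks(m, w)


class TestHemisphericAverage:
    def test_pair_mean(self):
        m = ROIMap([0.2, 0.4], ["lh_x", "rh_x"])
        out = hemispheric_average(m, [("lh_x", "rh_x")])
        assert out.values[0] == pytest.approx(0.3)
        assert out.roi_labels == ["x"]

    def test_symmetric_map_unchanged(self):
        m = ROIMap([0.7, 0.7, 0.1, 0.1], ["lh_a", "rh_a", "lh_b", "rh_b"])
        out = hemispheric_average(m, [("lh_a", "rh_a"), ("lh_b", "rh_b")])
        np.testing.assert_allclose(out.values, [0.7, 0.1])

    def test_full_atlas_pair_count(self):
        labels = [f"lh_r{i}" for i in range(34)] + [f"rh_r{i}" for i in range(34)]
        m = ROIMap(np.arange(68.0), labels)
        pairs = [(f"lh_r{i}", f"rh_r{i}") for i in range(34)]
        assert hemispheric_average(m, pairs).n == 34

    def test_missing_partner_rejected(self):
        m = ROIMap([1.0], ["lh_a"])
        with pytest.raises(ValueError, match="rh_a"):
            hemispheric_average(m, [("lh_a", "rh_a")])


class TestAssignZones:
    def test_equal_area_even_split(self):
        m = ROIMap([0.1, 0.2, 0.3, 0.4], areas=np.ones(4))
        np.testing.assert_array_equal(assign_zones(m, 2).zones, [1, 1, 2, 2])

    def test_single_zone(self):
        m = ROIMap([0.5, 0.1, 0.9], areas=np.ones(3))
        np.testing.assert_array_equal(assign_zones(m, 1).zones, [1, 1, 1])

    def test_unequal_areas_balanced(self):
        # areas (3,1,1,3), ascending values: balanced split is (1,1 | 2,2)
        m = ROIMap([0.1, 0.2, 0.3, 0.4], areas=np.array([3.0, 1, 1, 3]))
        np.testing.assert_array_equal(assign_zones(m, 2).zones, [1, 1, 2, 2])

    def test_zone_index_monotone_in_value(self):
        rng = np.random.default_rng(1)
        m = ROIMap(rng.uniform(0, 1, 12), areas=rng.uniform(0.5, 2, 12))
        za = assign_zones(m, 4)
        order = np.argsort(m.values)
        assert np.all(np.diff(za.zones[order]) >= 0)

    def test_invariant_to_roi_ordering(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, 10)
        areas = rng.uniform(0.5, 2, 10)
        labels = [f"r{i}" for i in range(10)]
        za = assign_zones(ROIMap(vals, labels, areas), 3)
        perm = rng.permutation(10)
        za_p = assign_zones(ROIMap(vals[perm], [labels[i] for i in perm],
                                   areas[perm]), 3)
        np.testing.assert_array_equal(za.zones[perm], za_p.zones)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_partitioner(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, min(n, 5)))
        vals = rng.uniform(0, 1, n)
        areas = rng.uniform(0.5, 3.0, n)
        labels = [f"r{i}" for i in range(n)]
        got = assign_zones(ROIMap(vals, labels, areas), k).zones
        expected = brute_force_zones(vals, areas, labels, k)
        np.testing.assert_array_equal(got, expected)

    def test_too_many_zones_rejected(self):
        m = ROIMap([0.1, 0.2], areas=np.ones(2))
        with pytest.raises(ValueError):
            assign_zones(m, 3)

    def test_requires_areas(self):
        with pytest.raises(ValueError, match="areas"):
            assign_zones(ROIMap([0.1, 0.2]), 2)


class TestZoneActivationProfile:
    def _zones(self, values, areas, k):
        return assign_zones(ROIMap(values, areas=np.asarray(areas, float)), k)

    def test_concentrated_component_peaks_in_its_zone(self):
        za = self._zones([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1], 2)
        comp = ROIMap([0.0, 0.0, 5.0, 5.0])
        profile, _ = zone_activation_profile([comp], za, np.ones(4))
        assert profile.iloc[0].idxmax() == "zone2"

    def test_normalization_conserved(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(0.5, 2, 8)
        za = self._zones(rng.uniform(0, 1, 8), areas, 3)
        comps = [ROIMap(rng.uniform(0, 4, 8)) for _ in range(3)]
        profile, _ = zone_activation_profile(comps, za, areas, total=100_000)
        zone_areas = np.array([areas[za.zones == z].sum() for z in (1, 2, 3)])
        sums = (profile.to_numpy() * zone_areas).sum(axis=1)
        np.testing.assert_allclose(sums, 100_000)

    def test_components_ordered_by_peak_zone(self):
        za = self._zones([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1], 2)
        high = ROIMap([0.0, 0.0, 1.0, 1.0])   # peaks in zone 2
        low = ROIMap([1.0, 1.0, 0.0, 0.0])    # peaks in zone 1
        profile, order = zone_activation_profile([high, low], za, np.ones(4))
        assert list(profile.index) == ["component2", "component1"]
        np.testing.assert_array_equal(order, [1, 0])

    def test_uniform_component_equal_scores_on_equal_zones(self):
        za = self._zones([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1], 2)
        profile, _ = zone_activation_profile([ROIMap(np.ones(4))], za, np.ones(4))
        assert profile.iloc[0]["zone1"] == pytest.approx(profile.iloc[0]["zone2"])

    def test_zero_component_rejected(self):
        za = self._zones([0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1], 2)
        with pytest.raises(ValueError, match="zero"):
            zone_activation_profile([ROIMap(np.zeros(4))], za, np.ones(4))


class TestCorrelateMaps:
    def test_identical_and_negated(self):
        a = ROIMap([1.0, 2, 3, 5, 4])
        r, p = correlate_maps(a, a)
        assert r == pytest.approx(1.0)
        r, _ = correlate_maps(a, ROIMap(-a.values, a.roi_labels))
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson_and_pvalue(self):
        a = ROIMap([1.0, 2, 3, 4, 5])
        b = ROIMap([2.0, 4, 6, 8, 11])
        r, p = correlate_maps(a, b)
        assert r == pytest.approx(0.9959, abs=1e-4)
        # p from the exact t transform with n-2 = 3 degrees of freedom
        from scipy import stats as ss
        t = r * np.sqrt(3 / (1 - r * r))
        assert p == pytest.approx(2 * ss.t.sf(t, 3), rel=1e-6)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            correlate_maps(ROIMap([1.0, 1, 1]), ROIMap([1.0, 2, 3]))


class TestFDR:
    def test_step_up_by_hand(self):
        flags = fdr_bh([0.001, 0.02, 0.03, 0.04, 0.9], q=0.05)
        np.testing.assert_array_equal(flags, [True, True, True, True, False])

    def test_all_ones_none_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0]).any()

    def test_single_small_p_rejected(self):
        assert fdr_bh([0.04], q=0.05)[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_step_up_enumeration(self, pvals, q):
        np.testing.assert_array_equal(fdr_bh(pvals, q), brute_force_bh(pvals, q))
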