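"""Curve construction: binning, standardization, HAC/HUC/HPC/SI, combining."""

import numpy as np
import pytest

from hscurves.data_io import SampleRecord, TraitRecord
from hscurves.ffg import COMMUNITY, assign_ffg
from hscurves.suitability import (
    BinScheme,
    CurveSet,
    availability_curve,
    build_curve_set,
    combine_campaigns,
    default_bins,
    huc_hac_excess,
    preference_curve,
    sample_value,
    standardize_by_campaign,
    to_si,
    utilization_curve,
)
from tests.conftest import random_dataset


def _sample(sid, campaign, v, counts=None, area=1.0, depth=0.2, sub="a"):
    return SampleRecord(sid, campaign, v, depth, sub, area, counts or {})


@pytest.fixture
def membership():
    return assign_ffg([TraitRecord("A", "O", "F", {"GAT": 10})])


class TestDefaultBins:
    def test_velocity_bins_cover_data(self):
        b = default_bins("velocity", data_max=0.58)
        assert b.n_bins == 12
        assert b.edges[0] == 0.0 and b.edges[-1] == 0.60

    def test_substrate_six_categories(self):
        b = default_bins("substrate")
        assert b.kind == "categorical"
        assert b.categories == ("a", "c", "ae", "ce", "e", "f")

    def test_degenerate_range_single_bin(self):
        b = default_bins("depth", data_max=0.03)
        assert b.n_bins == 1
        assert b.edges == (0.0, 0.05)

    def test_exact_multiple_no_extra_bin(self):
        assert default_bins("velocity", data_max=0.60).n_bins == 12


class TestBinIndex:
    def test_half_open_with_closed_last(self):
        b = default_bins("velocity", data_max=0.15)
        assert b.index(0.0) == 0
        assert b.index(0.05) == 1  # lower edge belongs to upper bin
        assert b.index(0.149) == 2
        assert b.index(0.15) == 2  # last bin closed

    def test_out_of_range(self):
        b = default_bins("velocity", data_max=0.15)
        with pytest.raises(ValueError):
            b.index(0.2)

    def test_categorical_lookup(self):
        b = default_bins("substrate")
        assert b.index("ce") == 3
        with pytest.raises(ValueError):
            b.index("x")


class TestStandardize:
    def test_single_campaign_divide_by_max(self, membership):
        samples = [_sample(f"s{i}", "c1", 0.1, {"A": n})
                   for i, n in enumerate((50, 25, 0))]
        std = standardize_by_campaign(samples, membership, COMMUNITY)
        assert [std[f"s{i}"] for i in range(3)] == [1.0, 0.5, 0.0]

    def test_per_campaign_maxima(self, membership):
        samples = [
            _sample("a1", "A", 0.1, {"A": 100}),
            _sample("a2", "A", 0.1, {"A": 25}),
            _sample("b1", "B", 0.1, {"A": 10}),
            _sample("b2", "B", 0.1, {"A": 5}),
        ]
        std = standardize_by_campaign(samples, membership, COMMUNITY)
        assert [std[k] for k in ("a1", "a2", "b1", "b2")] == [1.0, 0.25, 1.0, 0.5]

    def test_all_zero_campaign_warns(self, membership):
        samples = [_sample("z1", "Z", 0.1), _sample("z2", "Z", 0.2)]
        with pytest.warns(UserWarning, match="all zero"):
            std = standardize_by_campaign(samples, membership, COMMUNITY)
        assert std == {"z1": 0.0, "z2": 0.0}

    def test_count_rescale_invariance(self, membership):
        base = [(100, 20), (40, 5)]
        samples = [_sample(f"s{i}", "c1", 0.1, {"A": n}) for i, (n, _) in enumerate(base)]
        tripled = [_sample(f"s{i}", "c1", 0.1, {"A": 3 * n})
                   for i, (n, _) in enumerate(base)]
        a = standardize_by_campaign(samples, membership, COMMUNITY)
        b = standardize_by_campaign(tripled, membership, COMMUNITY)
        assert a == b


class TestAvailability:
    def test_equal_areas_two_bins(self):
        b = default_bins("velocity", data_max=0.1)
        samples = [_sample("s1", "c", 0.02), _sample("s2", "c", 0.07)]
        np.testing.assert_allclose(availability_curve(samples, b), [0.5, 0.5])

    def test_area_weighted(self):
        b = default_bins("velocity", data_max=0.1)
        samples = [
            _sample("s1", "c", 0.02, area=1.0),
            _sample("s2", "c", 0.07, area=1.0),
            _sample("s3", "c", 0.08, area=2.0),
        ]
        np.testing.assert_allclose(availability_curve(samples, b), [0.25, 0.75])

    def test_area_rescale_invariance(self):
        b = default_bins("velocity", data_max=0.1)
        samples = [_sample("s1", "c", 0.02, area=0.5), _sample("s2", "c", 0.07, area=1.5)]
        scaled = [_sample("s1", "c", 0.02, area=5.0), _sample("s2", "c", 0.07, area=15.0)]
        np.testing.assert_allclose(
            availability_curve(samples, b), availability_curve(scaled, b)
        )

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            availability_curve([], default_bins("substrate"))


class TestUtilization:
    def test_normalized_sums(self):
        b = default_bins("velocity", data_max=0.1)
        samples = [_sample("s1", "c", 0.02), _sample("s2", "c", 0.07)]
        u = utilization_curve(samples, b, {"s1": 1.0, "s2": 0.5})
        np.testing.assert_allclose(u, [2 / 3, 1 / 3])

    def test_zero_total_rejected(self):
        b = default_bins("velocity", data_max=0.1)
        samples = [_sample("s1", "c", 0.02)]
        with pytest.raises(ValueError, match="GAT"):
            utilization_curve(samples, b, {"s1": 0.0}, group="GAT")


class TestPreferenceAndSI:
    def test_uniform_use_flat_preference(self):
        hac = np.array([0.25] * 4)
        hpc, defined = preference_curve(hac, hac)
        np.testing.assert_allclose(hpc, np.ones(4))
        assert defined.all()

    def test_hand_worked_ratio(self):
        hpc, _ = preference_curve(np.array([0.6, 0.4]), np.array([0.8, 0.2]))
        np.testing.assert_allclose(hpc, [0.75, 2.0])
        si = to_si(hpc)
        np.testing.assert_allclose(si, [0.375, 1.0])

    def test_unavailable_bin_masked_not_zero(self):
        hpc, defined = preference_curve(
            np.array([0.5, 0.5, 0.0]), np.array([0.5, 0.5, 0.0])
        )
        assert defined.tolist() == [True, True, False]
        assert np.isnan(hpc[2])

    def test_use_without_availability_rejected(self):
        with pytest.raises(ValueError, match="zero availability"):
            preference_curve(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    def test_si_constant_positive_all_ones(self):
        np.testing.assert_allclose(to_si(np.array([0.3, 0.3])), [1.0, 1.0])

    def test_si_single_defined_bin(self):
        si = to_si(np.array([0.7, np.nan]), np.array([True, False]))
        assert si[0] == 1.0 and np.isnan(si[1])

    def test_si_all_zero_rejected(self):
        with pytest.raises(ValueError):
            to_si(np.array([0.0, 0.0]))


class TestExcess:
    def test_no_difference(self):
        rep = huc_hac_excess(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(rep.diff, [0, 0])
        assert rep.troughs == ()

    def test_trough_flagged_where_availability_exceeds_use(self):
        rep = huc_hac_excess(np.array([0.6, 0.4]), np.array([0.3, 0.7]))
        np.testing.assert_allclose(rep.diff, [0.3, -0.3])
        assert rep.troughs == (0,)

    def test_orphan_use_flagged(self):
        rep = huc_hac_excess(np.array([1.0, 0.0]), np.array([0.8, 0.2]))
        assert rep.use_without_availability == (1,)


def _curveset_from_si(si, defined=None):
    """Wrap a bare SI vector as a CurveSet for combination tests."""
    si = np.asarray(si, dtype=float)
    defined = np.ones(len(si), bool) if defined is None else np.asarray(defined)
    bins = default_bins("velocity", data_max=0.05 * len(si))
    return CurveSet(
        parameter="velocity", group="COMMUNITY", campaign="x", bins=bins,
        hac=si, huc=si, hpc=si, si_huc=si, si_hpc=si, defined=defined,
    )


class TestCombine:
    def test_single_campaign_pointwise_max_is_elementwise_max(self):
        cs = _curveset_from_si([0.2, 1.0, 0.4])
        object.__setattr__(cs, "si_huc", np.array([0.5, 1.0, 0.1]))
        final = combine_campaigns([cs], strategy="pointwise_max")
        np.testing.assert_allclose(final.si, [0.5, 1.0, 0.4])

    def test_two_campaign_pointwise_max(self):
        a = _curveset_from_si([1.0, 0.2, 0.1])
        b = _curveset_from_si([0.1, 0.2, 1.0])
        final = combine_campaigns([a, b], strategy="pointwise_max")
        np.testing.assert_allclose(final.si, [1.0, 0.2, 1.0])

    def test_envelope_fill_bridges_qualifying_bins(self):
        a = _curveset_from_si([1.0, 0.2, 0.1])
        b = _curveset_from_si([0.1, 0.2, 1.0])
        final = combine_campaigns([a, b], strategy="envelope_fill",
                                  fill_threshold=0.8)
        np.testing.assert_allclose(final.si, [1.0, 1.0, 1.0])

    def test_envelope_fill_dominates_pointwise_max(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            si1, si2 = rng.random(6), rng.random(6)
            a, b = _curveset_from_si(si1), _curveset_from_si(si2)
            pm = combine_campaigns([a, b], strategy="pointwise_max")
            ef = combine_campaigns([a, b], strategy="envelope_fill")
            assert (np.nan_to_num(ef.si) >= np.nan_to_num(pm.si) - 1e-12).all()

    def test_both_strategies_idempotent(self):
        a = _curveset_from_si([1.0, 0.2, 0.1, 0.9, 0.3])
        b = _curveset_from_si([0.1, 0.6, 1.0, 0.2, 0.2])
        for strategy in ("pointwise_max", "envelope_fill"):
            once = combine_campaigns([a, b], strategy=strategy)
            twice = combine_campaigns([once], strategy=strategy)
            np.testing.assert_allclose(twice.si, once.si)

    def test_envelope_fill_categorical_rejected(self):
        bins = default_bins("substrate")
        si = np.full(6, 0.5)
        cs = CurveSet(parameter="substrate", group="COMMUNITY", campaign="x",
                      bins=bins, hac=si, huc=si, hpc=si, si_huc=si, si_hpc=si,
                      defined=np.ones(6, bool))
        with pytest.raises(ValueError, match="categorical"):
            combine_campaigns([cs], strategy="envelope_fill")

    def test_masked_bins_treated_as_absent(self):
        a = _curveset_from_si([1.0, np.nan, 0.3], defined=[True, False, True])
        b = _curveset_from_si([0.2, 0.5, np.nan], defined=[True, True, False])
        final = combine_campaigns([a, b], strategy="pointwise_max")
        np.testing.assert_allclose(final.si, [1.0, 0.5, 0.3])
        assert final.defined.all()


# --- independent loop-based oracle -----------------------------------------

def brute_force_curves(samples, bins, standardized):
    """Availability and utilization by explicit per-sample loops."""
    n = bins.n_bins
    a = [0.0] * n
    u = [0.0] * n
    for s in samples:
        value = sample_value(s, bins.parameter)
        if bins.kind == "categorical":
            i = list(bins.categories).index(value)
        else:
            i = None
            for j in range(n):
                lo, hi = bins.edges[j], bins.edges[j + 1]
                if (lo <= value < hi) or (j == n - 1 and value == hi):
                    i = j
                    break
            assert i is not None, "value outside bins"
        a[i] += s.area
        u[i] += standardized[s.sample_id]
    sa, su = sum(a), sum(u)
    return [x / sa for x in a], [x / su for x in u]


class TestOracle:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("parameter", ["velocity", "depth", "substrate"])
    def test_curves_match_loop_tally(self, seed, parameter):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_samples=int(rng.integers(5, 21)))
        membership = assign_ffg(ds.traits)
        if parameter == "substrate":
            bins = default_bins("substrate")
        else:
            vmax = max(sample_value(s, parameter) for s in ds.samples)
            bins = default_bins(parameter, data_max=vmax)
        std = standardize_by_campaign(ds.samples, membership, COMMUNITY)
        hac = availability_curve(ds.samples, bins)
        huc = utilization_curve(ds.samples, bins, std)
        a_ref, u_ref = brute_force_curves(ds.samples, bins, std)
        np.testing.assert_allclose(hac, a_ref, atol=1e-12)
        np.testing.assert_allclose(huc, u_ref, atol=1e-12)


class TestConservation:
    @pytest.mark.parametrize("seed", range(3))
    def test_curve_sums_and_si_max(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, n_samples=15)
        membership = assign_ffg(ds.traits)
        bins = default_bins(
            "velocity", data_max=max(s.velocity for s in ds.samples)
        )
        cs = build_curve_set(ds.samples, membership, COMMUNITY, bins)
        assert cs.hac.sum() == pytest.approx(1.0, abs=1e-9)
        assert cs.huc.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.nanmax(cs.si_huc) == pytest.approx(1.0, abs=1e-12)
        assert np.nanmax(cs.si_hpc) == pytest.approx(1.0, abs=1e-12)
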