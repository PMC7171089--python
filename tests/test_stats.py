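import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from devbrainmap import stats as st


def brute_force_bh(p):
    """Step-up BH from the definition: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, m * p[idx] / rank))
        q[idx] = running
    return q


class TestBH:
    def test_hand_example(self):
        q = st.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(st.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(st.bh_adjust([0.037]), [0.037])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            st.bh_adjust([0.1, np.nan])

    def test_matches_brute_force_on_random_grid_vectors(self):
        rng = np.random.default_rng(12)
        grid = np.round(np.arange(0.01, 1.001, 0.01), 2)
        for length in range(1, 7):
            for _ in range(200):
                p = rng.choice(grid, size=length)
                np.testing.assert_allclose(st.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(20)
        q = st.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hs.lists(hs.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_properties_hold_for_arbitrary_p_vectors(self, p):
        q = st.bh_adjust(p)
        np.testing.assert_allclose(q, brute_force_bh(p), atol=1e-12)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0 + 1e-12)).all()


class TestNBGroupTest:
    def test_identical_groups_null(self):
        a = np.array([100, 110, 95, 105, 102])
        r = st.nb_group_test(a, a)
        assert r.p_value > 0.9
        assert abs(r.mean_a - r.mean_b) < 1e-9

    def test_all_zero_degenerate(self):
        r = st.nb_group_test([0, 0, 0], [0, 0, 0])
        assert r.degenerate and r.p_value == 1.0

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(3)
        a = st._rnb(rng, 200.0, 50.0, 5)
        b = st._rnb(rng, 800.0, 50.0, 5)
        r = st.nb_group_test(a, b)
        assert r.p_value < 0.01

    def test_offsets_absorb_volume_differences(self):
        # same density, one group observed over twice the volume
        rng = np.random.default_rng(4)
        base = st._rnb(rng, 300.0, 50.0, 5)
        doubled = st._rnb(rng, 600.0, 50.0, 5)
        r_with = st.nb_group_test(base, doubled,
                                  offsets_a=np.zeros(5), offsets_b=np.full(5, np.log(2.0)))
        r_without = st.nb_group_test(base, doubled)
        assert r_with.p_value > 0.05
        assert r_without.p_value < r_with.p_value

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            st.nb_group_test([5], [1, 2])

    @pytest.mark.parametrize("test", ["lrt", "wald"])
    def test_both_test_types_run(self, test):
        rng = np.random.default_rng(9)
        a = st._rnb(rng, 100.0, 20.0, 5)
        b = st._rnb(rng, 100.0, 20.0, 5)
        r = st.nb_group_test(a, b, config=st.StatsConfig(test=test))
        assert 0.0 <= r.p_value <= 1.0


class TestCompareRegions:
    def _tidy(self, rng, n_regions=8, planted=(3,), fold=3.0, n=5):
        rows = []
        for rid in range(1, n_regions + 1):
            mu = 300.0
            for sex, shift in (("M", fold if rid in planted else 1.0), ("F", 1.0)):
                counts = st._rnb(rng, mu * shift, 30.0, n)
                for s, c in enumerate(counts):
                    rows.append({"region_id": rid, "sex": sex, "subject": s,
                                 "n2d": int(c), "volume_mm3": 0.5})
        return pd.DataFrame(rows)

    def test_planted_region_flagged(self):
        rng = np.random.default_rng(21)
        df = self._tidy(rng)
        res = st.compare_regions(df, "sex")
        assert res.set_index("region_id").loc[3, "significant"]

    def test_q_at_least_p(self):
        rng = np.random.default_rng(22)
        res = st.compare_regions(self._tidy(rng), "sex")
        ok = res["q_value"].notna()
        assert (res.loc[ok, "q_value"] >= res.loc[ok, "p_value"] - 1e-12).all()

    def test_degenerate_regions_leave_fdr_family(self):
        rng = np.random.default_rng(23)
        df = self._tidy(rng)
        zero = df["region_id"] == 5
        df.loc[zero, "n2d"] = 0
        res = st.compare_regions(df, "sex").set_index("region_id")
        assert res.loc[5, "degenerate"]
        assert np.isnan(res.loc[5, "q_value"])
        assert not res.loc[5, "significant"]

    def test_needs_exactly_two_groups(self):
        rng = np.random.default_rng(24)
        df = self._tidy(rng)
        df.loc[df.index[:5], "sex"] = "X"
        with pytest.raises(ValueError, match="2 levels"):
            st.compare_regions(df, "sex")


class TestPower:
    def test_zero_effect_power_near_alpha(self):
        pw = st.nb_power(300.0, 20.0, 5, st.StatsConfig(seed=2), n_sim=400,
                         effect_size=0.0)
        assert abs(pw - 0.05) < 0.03

    def test_power_monotone_in_n(self):
        cfg = st.StatsConfig(seed=3)
        p3 = st.nb_power(300.0, 20.0, 3, cfg, n_sim=200)
        p5 = st.nb_power(300.0, 20.0, 5, cfg, n_sim=200)
        p10 = st.nb_power(300.0, 20.0, 10, cfg, n_sim=200)
        assert p3 <= p5 + 0.05 and p5 <= p10 + 0.05

    def test_huge_effect_power_near_one(self):
        pw = st.nb_power(300.0, 20.0, 5, st.StatsConfig(seed=4, effect_size=10.0), n_sim=100)
        assert pw > 0.95

    def test_region_power_summary(self):
        cfg = st.StatsConfig(seed=5)
        df = st.power_regions({1: 200.0, 2: 800.0}, 20.0, 5, cfg, n_sim=50)
        assert set(df["region_id"]) == {1, 2}
        assert 0.0 <= df.attrs["fraction_powered"] <= 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            st.nb_power(100.0, 20.0, 1)


class TestHistologyHelpers:
    @pytest.mark.parametrize(
        "double,total,decimals,expected",
        [
            (321, 383, 1, 83.8),
            (99, 576, 0, 17.0),
            (156, 1191, 0, 13.0),
            (301, 1581, 0, 19.0),
            (36, 49, 0, 73.0),
            (0, 50, 1, 0.0),
        ],
    )
    def test_colocalization_percent(self, double, total, decimals, expected):
        assert st.colocalization_percent(double, total, decimals) == expected

    def test_colocalization_zero_total_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            st.colocalization_percent(0, 0)

    def test_colocalization_bounds_checked(self):
        with pytest.raises(ValueError):
            st.colocalization_percent(10, 5)

    @pytest.mark.parametrize(
        "count,comparator,expected",
        [(0, ">=", False), (4, ">=", True), (4, ">", False), (10, ">=", True), (10, ">", True)],
    )
    def test_puncta_rule_comparators(self, count, comparator, expected):
        assert st.puncta_positive(count, comparator=comparator) is expected

    def test_spine_density_units(self):
        da, db, t, p = st.spine_density_test([20, 10], [10.0, 10.0], [5, 5], [10.0, 10.0])
        assert da.tolist() == [20.0, 10.0]

    def test_identical_groups_p_near_one(self):
        _, _, t, p = st.spine_density_test([10, 12], [10.0, 10.0], [10, 12], [10.0, 10.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_pooled_t(self):
        # hand-computed: densities A = (2, 4), B = (1, 1)
        # means 3 and 1; pooled var = ((2-3)^2+(4-3)^2+0+0)/2 = 1
        # t = (3-1)/sqrt(1*(1/2+1/2)) = 2; df = 2 -> p = 0.1835 (two-tailed)
        da, db, t, p = st.spine_density_test([2, 4], [10.0, 10.0], [1, 1], [10.0, 10.0])
        assert t == pytest.approx(2.0)
        assert p == pytest.approx(0.18350, abs=1e-4)

    def test_short_groups_rejected(self):
        with pytest.raises(ValueError, match="2 dendritic"):
            st.spine_density_test([5], [10.0], [1, 2], [10.0, 10.0])
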