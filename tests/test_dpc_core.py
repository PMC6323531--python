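import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foadpc as f
from foadpc import dpc_core
from conftest import make_hist
from dpc_oracle import oracle_dpc


hist_dicts = st.dictionaries(
    st.integers(0, 255), st.integers(1, 50), min_size=1, max_size=20
)


class TestChi:
    @pytest.mark.parametrize("x,expected", [(-1, 1), (0, 0), (3.5, 0), (-0.001, 1)])
    def test_indicator(self, x, expected):
        assert dpc_core.chi(x) == expected


class TestDensity:
    def test_worked_example(self, four_level_hist):
        levels, rho = dpc_core.compute_density(four_level_hist, 2)
        assert levels.tolist() == [10, 11, 50, 51]
        assert rho.tolist() == [8, 8, 10, 10]

    @settings(derandomize=True, max_examples=40)
    @given(hist_dicts)
    def test_dc_one_gives_counts(self, counts):
        # |g-g'| < 1 only at g'=g, so density reduces to the level count
        h = make_hist(counts)
        levels, rho = dpc_core.compute_density(h, 1.0)
        assert rho.tolist() == [counts[g] for g in sorted(counts)]

    def test_single_level(self):
        levels, rho = dpc_core.compute_density(make_hist({77: 100}), 7.3)
        assert levels.tolist() == [77] and rho.tolist() == [100]

    def test_dc_out_of_range(self, four_level_hist):
        with pytest.raises(ValueError):
            dpc_core.compute_density(four_level_hist, 0.5)

    @settings(derandomize=True, max_examples=30)
    @given(hist_dicts, st.floats(1, 10), st.floats(1, 10))
    def test_rho_monotone_in_dc(self, counts, a, b):
        h = make_hist(counts)
        lo, hi = sorted((a, b))
        _, rho_lo = dpc_core.compute_density(h, lo)
        _, rho_hi = dpc_core.compute_density(h, hi)
        assert (rho_hi >= rho_lo).all()


class TestDelta:
    def test_worked_example(self, four_level_hist):
        prof = dpc_core.build_profile(four_level_hist, 2)
        by_level = dict(zip(prof.levels.tolist(), prof.delta.tolist()))
        assert by_level == {51: 41, 50: 1, 10: 40, 11: 1}
        # rank order: 51, 50, 10, 11
        assert prof.levels[prof.rank_order].tolist() == [51, 50, 10, 11]

    def test_two_equal_levels_tie_breaks_to_lower_gray(self):
        prof = dpc_core.build_profile(make_hist({0: 1, 255: 1}), 2)
        assert prof.levels[prof.rank_order].tolist() == [0, 255]
        assert prof.delta.tolist() == [255, 255]

    def test_singleton_convention(self):
        prof = dpc_core.build_profile(make_hist({42: 9}), 5)
        assert prof.delta.tolist() == [1]
        assert prof.nn_higher.tolist() == [-1]


class TestGamma:
    def test_elementwise_product(self):
        got = dpc_core.compute_gamma(np.array([10, 10, 8, 8]),
                                     np.array([41, 1, 40, 1]))
        assert got.tolist() == [410, 10, 320, 8]

    def test_zero_delta(self):
        assert dpc_core.compute_gamma(np.array([5]), np.array([0])).tolist() == [0]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dpc_core.compute_gamma(np.array([1, 2]), np.array([1]))


class TestCentersAndLabels:
    def test_worked_example_centers(self, four_level_hist):
        model = dpc_core.fit(four_level_hist, f.DPCParams(2.0, 2))
        assert set(model.centers.tolist()) == {51, 10}
        assert model.level_label == {51: 0, 50: 0, 10: 1, 11: 1}

    def test_k_clamped_to_level_count(self, four_level_hist):
        model = dpc_core.fit(four_level_hist, f.DPCParams(2.0, 40))
        assert model.effective_k == 4
        # identity clustering: every level its own cluster
        assert len(set(model.level_label.values())) == 4

    def test_center_gamma_dominates(self, four_level_hist):
        model = dpc_core.fit(four_level_hist, f.DPCParams(2.0, 2))
        gamma = dict(zip(model.profile.levels.tolist(),
                         model.profile.gamma.tolist()))
        centers = set(model.centers.tolist())
        worst_center = min(gamma[g] for g in centers)
        best_rest = max((gamma[g] for g in gamma if g not in centers),
                        default=-1)
        assert worst_center >= best_rest

    def test_dominant_mode_still_two_clusters(self):
        # all levels within d_c of one dominant mode; k=2 still splits
        h = make_hist({100: 90, 101: 5, 102: 5})
        model = dpc_core.fit(h, f.DPCParams(5.0, 2))
        assert model.effective_k == 2
        assert len(set(model.level_label.values())) == 2


class TestOracleEquivalence:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(hist_dicts, st.floats(1, 10), st.integers(2, 40))
    def test_matches_bruteforce(self, counts, d_c, k):
        h = make_hist(counts)
        model = dpc_core.fit(h, f.DPCParams(d_c, k))
        rho, delta, gamma, centers, label = oracle_dpc(counts, d_c, k)
        prof = model.profile
        assert dict(zip(prof.levels.tolist(), prof.rho.tolist())) == rho
        assert dict(zip(prof.levels.tolist(), prof.delta.tolist())) == delta
        assert model.centers.tolist() == centers
        assert model.level_label == label


class TestDecisionGraph:
    def test_rows_sorted_by_gray(self, four_level_hist):
        table = dpc_core.decision_graph(dpc_core.build_profile(four_level_hist, 2))
        assert list(table.columns) == ["gray", "rho", "delta", "gamma"]
        assert table["gray"].tolist() == [10, 11, 50, 51]
        assert table["rho"].tolist() == [8, 8, 10, 10]

    def test_single_level_single_row(self):
        table = dpc_core.decision_graph(dpc_core.build_profile(make_hist({7: 3}), 1))
        assert len(table) == 1


class TestParams:
    @pytest.mark.parametrize("dc,k", [(0.9, 5), (10.1, 5), (5, 1), (5, 41),
                                      (float("nan"), 5), (5, 2.5)])
    def test_invalid(self, dc, k):
        with pytest.raises(ValueError):
            f.DPCParams(dc, k)
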