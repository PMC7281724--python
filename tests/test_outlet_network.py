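import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_manifold
from spiralsort.geometry import OutletChannel, OutletManifold
from spiralsort.outlet_network import (
    NetworkError,
    TuningError,
    assign_outlet,
    capture_windows,
    rectangular_resistance,
    solve_flow_split,
    tune_lengths,
)


def uniform_manifold(n=4, width=300.0, height=100.0, length=10.0):
    return OutletManifold(
        tuple(OutletChannel(i + 1, width, height, length) for i in range(n))
    )


def network_oracle(resistances, q):
    """Independent flow split: solve the full linear junction system."""
    n = len(resistances)
    a = np.zeros((n + 1, n + 1))
    b = np.zeros(n + 1)
    for i, r in enumerate(resistances):
        a[i, i] = r       # R_i q_i - p = 0  (shared junction pressure p)
        a[i, n] = -1.0
    a[n, :n] = 1.0        # sum of branch flows equals Q
    b[n] = q
    return np.linalg.solve(a, b)[:n]


class TestResistance:
    def test_closed_form_value(self):
        # 200x100 um duct, 5 mm long, water
        r = rectangular_resistance(200, 100, 5, 1e-3)
        assert r == pytest.approx(4.38e11, rel=2e-3)

    def test_proportional_to_length(self):
        r1 = rectangular_resistance(200, 100, 5, 1e-3)
        assert rectangular_resistance(200, 100, 10, 1e-3) == pytest.approx(2 * r1)

    def test_slit_limit(self):
        # w >= 100 h recovers 12 mu L / (w h^3) within 1%
        r = rectangular_resistance(10000, 100, 5, 1e-3)
        slit = 12 * 1e-3 * 5e-3 / (10000e-6 * (100e-6) ** 3)
        assert r == pytest.approx(slit, rel=0.01)

    def test_orientation_invariance_and_validation(self):
        assert rectangular_resistance(100, 200, 5, 1e-3) == rectangular_resistance(
            200, 100, 5, 1e-3
        )
        with pytest.raises(NetworkError):
            rectangular_resistance(0, 100, 5, 1e-3)


class TestFlowSplit:
    def test_identical_outlets_split_evenly(self):
        sol = solve_flow_split(uniform_manifold(), 1.8)
        assert sol.fractions == pytest.approx((0.25,) * 4)
        assert sum(sol.flows_ml_min) == pytest.approx(1.8, rel=1e-12)

    def test_two_branch_conductance_ratio(self):
        # R2 = 2 R1 via doubled length -> fractions (2/3, 1/3)
        m = OutletManifold(
            (OutletChannel(1, 300, 100, 5.0), OutletChannel(2, 300, 100, 10.0))
        )
        sol = solve_flow_split(m, 1.0)
        assert sol.fractions == pytest.approx((2 / 3, 1 / 3), rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_linear_network_oracle(self, seed):
        m = random_manifold(np.random.default_rng(seed))
        q = 1.8
        sol = solve_flow_split(m, q)
        expected = network_oracle(sol.resistances_pa_s_m3, q)
        assert np.allclose(sol.flows_ml_min, expected, rtol=1e-10, atol=1e-12)
        assert sum(sol.fractions) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_lengthening_a_branch_starves_it(self, seed):
        rng = np.random.default_rng(seed)
        m = random_manifold(rng)
        i = int(rng.integers(0, 4))
        base = solve_flow_split(m, 1.8).fractions[i]
        outlets = list(m.outlets)
        o = outlets[i]
        outlets[i] = OutletChannel(o.index, o.width_um, o.height_um, o.length_mm * 1.5)
        longer = solve_flow_split(OutletManifold(tuple(outlets)), 1.8).fractions[i]
        assert longer < base


class TestCaptureWindows:
    def test_equal_fractions_quarter_windows(self):
        w = capture_windows([0.25, 0.25, 0.25, 0.25])
        assert w == ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0))

    def test_cut_points_are_cumulative_sums(self):
        w = capture_windows([0.1, 0.2, 0.3, 0.4])
        assert [iv[1] for iv in w[:-1]] == pytest.approx([0.1, 0.3, 0.6])

    def test_windows_partition_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            f = rng.dirichlet(np.ones(4))
            w = capture_windows(f)
            assert w[0][0] == 0.0 and w[-1][1] == 1.0
            for (a, b), (c, d) in zip(w, w[1:]):
                assert b == c and a < b

    def test_assignment_boundaries(self):
        # binary-exact fractions so the cut points carry no rounding noise
        w = capture_windows([0.125, 0.375, 0.25, 0.25])
        assert assign_outlet(0.0, w) == 1
        assert assign_outlet(0.05, w) == 1
        assert assign_outlet(0.125, w) == 2    # half-open [lo, hi)
        assert assign_outlet(0.5, w) == 3
        assert assign_outlet(0.75, w) == 4
        assert assign_outlet(1.0, w) == 4      # last window closed
        with pytest.raises(NetworkError):
            assign_outlet(1.5, w)

    @given(st.floats(0, 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_every_position_has_exactly_one_outlet(self, x):
        w = capture_windows([0.1, 0.2, 0.3, 0.4])
        hits = [i + 1 for i, (a, b) in enumerate(w) if (a <= x < b) or (i == 3 and a <= x <= b)]
        assert hits == [assign_outlet(x, w)]


class TestTuneLengths:
    def test_equal_targets_equal_lengths(self):
        tuned = tune_lengths(uniform_manifold(length=7.0), [0.25] * 4)
        lengths = [o.length_mm for o in tuned.outlets]
        assert lengths == pytest.approx([lengths[0]] * 4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_round_trip_reproduces_targets(self, seed):
        rng = np.random.default_rng(seed)
        template = random_manifold(rng)
        target = rng.dirichlet(np.ones(4) * 2.0)
        target = np.clip(target, 0.01, None)
        target /= target.sum()
        tuned = tune_lengths(template, target)
        sol = solve_flow_split(tuned, 1.8)
        assert np.allclose(sol.fractions, target, atol=1e-6)
        # only lengths changed
        for a, b in zip(template.outlets, tuned.outlets):
            assert (a.width_um, a.height_um) == (b.width_um, b.height_um)

    def test_halving_a_fraction_doubles_its_length(self):
        # with total conductance held fixed the closed form is exact
        t1 = tune_lengths(uniform_manifold(), [0.4, 0.2, 0.2, 0.2])
        t2 = tune_lengths(uniform_manifold(), [0.2, 0.4, 0.2, 0.2])
        assert t2.outlets[0].length_mm == pytest.approx(2 * t1.outlets[0].length_mm)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(TuningError):
            tune_lengths(uniform_manifold(), [0.0, 0.5, 0.25, 0.25])
        with pytest.raises(TuningError):
            tune_lengths(uniform_manifold(), [0.5, 0.5])
        with pytest.raises(TuningError):
            tune_lengths(uniform_manifold(), [0.5, 0.3, 0.1, 0.2])
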