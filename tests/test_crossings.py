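"""Plane-crossing detection, Q(t) bookkeeping and the window estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import poreflux as pf
from poreflux.errors import ContractError, WindowUnreachableError

from conftest import make_scripted_trajectory


def brute_force_crossings(z_wrapped, plane, lz):
    """Independent oracle: unwrap the path, count signed plane crossings.

    Unwraps via minimum-image steps, then for every consecutive pair counts
    the plane images (plane + m L for every integer m) inside the traveled
    segment, with the (z0 < p <= z1] / [z1 <= p < z0) convention.
    """
    z = np.asarray(z_wrapped, dtype=float)
    unwrapped = [z[0]]
    for a, b in zip(z[:-1], z[1:]):
        d = b - a
        d -= lz * round(d / lz)
        unwrapped.append(unwrapped[-1] + d)
    total, events = 0, 0
    for a, b in zip(unwrapped[:-1], unwrapped[1:]):
        lo, hi = min(a, b), max(a, b)
        m_lo = math.floor((lo - plane) / lz) - 1
        m_hi = math.ceil((hi - plane) / lz) + 1
        for m in range(m_lo, m_hi + 1):
            p = plane + m * lz
            if (a < p <= b):
                total += 1
                events += 1
            elif (b <= p < a):
                total -= 1
                events += 1
    return total, events


def detector_results(z_paths, plane, lz):
    traj = make_scripted_trajectory(z_paths, box_z=lz)
    recs = pf.detect_crossings(traj, plane)
    by_particle = {}
    for r in recs:
        t, e = by_particle.get(r.particle_id, (0, 0))
        by_particle[r.particle_id] = (t + r.direction, e + 1)
    return by_particle


class TestDetectCrossings:
    def test_single_monotone_crossing(self):
        res = detector_results([[2.0, 7.0]], plane=5.0, lz=10.0)
        assert res == {0: (1, 1)}

    def test_zigzag_counts_every_straddle(self):
        path = [4.0, 6.0, 4.5, 5.5, 4.8, 6.2, 4.9]
        res = detector_results([path], plane=5.0, lz=10.0)
        net, n_events = brute_force_crossings(path, 5.0, 10.0)
        assert res[0] == (net, n_events)
        assert n_events == 6

    def test_periodic_wrap_far_from_plane_is_not_an_event(self):
        # wrap 9.8 -> 0.3 crosses z=0/10, not the plane at 5
        res = detector_results([[9.8, 0.3, 9.7]], plane=5.0, lz=10.0)
        assert res == {}

    def test_crossing_carried_through_the_boundary_is_counted(self):
        # plane near the boundary: 9.9 -> 0.4 passes the plane image at 10.1
        res = detector_results([[9.9, 0.4]], plane=0.1, lz=10.0)
        assert res == {0: (1, 1)}

    def test_plane_outside_box_rejected(self):
        traj = make_scripted_trajectory([[1.0, 2.0]])
        with pytest.raises(ContractError):
            pf.detect_crossings(traj, 11.0)

    def test_species_filter(self):
        species = (pf.IonSpecies("K+", +1, 2.54, 1),
                   pf.IonSpecies("CL-", -1, 2.45, 1))
        traj = make_scripted_trajectory([[2.0, 7.0], [2.0, 7.0]],
                                        species=species,
                                        species_index=[0, 1])
        recs = pf.detect_crossings(traj, 5.0, species_filter=["CL-"])
        assert [r.species for r in recs] == ["CL-"]

    def test_matches_brute_force_on_randomized_walks(self):
        # randomized wrapped walks with wraps; detector must agree exactly
        lz, plane = 10.0, 6.4
        rng = np.random.default_rng(2024)
        n_paths, n_steps = 400, 40
        steps = rng.uniform(-4.9, 4.9, size=(n_paths, n_steps))
        z = np.cumsum(np.concatenate(
            [rng.uniform(0, lz, size=(n_paths, 1)), steps], axis=1), axis=1)
        wrapped = z % lz
        res = detector_results(wrapped, plane, lz)
        for i in range(n_paths):
            expected = brute_force_crossings(wrapped[i], plane, lz)
            assert res.get(i, (0, 0)) == expected


class TestCumulativeCharge:
    CHARGES = {"K+": 1, "CL-": -1}

    @pytest.mark.parametrize("n_c, n_a, q", [
        (45, -108, 153),
        (-21, 103, -124),
        (144, -228, 372),
    ])
    def test_total_charge_bookkeeping(self, n_c, n_a, q):
        """Q = e (N_c - N_a) for signed net crossing counts."""
        recs = []
        t = 0.0
        for _ in range(abs(n_c)):
            t += 0.1
            recs.append(pf.CrossingRecord(t, 0, "K+", int(np.sign(n_c))))
        for _ in range(abs(n_a)):
            t += 0.1
            recs.append(pf.CrossingRecord(t, 1, "CL-", int(np.sign(n_a))))
        trace = pf.cumulative_charge(recs, np.array([t + 1.0]), self.CHARGES)
        assert int(trace.Q[-1]) == q

    def test_no_events_zero_charge(self):
        trace = pf.cumulative_charge([], np.linspace(0, 1, 5), self.CHARGES)
        assert not trace.Q.any()

    def test_unsorted_records_rejected(self):
        recs = [pf.CrossingRecord(0.2, 0, "K+", 1),
                pf.CrossingRecord(0.1, 0, "K+", 1)]
        with pytest.raises(ContractError):
            pf.cumulative_charge(recs, np.array([1.0]), self.CHARGES)

    @given(st.lists(st.tuples(st.sampled_from(["K+", "CL-"]),
                              st.sampled_from([-1, 1])), max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_integer_exactness_and_identity(self, events):
        recs = [pf.CrossingRecord(0.1 * (i + 1), i, sp, d)
                for i, (sp, d) in enumerate(events)]
        grid = np.arange(1, 8, dtype=float)
        trace = pf.cumulative_charge(recs, grid, self.CHARGES)
        assert trace.Q.dtype == np.int64
        np.testing.assert_array_equal(trace.Q, trace.N_c - trace.N_a)


def poisson_trace(rate, n_events, rng, species="K+"):
    gaps = rng.exponential(1.0 / rate, size=n_events)
    times = np.cumsum(gaps)
    recs = [pf.CrossingRecord(float(t), 0, species, 1) for t in times]
    return pf.cumulative_charge(recs, times, {"K+": 1, "CL-": -1})


class TestWindowEstimator:
    def test_periodic_events_have_exact_rate_and_zero_sigma(self):
        tau0 = 0.25
        times = tau0 * np.arange(1, 101)
        recs = [pf.CrossingRecord(float(t), 0, "K+", 1) for t in times]
        trace = pf.cumulative_charge(recs, times, {"K+": 1})
        w = pf.window_average_current(trace, q_ini=5, delta_Q=40)
        assert w.sigma == 0.0
        assert w.delta_I == 0.0
        assert w.I_bar == pytest.approx(pf.unit_current(1.0 / tau0), rel=1e-12)
        assert w.t_ini == pytest.approx(5 * tau0)
        assert w.t_end == pytest.approx(45 * tau0)

    def test_poisson_rate_recovered_within_sampling_bounds(self, rng):
        lam = 2.0
        trace = poisson_trace(lam, 200, rng)
        w = pf.window_average_current(trace, q_ini=5, delta_Q=40)
        rate = w.I_bar / pf.unit_current(1.0)
        assert rate == pytest.approx(lam, abs=3 * lam / np.sqrt(40))

    def test_window_unreachable_reports_achieved_charge(self):
        recs = [pf.CrossingRecord(0.1 * (i + 1), 0, "K+", 1)
                for i in range(30)]
        trace = pf.cumulative_charge(recs, np.array([r.time for r in recs]),
                                     {"K+": 1})
        with pytest.raises(WindowUnreachableError, match="30"):
            pf.window_average_current(trace, q_ini=5, delta_Q=40)

    def test_negative_transport_sign_restored(self, rng):
        gaps = rng.exponential(0.5, size=100)
        times = np.cumsum(gaps)
        recs = [pf.CrossingRecord(float(t), 0, "CL-", 1) for t in times]
        trace = pf.cumulative_charge(recs, times, {"CL-": -1})
        assert int(trace.Q[-1]) == -100
        w = pf.window_average_current(trace)
        assert w.I_bar < 0

    def test_successive_windows_strides(self, rng):
        trace = poisson_trace(2.0, 300, rng)
        wins = pf.successive_windows(trace, q_ini=5, delta_Q=40, stride=190)
        assert [w.q_ini for w in wins] == [5, 195]
        assert all(w.delta_Q == 40 for w in wins)
        single = pf.successive_windows(trace, q_ini=5, delta_Q=40, stride=10 ** 6)
        assert len(single) == 1

    def test_constant_rate_gives_equal_window_currents(self):
        times = 0.2 * np.arange(1, 301)
        recs = [pf.CrossingRecord(float(t), 0, "K+", 1) for t in times]
        trace = pf.cumulative_charge(recs, times, {"K+": 1})
        wins = pf.successive_windows(trace, stride=40)
        currents = {round(w.I_bar, 6) for w in wins}
        assert len(currents) == 1


class TestIVAssembly:
    def _win(self, i_bar, q_ini=5):
        return pf.WindowEstimate(q_ini=q_ini, delta_Q=40, t_ini=1.0,
                                 t_end=2.0, I_bar=i_bar, sigma=0.1,
                                 delta_I=1.0, n_events=40)

    def test_single_run_single_point(self):
        pts = pf.assemble_iv({"r1": [self._win(10.0)]}, {"r1": 100.0})
        assert len(pts) == 1 and pts[0].bias == 100.0

    def test_sorted_independent_of_input_order(self):
        runs = {"a": [self._win(1.0)], "b": [self._win(2.0)],
                "c": [self._win(3.0)]}
        biases = {"a": 300.0, "b": -100.0, "c": 0.0}
        fwd = pf.assemble_iv(runs, biases)
        rev = pf.assemble_iv(dict(reversed(runs.items())), biases)
        assert [p.bias for p in fwd] == [-100.0, 0.0, 300.0]
        assert fwd == rev

    def test_duplicate_window_rejected(self):
        with pytest.raises(ContractError):
            pf.assemble_iv({"r": [self._win(1.0), self._win(2.0)]},
                           {"r": 50.0})

    def test_linear_response_slope_recovered(self, rng):
        # synthetic runs with I proportional to bias recover the conductance
        g = 0.05  # e/ns per mV
        runs, biases = {}, {}
        for k, bias in enumerate((50.0, 100.0, 150.0, 200.0)):
            trace = poisson_trace(g * bias, 300, rng)
            runs[f"r{k}"] = pf.successive_windows(trace, stride=40)
            biases[f"r{k}"] = bias
        pts = pf.assemble_iv(runs, biases)
        slopes = [p.I_bar / pf.unit_current(1.0) / p.bias for p in pts]
        assert np.mean(slopes) == pytest.approx(g, rel=0.1)


class TestReferenceCurrent:
    def test_ohms_law_positive(self):
        ref = pf.reference_current(370.0)
        assert ref.i_ref == pytest.approx(370.0)
        assert ref.comparison == pytest.approx(37.0)

    def test_rectified_negative_branch(self):
        assert pf.reference_current(-370.0).i_ref == pytest.approx(-259.0)

    def test_zero_bias(self):
        assert pf.reference_current(0.0).i_ref == 0.0


class TestNeutralization:
    @pytest.mark.parametrize("pairs, q, expected", [
        (2054, +7, (2050, 2057)),
        (100, 0, (100, 100)),
        (100, +2, (99, 101)),
        (100, -3, (102, 99)),
    ])
    def test_split_rule(self, pairs, q, expected):
        assert pf.neutralize_ion_counts(pairs, q) == expected

    @given(st.integers(0, 10 ** 6), st.integers(-100, 100))
    @settings(max_examples=100, deadline=None)
    def test_neutrality_and_minimal_change(self, pairs, q):
        if pairs < abs(q):
            with pytest.raises(ContractError):
                pf.neutralize_ion_counts(pairs, q)
            return
        n_cat, n_an = pf.neutralize_ion_counts(pairs, q)
        assert n_an - n_cat == q
        assert abs((n_cat + n_an) - 2 * pairs) <= 1

    def test_infeasible_rejected(self):
        with pytest.raises(ContractError):
            pf.neutralize_ion_counts(3, +8)
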