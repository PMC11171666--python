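"""Force-curve segmentation, spring-energy extraction, plateau detection."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pistack.analysis import (
    binding_energy,
    detect_plateaus,
    detect_transitions,
    eq2_energy,
    pulling_work,
    results_table,
)
from pistack.smd import ForceCurve
from pistack.units import PN_PER_KCAL_MOL_A

K_PN = 278.0


def make_curve(force, com=None, dt=1.0):
    force = np.asarray(force, dtype=float)
    t = np.arange(len(force)) * dt
    if com is None:
        com = np.full(len(force), 4.0)
    return ForceCurve(t, force, np.zeros(len(force)), np.asarray(com, dtype=float))


class TestSpringEnergy:
    def test_unit_stretch_equals_half_k(self):
        """F0=0, dF=278 at k=278 is (1/2) k x^2 with x = 1 A."""
        assert eq2_energy(0.0, 278.0, 278.0) == pytest.approx(2.001, abs=2e-3)

    def test_worked_example(self):
        assert eq2_energy(100.0, 200.0, 278.0) == pytest.approx(2.071, abs=2e-3)

    def test_no_force_change_no_energy(self):
        assert eq2_energy(500.0, 0.0, 278.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eq2_energy(0.0, 10.0, 0.0)
        with pytest.raises(ValueError):
            eq2_energy(0.0, -5.0, 278.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        f0=st.floats(-500.0, 500.0),
        df=st.floats(0.0, 1000.0),
        k=st.floats(1.0, 1000.0),
    )
    def test_matches_spring_closed_form(self, f0, df, k):
        """(F0 + dF/2) dF / k == ((F0+dF)^2 - F0^2) / (2k), always."""
        closed = ((f0 + df) ** 2 - f0**2) / (2.0 * k) / PN_PER_KCAL_MOL_A
        assert eq2_energy(f0, df, k) == pytest.approx(closed, rel=1e-12, abs=1e-15)


class TestTransitionDetection:
    def test_sawtooth_two_transitions(self):
        curve = make_curve([0.0, 300.0, 50.0, 300.0, 0.0])
        trs = detect_transitions(curve, smooth_ps=0.0)
        assert len(trs) == 2
        assert trs[0].dF == pytest.approx(300.0)
        assert trs[1].dF == pytest.approx(250.0)
        assert trs[0].F_start == pytest.approx(0.0)
        assert trs[1].F_start == pytest.approx(50.0)

    def test_far_peak_discarded_by_com_rule(self):
        """A peak at COM >= 10 A cannot be a stacking interaction."""
        com = [4.0, 4.0, 4.0, 11.0, 11.0]
        curve = make_curve([0.0, 300.0, 50.0, 300.0, 0.0], com=com)
        trs = detect_transitions(curve, smooth_ps=0.0)
        assert len(trs) == 1
        assert trs[0].dF == pytest.approx(300.0)

    def test_flat_curve_yields_nothing(self):
        assert detect_transitions(make_curve(np.zeros(50)), smooth_ps=0.0) == []

    def test_small_wiggles_below_min_drop_ignored(self):
        curve = make_curve([0.0, 5.0, 1.0, 6.0, 2.0, 7.0, 3.0])
        assert detect_transitions(curve, smooth_ps=0.0, min_drop_pN=10.0) == []

    def test_empty_curve_is_an_error(self):
        empty = ForceCurve(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            detect_transitions(empty)

    def test_sawtooth_energy_equals_pull_work(self):
        """For an ideal quasi-static sawtooth, summed spring releases equal
        the work integral of the dummy exactly."""
        k, v = K_PN, 1.0
        # dummy-displacement breakpoints: ramps at slope k, instantaneous drops
        xs, fs = [0.0], [0.0]
        for peak, valley in [(300.0, 50.0), (300.0, 0.0)]:
            xs.append(xs[-1] + (peak - fs[-1]) / k)
            fs.append(peak)
            xs.append(xs[-1] + 1e-9)
            fs.append(valley)
        times = np.array(xs) / v
        curve = ForceCurve(times, np.array(fs), np.array(xs), np.full(len(xs), 4.0))
        trs = detect_transitions(curve, smooth_ps=0.0)
        total = sum(eq2_energy(tr.F_start, tr.dF, k) for tr in trs)
        assert total == pytest.approx(pulling_work(curve, v), rel=1e-6)


class TestBindingEnergyAggregation:
    def test_single_curve_sd_zero_with_warning(self):
        curve = make_curve([0.0, 278.0, 0.0])
        with pytest.warns(UserWarning, match="single replica"):
            res = binding_energy([curve], K_PN, smooth_ps=0.0)
        assert res.mean == pytest.approx(2.001, abs=2e-3)
        assert res.sd == 0.0

    def test_identical_replicas_have_zero_sd(self):
        curve = make_curve([0.0, 150.0, 20.0, 250.0, 0.0])
        res = binding_energy([curve] * 4, K_PN, smooth_ps=0.0)
        assert res.n_replicas == 4
        assert res.sd == 0.0
        assert res.mean == pytest.approx(res.replica_totals[0])

    def test_transitionless_replica_contributes_zero(self):
        good = make_curve([0.0, 278.0, 0.0])
        flat = make_curve(np.zeros(3))
        with pytest.warns(UserWarning, match="no retained transitions"):
            res = binding_energy([good, flat], K_PN, smooth_ps=0.0)
        assert res.replica_totals[1] == 0.0

    def test_results_table_shape(self):
        curve = make_curve([0.0, 278.0, 0.0])
        res = binding_energy([curve] * 2, K_PN, smooth_ps=0.0)
        df = results_table({"anthracene": res})
        assert df.loc[0, "system"] == "anthracene"
        assert df.loc[0, "n_replicas"] == 2


def synthetic_trace(seed, n=500, dt=10.0, dwell_min=300.0):
    """A free-diffusion COM trace with known injected bound intervals."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    d = 15.0 + rng.normal(0.0, 1.0, n)
    intervals = []
    pos = rng.integers(20, 80)
    for _ in range(rng.integers(1, 3)):
        length = int(rng.integers(int(dwell_min / dt), int(3 * dwell_min / dt)))
        if pos + length > n - 20:
            break
        d[pos : pos + length] = 4.5 + rng.normal(0.0, 0.2, length)
        intervals.append((t[pos], t[pos + length - 1]))
        pos += length + int(rng.integers(30, 100))
    return t, d, intervals


class TestPlateauDetection:
    def test_single_injected_plateau_recovered(self):
        rng = np.random.default_rng(0)
        t = np.arange(500) * 10.0
        d = 15.0 + rng.normal(0, 1.0, 500)
        d[200:350] = 4.5 + rng.normal(0, 0.2, 150)
        plats = detect_plateaus(t, d, dist_threshold=6.0, dwell=100.0, var_tol=1.5)
        assert len(plats) == 1
        p = plats[0]
        assert abs(p.t_start - 2000.0) <= 300.0 and abs(p.t_end - 3490.0) <= 300.0
        assert p.mean_distance < 6.0

    def test_two_separated_plateaus(self):
        rng = np.random.default_rng(1)
        t = np.arange(600) * 10.0
        d = 18.0 + rng.normal(0, 1.0, 600)
        d[100:220] = 4.5 + rng.normal(0, 0.2, 120)
        d[400:520] = 4.8 + rng.normal(0, 0.2, 120)
        plats = detect_plateaus(t, d, dist_threshold=6.0, dwell=100.0, var_tol=1.5)
        assert len(plats) == 2

    def test_pure_diffusion_no_plateau(self):
        rng = np.random.default_rng(2)
        t = np.arange(400) * 10.0
        d = 15.0 + rng.normal(0, 1.5, 400)
        assert detect_plateaus(t, d, dist_threshold=6.0, dwell=100.0) == []

    def test_dwell_longer_than_trace_warns_empty(self):
        t = np.arange(10) * 10.0
        d = np.full(10, 4.0)
        with pytest.warns(UserWarning, match="dwell"):
            assert detect_plateaus(t, d, dwell=1000.0) == []

    def test_recovery_rate_on_seeded_traces(self):
        """>= 95% of injected bound intervals recovered, zero false hits,
        across 100 seeded synthetic traces."""
        injected = recovered = false_hits = 0
        for seed in range(100):
            t, d, truth = synthetic_trace(seed)
            plats = detect_plateaus(t, d, dist_threshold=6.0, dwell=100.0, var_tol=1.5)
            injected += len(truth)
            used = set()
            for lo, hi in truth:
                for i, p in enumerate(plats):
                    overlap = min(hi, p.t_end) - max(lo, p.t_start)
                    if overlap > 0.5 * (hi - lo):
                        recovered += 1
                        used.add(i)
                        break
            false_hits += len([p for i, p in enumerate(plats) if i not in used])
        assert injected > 50
        assert recovered >= 0.95 * injected
        assert false_hits == 0
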