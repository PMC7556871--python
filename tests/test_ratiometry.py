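"""Biosensor ratio traces and the per-phase charge statistic."""

import numpy as np
import pytest

from saltadyn.phases import Phase, PhaseSegmentation, PhaseState
from saltadyn.ratiometry import (
    RatioTrace,
    compute_ratio_trace,
    condition_ratio_summary,
    percent_normalize,
    phase_charge,
    stationary_baseline,
)
from saltadyn.synthio import (
    EnergyModelParams,
    render_energy_stacks,
    simulate_energy_trace,
)

MIG, STAT = PhaseState.MIG, PhaseState.STAT


def _seg(phases, cell_id="cell-0"):
    return PhaseSegmentation(
        cell_id=cell_id, phases=[Phase(s, a, b) for s, a, b in phases]
    )


class TestComputeRatioTrace:
    def test_uniform_channels_exact_ratio(self):
        num = np.full((5, 8, 8), 2000.0)
        den = np.full((5, 8, 8), 1000.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        trace = compute_ratio_trace(num, den, mask, den_floor=0.0)
        assert np.all(trace.valid)
        np.testing.assert_array_equal(trace.r, 2.0)

    def test_z_max_projection(self):
        # per-wavelength z max-projection happens before the masked mean
        num = np.zeros((2, 3, 4, 4))
        num[:, 1] = 600.0  # brightest z-plane
        den = np.zeros((2, 3, 4, 4))
        den[:, 2] = 300.0
        mask = np.ones((4, 4), dtype=bool)
        trace = compute_ratio_trace(num, den, mask, den_floor=0.0)
        np.testing.assert_allclose(trace.r, 2.0)

    def test_denominator_floor_flags_frame(self):
        num = np.full((3, 4, 4), 100.0)
        den = np.full((3, 4, 4), 50.0)
        den[1] = 0.5  # below floor on the middle frame only
        mask = np.ones((4, 4), dtype=bool)
        trace = compute_ratio_trace(num, den, mask, den_floor=1.0)
        assert trace.valid.tolist() == [True, False, True]
        np.testing.assert_allclose(trace.r[[0, 2]], 2.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            compute_ratio_trace(
                np.zeros((2, 4, 4)), np.zeros((3, 4, 4)), np.ones((4, 4), bool)
            )

    def test_round_trip_with_generator(self):
        # rendered noiseless channels reproduce the clean model ratio
        labels = np.array(["MIG"] * 40 + ["STAT"] * 40, dtype=object)
        params = EnergyModelParams(noise_sd=0.0)
        num, den, truth = simulate_energy_trace(labels, 30.0, params)
        s_num, s_den, mask = render_energy_stacks(num, den)
        trace = compute_ratio_trace(s_num, s_den, mask, den_floor=0.0)
        np.testing.assert_allclose(
            trace.r, truth.energy_trace_clean, atol=1e-9
        )


class TestStationaryBaseline:
    def test_constant_trace(self):
        t = np.arange(0.0, 300.0, 30.0)
        trace = RatioTrace("cell-0", t=t, r=np.full(t.size, 1.5))
        seg = _seg([(STAT, 0.0, 150.0), (MIG, 150.0, 270.0)])
        assert stationary_baseline(trace, seg) == pytest.approx(1.5)

    def test_only_stationary_frames_used(self):
        t = np.array([0.0, 30.0, 60.0, 90.0])
        r = np.array([1.0, 2.0, 7.0, 9.0])  # MIG frames arbitrary
        trace = RatioTrace("cell-0", t=t, r=r)
        seg = _seg([(STAT, 0.0, 45.0), (MIG, 45.0, 90.0)])
        assert stationary_baseline(trace, seg) == pytest.approx(1.5)

    def test_no_stationary_phase_errors(self):
        t = np.array([0.0, 30.0])
        trace = RatioTrace("cell-0", t=t, r=np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="stationary"):
            stationary_baseline(trace, _seg([(MIG, 0.0, 30.0)]))

    def test_matches_brute_force_masked_mean(self):
        rng = np.random.default_rng(12)
        t = np.arange(0.0, 3600.0, 30.0)
        r = 1.5 + 0.1 * rng.standard_normal(t.size)
        trace = RatioTrace("cell-0", t=t, r=r)
        seg = _seg(
            [(STAT, 0.0, 900.0), (MIG, 900.0, 2100.0), (STAT, 2100.0, 3570.0)]
        )
        manual = r[(t < 900.0) | (t >= 2100.0)].mean()
        assert stationary_baseline(trace, seg) == pytest.approx(manual, abs=1e-12)


class TestPhaseCharge:
    def test_flat_at_baseline_is_zero(self):
        t = np.arange(0.0, 600.0, 30.0)
        trace = RatioTrace("cell-0", t=t, r=np.full(t.size, 1.4))
        seg = _seg([(STAT, 0.0, 300.0), (MIG, 300.0, 570.0)])
        res = phase_charge(trace, seg, baseline=1.4)
        assert all(p.charge == pytest.approx(0.0) for p in res.phases)

    def test_constant_offset(self):
        t = np.arange(0.0, 600.0, 30.0)
        trace = RatioTrace("cell-0", t=t, r=np.full(t.size, 1.3))
        seg = _seg([(STAT, 0.0, 570.0)])
        res = phase_charge(trace, seg, baseline=1.4)
        assert res.phases[0].charge == pytest.approx(-0.1, abs=1e-12)

    def test_triangular_dip(self):
        # symmetric triangular dip of depth 0.2 spanning the phase: mean -0.1
        t = np.array([0.0, 50.0, 100.0])
        r = np.array([1.0, 0.8, 1.0])
        trace = RatioTrace("cell-0", t=t, r=r)
        seg = _seg([(MIG, 0.0, 100.0)])
        res = phase_charge(trace, seg, baseline=1.0)
        assert res.phases[0].charge == pytest.approx(-0.1, abs=1e-12)

    def test_linearity_and_shift_invariance(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 1200.0, 30.0)
        r = 1.5 + 0.2 * rng.standard_normal(t.size)
        seg = _seg([(STAT, 0.0, 600.0), (MIG, 600.0, 1170.0)])
        base = float(r[t < 600.0].mean())
        charges = [p.charge for p in
                   phase_charge(RatioTrace("cell-0", t=t, r=r), seg, base).phases]
        # scaling (r - baseline) by c scales charges by c
        c = 3.7
        r_scaled = base + c * (r - base)
        scaled = [p.charge for p in
                  phase_charge(RatioTrace("cell-0", t=t, r=r_scaled), seg,
                               base).phases]
        np.testing.assert_allclose(scaled, np.array(charges) * c, atol=1e-12)
        # adding a constant shifts the baseline equally; charges unchanged
        shifted = [p.charge for p in
                   phase_charge(RatioTrace("cell-0", t=t, r=r + 0.9), seg,
                                base + 0.9).phases]
        np.testing.assert_allclose(shifted, charges, atol=1e-12)

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(5)
        t_s = np.arange(0.0, 1800.0, 30.0)
        r = 1.5 + 0.1 * rng.standard_normal(t_s.size)
        seg_s = _seg([(STAT, 0.0, 900.0), (MIG, 900.0, 1770.0)])
        seg_min = _seg([(STAT, 0.0, 15.0), (MIG, 15.0, 29.5)])
        c_s = phase_charge(RatioTrace("cell-0", t=t_s, r=r), seg_s, 1.5)
        c_min = phase_charge(
            RatioTrace("cell-0", t=t_s / 60.0, r=r), seg_min, 1.5
        )
        for a, b in zip(c_s.phases, c_min.phases):
            assert a.charge == pytest.approx(b.charge, abs=1e-12)

    def test_duration_weighted_sum_equals_total_auc(self):
        rng = np.random.default_rng(8)
        t = np.arange(0.0, 3600.0, 30.0)
        r = 1.5 + 0.15 * rng.standard_normal(t.size)
        seg = _seg(
            [
                (STAT, 0.0, 600.0),
                (MIG, 600.0, 1500.0),
                (STAT, 1500.0, 2400.0),
                (MIG, 2400.0, 3570.0),
            ]
        )
        base = 1.5
        res = phase_charge(RatioTrace("cell-0", t=t, r=r), seg, base)
        weighted = sum(
            p.charge * (p.t_end - p.t_start) for p in res.phases
        )
        total = np.trapezoid(r - base, t)
        assert weighted == pytest.approx(float(total), abs=1e-9)

    def test_sub_frame_phase_flagged(self):
        t = np.arange(0.0, 600.0, 30.0)
        trace = RatioTrace("cell-0", t=t, r=np.full(t.size, 1.5))
        seg = _seg([(STAT, 0.0, 570.0)])
        seg.phases = [
            Phase(STAT, 0.0, 10.0), Phase(MIG, 10.0, 570.0)
        ]  # 10 s < one 30 s frame
        res = phase_charge(trace, seg, 1.5)
        assert res.phases[0].flagged and res.phases[0].charge is None
        assert not res.phases[1].flagged


class TestPercentNormalize:
    def test_constant_trace_all_100(self):
        trace = RatioTrace("c", t=[0, 30, 60], r=[1.2, 1.2, 1.2])
        np.testing.assert_allclose(percent_normalize(trace), 100.0)

    def test_simple_values(self):
        trace = RatioTrace("c", t=[0, 30, 60], r=[1.0, 2.0, 4.0])
        np.testing.assert_allclose(percent_normalize(trace), [25.0, 50.0, 100.0])

    def test_max_exactly_100_order_preserved(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(0.5, 3.0, 50)
        trace = RatioTrace("c", t=np.arange(50.0), r=r)
        pct = percent_normalize(trace)
        assert pct.max() == 100.0
        np.testing.assert_array_equal(np.argsort(pct), np.argsort(r))


class TestConditionSummary:
    def _trace(self, value, cell_id):
        return RatioTrace(cell_id, t=[0.0, 30.0], r=[value, value])

    def test_single_condition(self):
        df = condition_ratio_summary(
            {"DMSO": [self._trace(2.0, "a"), self._trace(2.0, "b")]}
        )
        assert df.loc[0, "mean_ratio"] == pytest.approx(2.0)
        assert df.loc[0, "sem"] == pytest.approx(0.0)
        assert df.loc[0, "n"] == 2

    def test_empty_condition_warns_and_is_omitted(self):
        with pytest.warns(UserWarning, match="rotenone"):
            df = condition_ratio_summary(
                {"DMSO": [self._trace(2.0, "a")], "rotenone": []}
            )
        assert df["condition"].tolist() == ["DMSO"]

    def test_programmed_dose_response_recovered(self):
        # decreasing true ratio across doses -> strictly decreasing means
        doses = {"0": 2.0, "1": 1.7, "10": 1.4, "20": 1.1}
        groups = {
            d: [self._trace(v + 0.01 * i, f"{d}-{i}") for i in range(3)]
            for d, v in doses.items()
        }
        df = condition_ratio_summary(groups)
        means = df["mean_ratio"].to_numpy()
        assert np.all(np.diff(means) < 0)
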