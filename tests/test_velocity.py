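"""HRM / Tmax estimators and the Dual Method Approach selection rule."""

import math

import numpy as np
import pytest

import heatpulse as hp
from conftest import K_DEFAULT, make_medium


def _estimate(v_h, t0, geometry, noise=None, k=K_DEFAULT):
    noise = noise or hp.NOISELESS
    m = make_medium(v_h=v_h, t0=t0, k=k)
    rec = hp.generate_pulse_record(geometry, m, noise)
    s = hp.summarize_pulse(rec)[0]
    return hp.dma_select(s, geometry, k, t0)


class TestHrmVelocity:
    def test_zero_ratio_zero_flow(self):
        assert hp.hrm_velocity(0.0, K_DEFAULT, 0.5) == 0.0

    def test_hand_evaluated(self):
        # (k/x) * 2 = 0.01 cm/s = 36 cm/hr
        assert hp.hrm_velocity(2.0, K_DEFAULT, 0.5) == pytest.approx(36.0)

    @pytest.mark.parametrize("v", [-20.0, -5.0, 0.0, 5.0, 20.0])
    def test_end_to_end_low_and_reverse_flow(self, v, single_depth_geometry):
        est = _estimate(v, 0.0, single_depth_geometry)
        assert est.v_hrm == pytest.approx(v, abs=0.1)


class TestHrmVelocityAsym:
    def test_reduces_to_symmetric_form(self):
        for lr in (-1.0, 0.0, 0.7, 2.0):
            for t in (60.0, 80.0, 100.0):
                assert hp.hrm_velocity_asym(
                    lr, K_DEFAULT, 0.5, 0.5, t, 2.0
                ) == pytest.approx(hp.hrm_velocity(lr, K_DEFAULT, 0.5))

    def test_spacing_correction_term_isolated(self):
        # ln_ratio = 0: only the (x_d - x_u)/(2 (t - t0/2)) term remains
        v = hp.hrm_velocity_asym(0.0, K_DEFAULT, 0.6, 0.5, 80.0, 2.0)
        assert v == pytest.approx(0.1 / (2 * 79.0) * 3600.0)

    def test_recovers_velocity_on_asymmetric_geometry(self):
        # per-sample evaluation on a noiseless instantaneous-pulse trace
        x_d, x_u, v_true = 0.6, 0.5, 20.0
        m = make_medium(v_h=v_true, t0=0.0)
        for t in np.arange(60.0, 100.5, 10.0):
            lr = float(
                np.log(
                    hp.instantaneous_pulse_dT(x_d, t, m)
                    / hp.instantaneous_pulse_dT(-x_u, t, m)
                )
            )
            v_est = hp.hrm_velocity_asym(lr, K_DEFAULT, x_d, x_u, float(t), 0.0)
            assert v_est == pytest.approx(v_true, rel=2e-3)

    def test_time_domain(self):
        with pytest.raises(hp.DomainError):
            hp.hrm_velocity_asym(1.0, K_DEFAULT, 0.5, 0.5, 1.0, 2.0)


class TestTmaxVelocity:
    def test_zero_at_radicand_boundary(self):
        tm = 0.25 / (4 * K_DEFAULT)  # x^2/(4k) = 25 s
        assert hp.tmax_velocity(tm, K_DEFAULT, 0.5) == 0.0

    def test_inverse_of_peak_time_quadratic(self):
        # closed-form round trip: v -> t_m -> v
        assert hp.tmax_velocity(20.71067811865475, K_DEFAULT, 0.5) == pytest.approx(
            36.0, rel=1e-9
        )

    def test_below_resolution_raises(self):
        with pytest.raises(hp.BelowTmaxResolutionError):
            hp.tmax_velocity(30.0, K_DEFAULT, 0.5)


class TestTmaxVelocityCorrected:
    def test_degenerate_pulse_limit(self):
        tm = 15.0
        v0 = hp.tmax_velocity(tm, K_DEFAULT, 0.5)
        v_eps = hp.tmax_velocity_corrected(tm, K_DEFAULT, 0.5, 1e-9)
        assert v_eps == pytest.approx(v0, rel=1e-6)

    def test_exact_on_true_finite_pulse_peak_time(self):
        # the corrected form inverts the top-hat peak condition exactly
        for v_true in (36.0, 100.0, 200.0):
            m = make_medium(v_h=v_true, t0=2.0)
            tm = hp.peak_time(m, 0.5)
            v = hp.tmax_velocity_corrected(tm, K_DEFAULT, 0.5, 2.0)
            assert v == pytest.approx(v_true, rel=1e-7)

    @pytest.mark.parametrize("v_true", [36.0, 72.0, 100.0, 200.0])
    def test_smaller_bias_than_instantaneous_form(self, v_true):
        # on finite-pulse (t0 = 2 s) traces the corrected form must win
        m = make_medium(v_h=v_true, t0=2.0)
        tm = hp.peak_time(m, 0.5)
        err_corr = abs(hp.tmax_velocity_corrected(tm, K_DEFAULT, 0.5, 2.0) - v_true)
        err_inst = abs(hp.tmax_velocity(tm, K_DEFAULT, 0.5) - v_true)
        assert err_corr < err_inst

    def test_late_peak_negative_radicand(self):
        # t_m = 30 s with t0 = 2 s: (4k/t0) ln(1 - t0/t_m) + x^2/(t_m (t_m - t0))
        # = -4.7e-5 < 0, a conduction-dominated peak the method cannot invert
        with pytest.raises(hp.BelowTmaxResolutionError):
            hp.tmax_velocity_corrected(30.0, K_DEFAULT, 0.5, 2.0)

    def test_peak_inside_pulse_rejected(self):
        with pytest.raises(hp.DomainError):
            hp.tmax_velocity_corrected(1.5, K_DEFAULT, 0.5, 2.0)


class TestDmaSelect:
    def test_zero_flow_selects_hrm(self, single_depth_geometry):
        est = _estimate(0.0, 2.0, single_depth_geometry)
        assert est.beta == pytest.approx(0.0, abs=0.01)
        assert est.method_selected == "HRM"
        assert est.v_h == pytest.approx(0.0, abs=0.1)

    def test_high_flow_selects_tmax(self, single_depth_geometry):
        est = _estimate(200.0, 2.0, single_depth_geometry)
        assert est.method_selected == "Tmax"

    def test_beta_exactly_one_is_hrm(self, single_depth_geometry):
        s = hp.PulseSummary(
            depth=0.5,
            dT_d_max=1.0,
            dT_u_max=1.0 / math.e,  # beta exactly 1
            t_m_down=15.0,
            ln_ratio_window=1.0,
            beta=1.0,
        )
        est = hp.dma_select(s, single_depth_geometry, K_DEFAULT, 2.0)
        assert est.method_selected == "HRM"

    def test_fallback_when_selected_method_fails(self, single_depth_geometry):
        # beta > 1 prefers Tmax, but the peak was unresolved -> HRM + flag
        s = hp.PulseSummary(
            depth=0.5,
            dT_d_max=1.0,
            dT_u_max=0.1,
            t_m_down=None,
            ln_ratio_window=2.0,
            beta=np.log(10.0),
        )
        est = hp.dma_select(s, single_depth_geometry, K_DEFAULT, 2.0)
        assert est.method_selected == "HRM"
        assert "dma-fallback" in est.qc_flags

    def test_both_methods_failed(self, single_depth_geometry):
        s = hp.PulseSummary(
            depth=0.5,
            dT_d_max=1.0,
            dT_u_max=0.1,
            t_m_down=None,
            ln_ratio_window=None,
            beta=2.0,
        )
        with pytest.raises(hp.NoEstimateError):
            hp.dma_select(s, single_depth_geometry, K_DEFAULT, 2.0)

    def test_selected_method_changes_once_over_sweep(self, single_depth_geometry):
        methods = []
        for v in (-20.0, 0.0, 10.0, 17.0, 19.0, 36.0, 100.0, 200.0):
            methods.append(_estimate(v, 2.0, single_depth_geometry).method_selected)
        switches = sum(a != b for a, b in zip(methods, methods[1:]))
        assert methods[0] == "HRM" and methods[-1] == "Tmax"
        assert switches == 1

    @pytest.mark.parametrize("v", [-20.0, -10.0, 0.0, 10.0, 36.0, 72.0, 120.0, 200.0])
    def test_noiseless_grid_recovery(self, v, single_depth_geometry):
        est = _estimate(v, 2.0, single_depth_geometry)
        if abs(v) >= 10.0:
            assert est.v_h == pytest.approx(v, rel=0.02)
        else:
            assert est.v_h == pytest.approx(v, abs=0.5)

    def test_hrm_antisymmetry_under_trace_mirroring(self, single_depth_geometry):
        m = make_medium(v_h=12.0, t0=2.0)
        rec = hp.generate_pulse_record(single_depth_geometry, m, hp.NOISELESS)
        # swap the up/down roles of the channels
        mirrored = hp.PulseRecord(
            cycle_id="m",
            timestamps=rec.timestamps,
            channels={k: v.copy() for k, v in rec.channels.items()},
            t0=rec.t0,
            channel_map={
                name: ("up" if side == "down" else "down", depth)
                for name, (side, depth) in rec.channel_map.items()
            },
        )
        e1 = hp.dma_select(
            hp.summarize_pulse(rec)[0], single_depth_geometry, K_DEFAULT, 2.0
        )
        e2 = hp.dma_select(
            hp.summarize_pulse(mirrored)[0], single_depth_geometry, K_DEFAULT, 2.0
        )
        assert e2.v_h == pytest.approx(-e1.v_h, rel=1e-9)


class TestEstimateKZeroFlow:
    def test_recovers_true_diffusivity(self, single_depth_geometry):
        rec = hp.generate_pulse_record(
            single_depth_geometry, make_medium(v_h=0.0, t0=2.0), hp.NOISELESS
        )
        k_est = hp.estimate_k_zero_flow(rec, single_depth_geometry)
        assert k_est == pytest.approx(K_DEFAULT, rel=0.01)

    def test_advection_biases_upward(self, single_depth_geometry):
        rec = hp.generate_pulse_record(
            single_depth_geometry, make_medium(v_h=36.0, t0=2.0), hp.NOISELESS
        )
        k_est = hp.estimate_k_zero_flow(rec, single_depth_geometry)
        assert k_est > K_DEFAULT


def test_annuli_from_depths_midpoint_boundaries():
    annuli = hp.annuli_from_depths([0.5, 1.5, 2.5], sapwood_radius=3.0)
    assert annuli == [(2.0, 3.0), (1.0, 2.0), (0.0, 1.0)]
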