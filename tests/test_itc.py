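"""ITC forward model and sequential fitter: oracles and recovery."""

import numpy as np
import pytest

from bindfit.equilibria import SequentialBindingModel, one_to_one_bound_fraction
from bindfit.itc import (
    ITCProtocol,
    Isotherm,
    default_injection_volumes,
    fit_sequential_itc,
    injection_concentrations,
    simulate_isotherm,
)


def wiseman_one_site_isotherm(kd, dh, protocol):
    """Independent closed-form single-site oracle.

    Uses the exact 1:1 quadratic for the bound concentration at each
    injection's diluted totals and the same displacement-heat convention.
    """
    d = np.cumprod(1.0 - protocol.injection_volumes / protocol.cell_volume)
    m = protocol.cell_conc * d
    ltot = protocol.syringe_conc * (1.0 - d)
    bound = np.array(
        [mj * one_to_one_bound_fraction(kd, mj, lj) for mj, lj in zip(m, ltot)]
    )
    h = protocol.cell_volume * dh * bound
    h_prev = np.concatenate(([0.0], h[:-1]))
    v = protocol.injection_volumes
    q = h - h_prev + (v / protocol.cell_volume) * 0.5 * (h + h_prev)
    return q / (protocol.syringe_conc * v)


class TestInjectionConcentrations:
    def test_small_first_injection_leaves_cell_nearly_undiluted(self, vpitc_protocol):
        m1, l1 = injection_concentrations(vpitc_protocol, 1)
        # 2 ul into 1461.9 ul: dilution factor 1 - 2/1461.9
        assert m1 == pytest.approx(110e-6 * (1 - 2 / 1461.9), rel=1e-12)
        assert 0 < l1 < vpitc_protocol.syringe_conc

    def test_dilution_product_28_injections(self):
        protocol = ITCProtocol(
            injection_volumes=np.full(28, 10e-6), discard_first=False
        )
        m, _ = injection_concentrations(protocol, 28)
        assert m == pytest.approx(110e-6 * (1 - 10 / 1461.9) ** 28, rel=1e-12)

    def test_single_full_cell_injection_empties_cell(self):
        protocol = ITCProtocol(injection_volumes=np.array([1.4619e-3]),
                               discard_first=False)
        m, l = injection_concentrations(protocol, 1)
        # the discrete dilution model flushes everything at v = V0 (not m0/e)
        assert m == 0.0
        assert l == pytest.approx(1.5e-3)

    def test_totals_monotone(self, vpitc_protocol):
        series = [injection_concentrations(vpitc_protocol, j)
                  for j in range(1, vpitc_protocol.n_injections + 1)]
        m, l = np.array(series).T
        assert np.all(np.diff(m) < 0)
        assert np.all(np.diff(l) > 0)

    def test_index_out_of_range(self, vpitc_protocol):
        with pytest.raises(IndexError):
            injection_concentrations(vpitc_protocol, 0)
        with pytest.raises(IndexError):
            injection_concentrations(vpitc_protocol, 99)


class TestSimulateIsotherm:
    def test_athermal_binding_is_heatless(self, vpitc_protocol):
        model = SequentialBindingModel(kd=(1e-7, 1e-6, 1e-6), dh=(0, 0, 0))
        iso = simulate_isotherm(model, vpitc_protocol)
        np.testing.assert_allclose(iso.q_per_mol, 0.0, atol=1e-15)

    def test_na_condition_isotherm_is_biphasic(self, na_model, vpitc_protocol):
        """The endothermic second step produces an interior extremum: heats
        become less exothermic mid-titration before dropping again."""
        iso = simulate_isotherm(na_model, vpitc_protocol)
        q = iso.q_per_mol[1:]  # skip the small first injection
        assert np.all(q < 0)  # net exothermic throughout
        peak = int(np.argmax(q))
        assert 0 < peak < q.size - 1
        assert q[peak] > q[0] + 0.5 and q[peak] > q[-1] + 0.1

    def test_one_active_step_matches_wiseman_oracle(self, vpitc_protocol):
        kd1, dh1 = 3e-7, -7.7
        model = SequentialBindingModel(kd=(kd1, 1e9, 1e9), dh=(dh1, 0.0, 0.0))
        iso = simulate_isotherm(model, vpitc_protocol)
        oracle = wiseman_one_site_isotherm(kd1, dh1, vpitc_protocol)
        np.testing.assert_allclose(iso.q_per_mol, oracle, rtol=1e-6)

    def test_cumulative_heat_identity(self, na_model, vpitc_protocol):
        """sum q_j telescopes to H_last plus the displacement corrections."""
        iso = simulate_isotherm(na_model, vpitc_protocol)
        v = vpitc_protocol.injection_volumes
        v0 = vpitc_protocol.cell_volume
        # recover H_j from the recursion q_j = H_j - H_{j-1} + (v/V0)(H_j+H_{j-1})/2
        h = np.empty(v.size)
        h_prev = 0.0
        for j in range(v.size):
            a = v[j] / v0
            h[j] = (iso.raw_heat[j] + h_prev * (1 - a / 2)) / (1 + a / 2)
            h_prev = h[j]
        corrections = (v / v0) * 0.5 * (h + np.concatenate(([0.0], h[:-1])))
        lhs = np.sum(iso.raw_heat)
        rhs = h[-1] + np.sum(corrections)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_molar_ratio_depends_only_on_cumulative_schedule(self, na_model):
        vols = np.array([2e-6] + [10e-6] * 10 + [5e-6] * 4)
        p1 = ITCProtocol(injection_volumes=vols)
        p2 = ITCProtocol(injection_volumes=vols[::-1].copy())
        i1 = simulate_isotherm(na_model, p1)
        i2 = simulate_isotherm(na_model, p2)
        # final composition identical for any ordering of the same volumes
        assert i1.molar_ratio[-1] == pytest.approx(i2.molar_ratio[-1], rel=1e-12)
        # equal-volume schedule is trivially permutation-invariant
        pe = ITCProtocol(injection_volumes=np.full(14, 10e-6))
        np.testing.assert_allclose(
            simulate_isotherm(na_model, pe).molar_ratio,
            simulate_isotherm(na_model, ITCProtocol(
                injection_volumes=np.full(14, 10e-6))).molar_ratio,
        )


class TestFitSequential:
    @pytest.mark.parametrize("which", ["na", "k"])
    def test_noiseless_recovery_from_perturbed_start(
        self, which, na_model, k_model, vpitc_protocol
    ):
        truth = {"na": na_model, "k": k_model}[which]
        iso = simulate_isotherm(truth, vpitc_protocol)
        init = SequentialBindingModel(kd=tuple(3 * k for k in truth.kd),
                                      dh=tuple(3 * h for h in truth.dh))
        res = fit_sequential_itc(iso, init)
        assert res.converged
        for fit_v, true_v in zip(res.model.kd, truth.kd):
            assert fit_v == pytest.approx(true_v, rel=1e-2)
        for fit_v, true_v in zip(res.model.dh, truth.dh):
            assert fit_v == pytest.approx(true_v, rel=1e-2)

    def test_all_zero_isotherm_flags_unidentifiable(self, vpitc_protocol):
        n = vpitc_protocol.n_injections
        d = np.cumprod(1 - vpitc_protocol.injection_volumes
                       / vpitc_protocol.cell_volume)
        mr = vpitc_protocol.syringe_conc * (1 - d) / (vpitc_protocol.cell_conc * d)
        iso = Isotherm(mr, np.zeros(n), np.zeros(n), vpitc_protocol)
        init = SequentialBindingModel(kd=(1e-7, 1e-6, 1e-6), dh=(-5, 1, -5))
        res = fit_sequential_itc(iso, init)
        assert any("unidentifiable" in w for w in res.warnings)
        np.testing.assert_allclose(res.model.dh, 0.0, atol=1e-6)

    def test_noise_robust_recovery_study(self, na_model, vpitc_protocol, rng):
        """Repeated noisy round trips recover all six parameters within 15%
        at 0.2% relative noise.

        Under this protocol the titrant is ~400-fold above the stepwise Kd,
        so the isotherm is nearly rectangular and the Kd are informed only
        by the step-edge curvature; their statistical error grows steeply
        with noise (tens of percent already at 2% noise, regardless of
        starting values)."""
        iso0 = simulate_isotherm(na_model, vpitc_protocol)
        sd = 0.002 * np.max(np.abs(iso0.q_per_mol))
        init = SequentialBindingModel(kd=tuple(3 * k for k in na_model.kd),
                                      dh=tuple(3 * h for h in na_model.dh))
        n_rep = 25
        for _ in range(n_rep):
            q = iso0.q_per_mol + rng.normal(0, sd, iso0.q_per_mol.size)
            iso = Isotherm(iso0.molar_ratio, q, iso0.raw_heat, vpitc_protocol)
            res = fit_sequential_itc(iso, init, multistart=False)
            rel_kd = np.abs(np.array(res.model.kd) / np.array(na_model.kd) - 1)
            rel_dh = np.abs(np.array(res.model.dh) / np.array(na_model.dh) - 1)
            assert np.max(rel_kd) < 0.15
            assert np.max(rel_dh) < 0.15

    def test_reported_errors_track_true_scatter_at_higher_noise(
        self, na_model, vpitc_protocol, rng
    ):
        """At 2% noise the Kd estimates scatter widely; the fit must report
        standard errors of matching magnitude rather than false precision."""
        iso0 = simulate_isotherm(na_model, vpitc_protocol)
        sd = 0.02 * np.max(np.abs(iso0.q_per_mol))
        q = iso0.q_per_mol + rng.normal(0, sd, iso0.q_per_mol.size)
        iso = Isotherm(iso0.molar_ratio, q, iso0.raw_heat, vpitc_protocol)
        res = fit_sequential_itc(iso, na_model, multistart=False)
        rel_se = res.kd_stderr / np.array(res.model.kd)
        # reported relative SE should acknowledge >=10% uncertainty
        assert np.max(rel_se) > 0.10

    def test_too_few_injections_rejected(self, na_model):
        p = ITCProtocol(injection_volumes=np.full(8, 10e-6))
        iso = simulate_isotherm(na_model, p)
        with pytest.raises(ValueError, match="12 usable"):
            fit_sequential_itc(iso, na_model)


def test_default_schedule_shape():
    vols = default_injection_volumes()
    assert vols.size == 29
    assert vols[0] == pytest.approx(2e-6)
    np.testing.assert_allclose(vols[1:], 10e-6)
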