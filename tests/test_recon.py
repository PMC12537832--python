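"""TFI initializer and mTFI inversion on the coarse (32^3) phantom."""

import numpy as np
import pytest

from dgmqsm.grids import dipole_kernel, forward_field
from dgmqsm.recon import (
    ReconParams,
    SusceptibilityMap,
    csf_reference,
    echo_time_weighted_magnitude,
    fit_signal_model,
    gradient_edge_weights,
    mtfi_reconstruct,
    total_field_inversion_init,
)
from dgmqsm.synthetic import AcquisitionParams, synthesize_multiecho
from dgmqsm.synthetic.signal import synthesize_background_field
from dgmqsm.units import hz_per_ppm

FAST = ReconParams(max_outer_iters=6, cg_iters=30)


def _roi_means(chi, phantom):
    return {
        name: float(chi[phantom.labels == lid].mean())
        for lid, name in phantom.label_names.items()
    }


class TestCsfReference:
    def test_zero_mean_after_referencing(self, coarse_phantom):
        rng = np.random.default_rng(0)
        chi = rng.standard_normal(coarse_phantom.grid.shape)
        ref = csf_reference(chi, coarse_phantom.csf_mask)
        assert abs(ref.chi[coarse_phantom.csf_mask].mean()) < 1e-9
        assert ref.reference_region == "csf"

    def test_identity_when_already_referenced(self, coarse_phantom):
        chi = np.ones(coarse_phantom.grid.shape)
        chi[coarse_phantom.csf_mask] = 0.0
        chi -= chi[coarse_phantom.csf_mask].mean()
        ref = csf_reference(chi, coarse_phantom.csf_mask)
        np.testing.assert_allclose(ref.chi, chi, atol=1e-12)

    def test_constant_shift_invariance_of_contrasts(self, coarse_phantom):
        rng = np.random.default_rng(1)
        chi = rng.standard_normal(coarse_phantom.grid.shape)
        a = csf_reference(chi, coarse_phantom.csf_mask).chi
        b = csf_reference(chi + 0.7, coarse_phantom.csf_mask).chi
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_empty_mask_rejected(self, coarse_phantom):
        with pytest.raises(ValueError, match="empty"):
            csf_reference(np.zeros(coarse_phantom.grid.shape), np.zeros(coarse_phantom.grid.shape, bool))


class TestTotalFieldInversion:
    def test_zero_field_gives_zero_chi(self, coarse_signal, coarse_phantom):
        fit = fit_signal_model(coarse_signal)
        fit.field_hz[:] = 0.0
        kern = dipole_kernel(coarse_phantom.grid)
        chi, _ = total_field_inversion_init(fit, kern, FAST, coarse_phantom.brain_mask)
        assert np.abs(chi).max() < 1e-9

    def test_noiseless_roi_recovery_within_ten_percent(self, coarse_signal, coarse_phantom):
        fit = fit_signal_model(coarse_signal)
        kern = dipole_kernel(coarse_phantom.grid)
        ew = gradient_edge_weights(
            echo_time_weighted_magnitude(coarse_signal), coarse_phantom.brain_mask
        )
        chi, log = total_field_inversion_init(
            fit, kern, FAST, coarse_phantom.brain_mask, edge_weights=ew
        )
        chi = chi - chi[coarse_phantom.csf_mask].mean()
        for name, value in _roi_means(chi, coarse_phantom).items():
            truth = {"thalamus": -0.008, "caudate": 0.042, "putamen": 0.050, "pallidum": 0.099}[name]
            assert value == pytest.approx(truth, rel=0.10), name

    def test_background_robustness(self, coarse_phantom):
        """ROI means with and without a background field agree within 15%."""
        bg = synthesize_background_field(coarse_phantom.grid, coarse_phantom.brain_mask)
        kern = dipole_kernel(coarse_phantom.grid)
        means = []
        for background in (None, bg):
            sig = synthesize_multiecho(coarse_phantom, AcquisitionParams(), background=background)
            fit = fit_signal_model(sig)
            ew = gradient_edge_weights(
                echo_time_weighted_magnitude(sig), coarse_phantom.brain_mask
            )
            chi, _ = total_field_inversion_init(
                fit, kern, FAST, coarse_phantom.brain_mask, edge_weights=ew
            )
            chi = chi - chi[coarse_phantom.csf_mask].mean()
            means.append(_roi_means(chi, coarse_phantom))
        for name in means[0]:
            assert means[1][name] == pytest.approx(means[0][name], rel=0.15), name


@pytest.fixture(scope="module")
def recon(coarse_signal, coarse_phantom):
    return mtfi_reconstruct(
        coarse_signal, coarse_phantom.brain_mask, coarse_phantom.csf_mask, FAST
    )


class TestMtfi:
    def test_roi_recovery(self, recon, coarse_phantom):
        truth = {"thalamus": -0.008, "caudate": 0.042, "putamen": 0.050, "pallidum": 0.099}
        for name, value in _roi_means(recon.chi, coarse_phantom).items():
            assert abs(value - truth[name]) <= max(0.1 * abs(truth[name]), 0.005), name

    def test_objective_monotone_nonincreasing(self, recon):
        log = np.asarray(recon.objective_log)
        assert len(log) >= 2
        assert np.all(np.diff(log) <= 1e-9 * np.abs(log[:-1]))

    def test_csf_referenced(self, recon, coarse_phantom):
        assert abs(recon.chi[coarse_phantom.csf_mask].mean()) < 1e-9
        assert recon.reference_region == "csf"

    def test_self_consistency_forward_field(self, recon, coarse_signal, coarse_phantom):
        """forward_field(chi_hat) correlates with the fitted field at r > 0.95."""
        fit = fit_signal_model(coarse_signal)
        f_ppm = fit.field_hz / hz_per_ppm(3.0)
        pred = forward_field(recon.chi, dipole_kernel(coarse_phantom.grid))
        m = coarse_phantom.brain_mask
        r = np.corrcoef(pred[m], f_ppm[m])[0, 1]
        assert r > 0.95

    def test_global_phase_shift_invariance(self, coarse_signal, coarse_phantom, recon):
        """Multiplying every echo by e^{i phi} changes chi by < 1e-6 ppm."""
        shifted = coarse_signal
        shifted = type(shifted)(
            grid=shifted.grid, acq=shifted.acq, data=shifted.data * np.exp(1j * 0.9)
        )
        other = mtfi_reconstruct(
            shifted, coarse_phantom.brain_mask, coarse_phantom.csf_mask, FAST
        )
        assert np.abs(other.chi - recon.chi).max() < 1e-6

    def test_deterministic(self, coarse_signal, coarse_phantom, recon):
        again = mtfi_reconstruct(
            coarse_signal, coarse_phantom.brain_mask, coarse_phantom.csf_mask, FAST
        )
        np.testing.assert_array_equal(again.chi, recon.chi)

    def test_empty_csf_mask_flags_unreferenced(self, coarse_signal, coarse_phantom):
        m = mtfi_reconstruct(
            coarse_signal,
            coarse_phantom.brain_mask,
            None,
            ReconParams(max_outer_iters=2, cg_iters=10),
        )
        assert m.flags.get("unreferenced") is True
        assert m.reference_region is None

    def test_tv_dominated_limit_is_flat(self, coarse_signal, coarse_phantom):
        """Very large lambda drives the penalized (edge-masked) total
        variation orders of magnitude below the near-unregularized one."""
        from dgmqsm.recon.solvers import gradient

        big = mtfi_reconstruct(
            coarse_signal,
            coarse_phantom.brain_mask,
            coarse_phantom.csf_mask,
            ReconParams(lambda_tv=1e3, max_outer_iters=12, cg_iters=40),
        )
        small = mtfi_reconstruct(
            coarse_signal,
            coarse_phantom.brain_mask,
            coarse_phantom.csf_mask,
            ReconParams(lambda_tv=1e-6, max_outer_iters=4, cg_iters=20),
        )
        ew = gradient_edge_weights(
            echo_time_weighted_magnitude(coarse_signal), coarse_phantom.brain_mask
        )
        tv = lambda c: float(np.sum(ew * np.abs(gradient(c))))
        assert tv(big.chi) < 1e-2 * tv(small.chi)

    def test_noise_robustness_and_snr_monotonicity(self, coarse_phantom):
        """ROI error shrinks (on average) as SNR rises from 25 to 100."""
        truth = {"thalamus": -0.008, "caudate": 0.042, "putamen": 0.050, "pallidum": 0.099}

        def mean_abs_err(noise_sigma, seed):
            sig = synthesize_multiecho(
                coarse_phantom, AcquisitionParams(noise_sigma=noise_sigma), seed=seed
            )
            rec = mtfi_reconstruct(
                sig, coarse_phantom.brain_mask, coarse_phantom.csf_mask, FAST
            )
            rois = _roi_means(rec.chi, coarse_phantom)
            return np.mean([abs(rois[k] - truth[k]) for k in truth])

        err_low = np.mean([mean_abs_err(0.04, s) for s in (0, 1, 2)])  # SNR 25
        err_high = np.mean([mean_abs_err(0.01, s) for s in (0, 1, 2)])  # SNR 100
        assert err_high <= err_low
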