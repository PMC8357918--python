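"""Scalar beamformer: covariance, orientation, weights, reconstruction."""

import numpy as np
import pytest

from megretest.beamformer import (BeamformerError, compute_weights,
                                  estimate_covariance, optimal_orientation,
                                  reconstruct_roi_series)
from megretest.cohort import SensorRecording
from megretest.connectivity import aec_matrix
from megretest.forward import (HeadModel, build_sensor_array, lead_field,
                               lead_field_block, source_layout)
from megretest.preprocess import split_epochs


@pytest.fixture(scope="module")
def single_source_setup():
    """One tangential dipole driving a ctf151 array with 1% sensor noise."""
    rng = np.random.default_rng(7)
    arr = build_sensor_array("ctf151")
    head = HeadModel()
    pos, ori, _ = source_layout()
    roi = 12
    t = 20_000
    sig = np.fft.irfft(np.pad(
        (rng.standard_normal(500) + 1j * rng.standard_normal(500)),
        (100, t // 2 + 1 - 600)), n=t)  # band-limited source
    sig = sig / sig.std()
    lf = lead_field(arr, head, pos[roi], ori[roi])
    data = np.outer(lf, sig)
    noise = 0.01 * np.abs(data).std() * rng.standard_normal(data.shape)
    rec = SensorRecording(data=data + noise, rate=312.5, array=arr,
                          head=head, system="ctf151")
    return rec, pos, ori, roi, sig


class TestCovariance:
    def test_white_noise_gives_scaled_identity(self, rng):
        x = rng.standard_normal((20, 100_000))
        cov = estimate_covariance(x, 312.5, reg=0.0, prefiltered=True)
        off = cov.c[~np.eye(20, dtype=bool)]
        assert np.abs(np.diag(cov.c) - 1.0).max() < 0.05
        assert np.abs(off).max() < 0.05

    def test_symmetric(self, rng):
        cov = estimate_covariance(rng.standard_normal((10, 5000)), 312.5)
        assert np.abs(cov.c - cov.c.T).max() < 1e-12

    def test_diagonal_loading_floor(self, rng):
        # eigendecomposition oracle: loading lifts the spectrum floor
        x = rng.standard_normal((5, 3000))
        x[4] = x[0] + x[1]  # rank-deficient direction
        unloaded_eigs = np.linalg.eigvalsh(np.cov(x))
        loaded = estimate_covariance(x, 312.5, reg=0.05, prefiltered=True)
        floor = 0.05 * unloaded_eigs.mean()
        assert np.linalg.eigvalsh(loaded.c).min() >= floor * (1 - 1e-9)

    def test_singular_with_zero_loading_rejected(self, rng):
        x = rng.standard_normal((5, 3000))
        x[4] = x[0] + x[1]
        with pytest.raises(BeamformerError, match="singular"):
            estimate_covariance(x, 312.5, reg=0.0, prefiltered=True)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(BeamformerError):
            estimate_covariance(rng.standard_normal((1, 100)), 312.5)


def pseudo_z_grid_oracle(l_block, c):
    """1-degree grid search over tangential orientations maximizing the
    pseudo-Z output SNR (l'C^-1 l)/(l'C^-2 l)."""
    c_inv = np.linalg.inv(c)
    _, _, vt = np.linalg.svd(l_block)
    best, best_nu = -np.inf, None
    for deg in range(180):
        a = np.deg2rad(deg)
        nu = np.cos(a) * vt[0] + np.sin(a) * vt[1]
        l_vec = l_block @ nu
        z = (l_vec @ c_inv @ l_vec) / (l_vec @ c_inv @ c_inv @ l_vec)
        if z > best:
            best, best_nu = z, nu
    return best_nu


class TestOrientation:
    def test_recovers_true_orientation(self, single_source_setup):
        rec, pos, ori, roi, _ = single_source_setup
        cov = estimate_covariance(rec.data, rec.rate, prefiltered=True)
        l_block = lead_field_block(rec.array, rec.head, pos[roi])
        nu = optimal_orientation(l_block, cov.c)
        angle = np.degrees(np.arccos(min(1.0, abs(nu @ ori[roi]))))
        assert angle < 5.0

    def test_agrees_with_grid_search_oracle(self, single_source_setup):
        rec, pos, _, roi, _ = single_source_setup
        cov = estimate_covariance(rec.data, rec.rate, prefiltered=True)
        l_block = lead_field_block(rec.array, rec.head, pos[roi])
        nu = optimal_orientation(l_block, cov.c)
        nu_grid = pseudo_z_grid_oracle(l_block, cov.c)
        angle = np.degrees(np.arccos(min(1.0, abs(nu @ nu_grid))))
        assert angle < 5.0

    def test_unit_norm(self, single_source_setup):
        rec, pos, _, roi, _ = single_source_setup
        cov = estimate_covariance(rec.data, rec.rate, prefiltered=True)
        nu = optimal_orientation(
            lead_field_block(rec.array, rec.head, pos[roi]), cov.c)
        assert np.linalg.norm(nu) == pytest.approx(1.0, abs=1e-12)

    def test_identity_covariance_deterministic(self, ctf_array, head):
        l_block = lead_field_block(ctf_array, head,
                                   np.array([0.02, 0.01, 0.05]))
        c = np.eye(151)
        with pytest.warns(UserWarning, match="degenerate"):
            a = optimal_orientation(l_block, c)
        with pytest.warns(UserWarning, match="degenerate"):
            b = optimal_orientation(l_block, c)
        assert np.array_equal(a, b)


class TestWeights:
    def test_unit_gain_identity(self, single_source_setup):
        rec, pos, _, roi, _ = single_source_setup
        cov = estimate_covariance(rec.data, rec.rate, prefiltered=True)
        l_block = lead_field_block(rec.array, rec.head, pos[roi])
        nu = optimal_orientation(l_block, cov.c)
        w = compute_weights(l_block, cov.c, nu, normalize=False)
        assert w @ (l_block @ nu) == pytest.approx(1.0, abs=1e-10)

    def test_normalized_weights_unit_norm(self, single_source_setup):
        rec, pos, _, roi, _ = single_source_setup
        cov = estimate_covariance(rec.data, rec.rate, prefiltered=True)
        l_block = lead_field_block(rec.array, rec.head, pos[roi])
        nu = optimal_orientation(l_block, cov.c)
        w = compute_weights(l_block, cov.c, nu, normalize=True)
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-10)

    def test_identity_covariance_closed_form(self, ctf_array, head):
        l_block = lead_field_block(ctf_array, head,
                                   np.array([0.03, 0.0, 0.05]))
        nu = np.array([0.0, 1.0, 0.0])
        l_vec = l_block @ nu
        w = compute_weights(l_block, np.eye(151), nu, normalize=False)
        assert np.allclose(w, l_vec / (l_vec @ l_vec))

    def test_silent_source_rejected(self, ctf_array, head):
        with pytest.raises(BeamformerError, match="silent"):
            compute_weights(np.zeros((151, 3)), np.eye(151),
                            np.array([1.0, 0, 0]))


class TestReconstruction:
    def test_single_source_recovered(self, single_source_setup):
        rec, pos, _, roi, sig = single_source_setup
        series, weights = reconstruct_roi_series(rec, pos)
        assert series.shape == (90, rec.data.shape[1])
        r = np.corrcoef(series[roi], sig)[0, 1]
        assert abs(r) > 0.95

    def test_two_sources_separated(self, ctf_array, head, rng):
        pos, ori, _ = source_layout()
        i, j = 5, 60  # well-separated ROIs
        t = 20_000
        sigs = rng.standard_normal((2, t))
        from megretest.connectivity import brickwall_bandpass
        sigs = brickwall_bandpass(sigs, (2, 40), 312.5)
        data = (np.outer(lead_field(ctf_array, head, pos[i], ori[i]), sigs[0])
                + np.outer(lead_field(ctf_array, head, pos[j], ori[j]),
                           sigs[1]))
        data += 0.01 * np.abs(data).std() * rng.standard_normal(data.shape)
        rec = SensorRecording(data=data, rate=312.5, array=ctf_array,
                              head=head, system="ctf151")
        series, _ = reconstruct_roi_series(rec, pos)
        for roi, own, other in ((i, sigs[0], sigs[1]),
                                (j, sigs[1], sigs[0])):
            r_own = abs(np.corrcoef(series[roi], own)[0, 1])
            r_other = abs(np.corrcoef(series[roi], other)[0, 1])
            assert r_own > r_other

    def test_weight_normalization_invisible_to_aec(self, single_source_setup):
        # normalization rescales per-ROI amplitude only
        rec, pos, _, _, _ = single_source_setup
        a, _ = reconstruct_roi_series(rec, pos[:6], normalize=True)
        b, _ = reconstruct_roi_series(rec, pos[:6], normalize=False)
        ep_a = split_epochs(a, 312.5)
        ep_b = split_epochs(b, 312.5)
        ma = aec_matrix(ep_a, (8.0, 13.0))
        mb = aec_matrix(ep_b, (8.0, 13.0))
        off = ~np.eye(6, dtype=bool)
        assert np.abs(ma.values[off] - mb.values[off]).max() < 1e-10

    def test_linear_in_sensor_data(self, single_source_setup):
        rec, pos, _, _, _ = single_source_setup
        series, weights = reconstruct_roi_series(rec, pos[:4])
        doubled = SensorRecording(data=2 * rec.data, rate=rec.rate,
                                  array=rec.array, head=rec.head,
                                  system=rec.system)
        # same weights applied to doubled data double the output
        from megretest.connectivity import brickwall_bandpass
        filt = brickwall_bandpass(doubled.data, (0.5, 48.0), rec.rate)
        diff = np.abs(weights.w @ filt - 2 * series).max()
        assert diff < 1e-9 * np.abs(series).max()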