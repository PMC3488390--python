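from dataclasses import replace

import numpy as np
import pytest

from hosemg.experiments import third_order_cumulant_reference, _principal_argmax
from hosemg.hos import (
    BispectrumGrid,
    bispectrum_direct,
    bispectrum_indirect,
    hanning_2d,
    power_spectrum,
    principal_domain_mask,
    qpc_quantity,
    third_order_cumulant,
)
from hosemg.io_uci import Episode
from hosemg.synthetic import generate_coupled_episode


class TestThirdOrderCumulant:
    def test_zero_signal_zero_lattice(self):
        lat = third_order_cumulant(np.zeros(64), max_lag=3)
        assert np.all(lat.values == 0.0)

    def test_three_point_hand_value(self):
        # x=[1,2,4] centers to [-4/3,-1/3,5/3]; mean cube = 20/27
        lat = third_order_cumulant(np.array([1.0, 2.0, 4.0]), max_lag=0)
        assert lat.values[0, 0] == pytest.approx(20.0 / 27.0, abs=1e-14)

    @pytest.mark.parametrize("estimator", ["biased", "unbiased"])
    def test_matches_brute_force_oracle(self, estimator, rng):
        tol = 1e-12 if estimator == "biased" else 1e-10
        for n in (11, 24, 64):
            x = rng.normal(size=n) ** 3
            fast = third_order_cumulant(x, 4, estimator).values
            ref = third_order_cumulant_reference(x, 4, estimator)
            assert np.abs(fast - ref).max() < tol

    @pytest.mark.parametrize("estimator", ["biased", "unbiased"])
    def test_transpose_symmetry_exact(self, estimator, rng):
        x = rng.normal(size=100) ** 3
        v = third_order_cumulant(x, 5, estimator).values
        assert np.array_equal(v, v.T)  # C3(1,2) == C3(2,1) bitwise

    def test_full_lag_symmetry_group(self, rng):
        # C3(n1,n2) = C3(-n1, n2-n1) = C3(n1-n2, -n2) on the lattice
        x = rng.normal(size=80) ** 3
        L = 3
        v = third_order_cumulant(x, L, "biased").values
        for n1 in range(-L, L + 1):
            for n2 in range(-L, L + 1):
                for m1, m2 in [(-n1, n2 - n1), (n1 - n2, -n2)]:
                    if abs(m1) <= L and abs(m2) <= L:
                        assert v[n1 + L, n2 + L] == v[m1 + L, m2 + L]

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            third_order_cumulant(np.array([]), 0)
        with pytest.raises(ValueError, match="too short"):
            third_order_cumulant(np.ones(10), 5)
        with pytest.raises(ValueError, match="estimator"):
            third_order_cumulant(np.ones(10), 1, "magic")


class TestHanning2d:
    def test_shape_and_peak(self):
        W = hanning_2d(50)  # 0.05 s at 1 kHz
        assert W.shape == (101, 101)
        assert W[50, 50] == 1.0  # peak-normalized at lag (0,0)

    def test_separable_symmetry(self):
        W = hanning_2d(10)
        assert W[13, 17] == W[17, 13]
        w = W[10]  # center row is the 1-D taper
        assert np.allclose(W, np.outer(w, w))

    def test_vanishes_at_edge(self):
        W = hanning_2d(8)
        assert W[0, 8] == 0.0 and W[16, 8] == 0.0

    def test_rejects_bad_length(self):
        with pytest.raises(ValueError):
            hanning_2d(0)


class TestBispectrumIndirect:
    def test_zero_lattice_zero_grid(self):
        lat = third_order_cumulant(np.zeros(64), 4)
        B = bispectrum_indirect(lat, nfft=16)
        assert np.all(B.values == 0.0)

    def test_grid_symmetries(self, rng):
        x = rng.normal(size=300) ** 3
        lat = third_order_cumulant(x, 6)
        B = bispectrum_indirect(lat, nfft=32)
        v = B.values
        assert np.allclose(v, v.T, rtol=1e-9, atol=1e-12)  # B(w1,w2)=B(w2,w1)
        # real input: B(-w1,-w2) = conj(B(w1,w2))
        flipped = v[(-np.arange(32)) % 32][:, (-np.arange(32)) % 32]
        assert np.allclose(flipped, np.conj(v), rtol=1e-9, atol=1e-12)

    def test_window_larger_than_lattice_errors(self, rng):
        lat = third_order_cumulant(rng.normal(size=50), 3)
        with pytest.raises(ValueError, match="window"):
            bispectrum_indirect(lat, window=hanning_2d(10), nfft=32)

    def test_nfft_smaller_than_lattice_errors(self, rng):
        lat = third_order_cumulant(rng.normal(size=50), 8)
        with pytest.raises(ValueError, match="nfft"):
            bispectrum_indirect(lat, nfft=8)


class TestBispectrumDirect:
    def test_zero_episode_zero_grid(self):
        ep = Episode(samples=np.zeros(1000))
        B = bispectrum_direct(ep, segment_length=128, nfft=128)
        assert np.all(B.values == 0.0)

    def test_grid_symmetries(self, rng):
        ep = Episode(samples=rng.normal(size=1500) ** 3)
        B = bispectrum_direct(ep, segment_length=64, nfft=64)
        v = B.values
        assert np.allclose(v, v.T, rtol=1e-9, atol=1e-12)
        flipped = v[(-np.arange(64)) % 64][:, (-np.arange(64)) % 64]
        assert np.allclose(flipped, np.conj(v), rtol=1e-9, atol=1e-12)

    def test_short_episode_errors(self):
        ep = Episode(samples=np.ones(100))
        with pytest.raises(ValueError, match="shorter"):
            bispectrum_direct(ep, segment_length=256)

    def test_single_segment_warns_but_returns(self, caplog):
        ep = Episode(samples=np.random.default_rng(0).normal(size=300))
        with caplog.at_level("WARNING"):
            B = bispectrum_direct(ep, segment_length=256, nfft=256)
        assert B.values.shape == (256, 256)
        assert any("segment" in r.message for r in caplog.records)

    def test_bad_overlap_errors(self):
        ep = Episode(samples=np.ones(1000))
        with pytest.raises(ValueError, match="overlap"):
            bispectrum_direct(ep, overlap_fraction=1.0)

    def test_cross_estimator_argmax_agreement(self, short_aggressive_spec):
        spec = replace(short_aggressive_spec, duration=10.0)
        ep = generate_coupled_episode(spec)
        Bd = bispectrum_direct(ep, segment_length=256, nfft=256)
        c3 = third_order_cumulant(ep, max_lag=50)
        Bi = bispectrum_indirect(c3, nfft=256)
        assert _principal_argmax(Bd) == _principal_argmax(Bi)
        # and the cell contains (max(f1,f2), min(f1,f2))
        i, j = _principal_argmax(Bd)
        df = 1000.0 / 256
        assert i * df <= max(spec.f1, spec.f2) < (i + 1) * df
        assert j * df <= min(spec.f1, spec.f2) < (j + 1) * df


class TestPrincipalDomain:
    def test_boundary_cells(self):
        m = principal_domain_mask(16)
        assert m[0, 0]  # origin included
        assert not m[8, 8]  # (Nyquist, Nyquist): w1+w2 > pi
        assert m[8, 0]  # w1 = Nyquist, w2 = 0 boundary

    def test_triangle_condition_brute_force(self):
        nfft = 64
        m = principal_domain_mask(nfft)
        for i in range(nfft):
            for j in range(nfft):
                assert m[i, j] == (j <= i and i + j <= nfft // 2)

    def test_cell_count_scales_as_one_sixteenth(self):
        nfft = 512
        count = principal_domain_mask(nfft).sum()
        assert count == pytest.approx(nfft**2 / 16, rel=0.02)

    def test_rejects_tiny_grid(self):
        with pytest.raises(ValueError):
            principal_domain_mask(1)


class TestQpcQuantity:
    def _grid(self, values):
        n = values.shape[0]
        return BispectrumGrid(
            values=values,
            freq_axis=np.arange(n) * 1000.0 / n,
            sampling_rate=1000.0,
            method="direct",
        )

    def test_zero_grid_zero_D(self):
        q = qpc_quantity(self._grid(np.zeros((16, 16), complex)))
        assert q.D == 0.0
        assert q.n_cells > 0

    def test_diagonal_excluded(self):
        # grid supported only on w1 == w2 contributes nothing
        v = np.diag(np.arange(16, dtype=complex) + 5)
        assert qpc_quantity(self._grid(v)).D == 0.0

    def test_single_offdiagonal_cell_counts(self):
        v = np.zeros((16, 16), complex)
        v[3, 1] = 2.0 - 1.0j  # inside the principal triangle
        assert qpc_quantity(self._grid(v)).D == pytest.approx(abs(v[3, 1]))

    def test_sign_flip_invariance(self, short_aggressive_spec):
        ep = generate_coupled_episode(short_aggressive_spec)
        neg = Episode(samples=-ep.samples, sampling_rate=ep.sampling_rate)
        d1 = qpc_quantity(bispectrum_direct(ep, 256, 256)).D
        d2 = qpc_quantity(bispectrum_direct(neg, 256, 256)).D
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_cubic_amplitude_scaling(self, short_aggressive_spec):
        ep = generate_coupled_episode(short_aggressive_spec)
        scaled = Episode(samples=3.0 * ep.samples, sampling_rate=ep.sampling_rate)
        d1 = qpc_quantity(bispectrum_direct(ep, 256, 256)).D
        d2 = qpc_quantity(bispectrum_direct(scaled, 256, 256)).D
        assert d2 == pytest.approx(27.0 * d1, rel=1e-9)

    def test_nonfinite_grid_rejected(self):
        v = np.zeros((8, 8), complex)
        v[1, 0] = np.nan
        with pytest.raises(ValueError):
            self._grid(v)


class TestPowerSpectrum:
    def test_pure_tone_argmax(self):
        fs, f0 = 1000.0, 125.0  # bin-centered at nfft=256
        t = np.arange(4000) / fs
        ep = Episode(samples=np.cos(2 * np.pi * f0 * t), sampling_rate=fs)
        f, p = power_spectrum(ep, 256, 256)
        half = len(f) // 2
        assert f[np.argmax(p[:half])] == pytest.approx(f0, abs=fs / 256)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(size=20_000)
        ep = Episode(samples=x)
        f, p = power_spectrum(ep, 256, 256)
        df = f[1] - f[0]
        assert p.sum() * df == pytest.approx(np.var(x), rel=0.05)
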