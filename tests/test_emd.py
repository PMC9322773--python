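import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multilstm.emd import (
    EMDConfig,
    MonotoneResidual,
    build_envelopes,
    component_correlation,
    count_zero_crossings,
    decompose,
    extract_imf,
    find_extrema,
    instantaneous_spectrum,
    is_imf,
    orthogonality_index,
    reconstruct,
    sd_value,
    sift_once,
)

from reference_emd import reference_emd


class TestExtrema:
    @pytest.mark.parametrize(
        "x,maxima,minima",
        [
            ([0, 1, 0, 1, 0], [1, 3], [2]),
            ([0, 1, 2, 3, 4], [], []),  # monotone ramp
            ([0, 1, 1, 0], [1], []),  # plateau midpoint, tie to lower index
            ([3, 1, 4, 1, 5, 9, 2, 6], [2, 5], [1, 3, 6]),
            ([0, -1, -1, -1, 0], [], [2]),  # three-wide plateau minimum
        ],
    )
    def test_interior_extrema(self, x, maxima, minima):
        mx, mn = find_extrema(np.asarray(x, dtype=float))
        assert mx == maxima
        assert mn == minima

    @pytest.mark.parametrize(
        "x,n",
        [
            ([1, -1, 1, -1], 3),
            ([1, 2, 3], 0),
            ([1, 0, -1], 1),  # exact zero between opposite signs: once
            ([1, 0, 1], 0),  # exact zero between same signs: not a crossing
            ([-1, 0, 0, 1], 1),
        ],
    )
    def test_zero_crossings(self, x, n):
        assert count_zero_crossings(np.asarray(x, dtype=float)) == n


class TestEnvelopes:
    def test_dense_sine_envelope_mean_near_zero(self):
        t = np.linspace(0, 8, 1000, endpoint=False)
        x = np.sin(2 * np.pi * t)
        env = build_envelopes(x)
        interior = slice(100, 900)
        assert np.max(np.abs(env.m[interior])) < 0.05
        assert np.all(env.u[interior] >= env.v[interior])

    def test_symmetric_triangle_mean_zero(self):
        # symmetric triangle wave: envelopes are the constant peak lines
        period = 100
        t = np.arange(1000)
        x = 2 * np.abs(t / period - np.floor(t / period + 0.5)) - 0.5
        env = build_envelopes(x)
        assert np.max(np.abs(env.m[100:900])) < 1e-6

    def test_two_extrema_of_each_kind_suffice(self):
        t = np.linspace(0, 2, 200, endpoint=False)
        x = np.sin(2 * np.pi * t)  # 2 maxima, 2 minima
        env = build_envelopes(x)
        assert env.u.shape == x.shape and env.v.shape == x.shape

    def test_monotone_signal_raises(self):
        with pytest.raises(MonotoneResidual):
            build_envelopes(np.arange(10.0))

    def test_sift_subtracts_envelope_mean(self):
        t = np.linspace(0, 4, 500, endpoint=False)
        x = 3.0 + np.sin(2 * np.pi * t)  # constant offset + tone
        h = sift_once(x).h
        assert abs(np.mean(h)) < 0.05  # first sift removes the offset


class TestSDValue:
    def test_hand_example(self):
        # (0.1^2 + 0.2^2) / (1 + 4) = 0.01
        assert sd_value([1.0, 2.0], [0.9, 1.8]) == pytest.approx(0.01)

    def test_identical_series_zero(self):
        assert sd_value([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_full_mass_difference(self):
        assert sd_value([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_zero_previous_iterate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sd_value([0.0, 0.0], [1.0, 1.0])


class TestIsIMF:
    def test_pure_tone_is_imf(self):
        t = np.linspace(0, 5, 500, endpoint=False)
        ok, diag = is_imf(np.sin(2 * np.pi * t))
        assert ok
        assert abs(diag["n_extrema"] - diag["n_zero_crossings"]) <= 1

    def test_positive_ramp_is_not(self):
        ok, _ = is_imf(np.linspace(1, 10, 50))
        assert not ok

    def test_zero_series_is_imf_by_convention(self):
        ok, _ = is_imf(np.zeros(100))
        assert ok


class TestExtract:
    def test_first_imf_matches_fast_tone(self, two_tone):
        _, x, comps = two_tone
        imf = extract_imf(x)
        assert np.corrcoef(imf.c, comps[0])[0, 1] >= 0.95

    def test_pure_tone_returned_nearly_unchanged(self):
        t = np.linspace(0, 5, 500, endpoint=False)
        x = np.sin(2 * np.pi * t)
        imf = extract_imf(x)
        assert imf.n_sift_iterations <= 2
        assert np.corrcoef(imf.c, x)[0, 1] > 0.999

    def test_sift_cap_honored(self, two_tone):
        _, x, _ = two_tone
        imf = extract_imf(x, EMDConfig(max_sift_iter=1))
        assert imf.n_sift_iterations == 1

    def test_monotone_input_has_nothing_to_extract(self):
        with pytest.raises(MonotoneResidual):
            extract_imf(np.arange(20.0))


class TestDecompose:
    def test_linear_ramp_yields_no_imfs(self):
        d = decompose(np.linspace(0, 9, 100))
        assert d.n_imfs == 0
        np.testing.assert_array_equal(d.residual, np.linspace(0, 9, 100))

    def test_two_tone_separation(self, two_tone):
        _, x, comps = two_tone
        d = decompose(x)
        assert d.n_imfs >= 2
        fast = np.corrcoef(d.imfs[0].c, comps[0])[0, 1]
        slow = max(
            abs(np.corrcoef(c, comps[1])[0, 1])
            for c in [imf.c for imf in d.imfs[1:]] + [d.residual]
            if np.std(c) > 0
        )
        assert fast >= 0.95
        assert slow >= 0.95

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="N=3"):
            decompose(np.array([1.0, 2.0, 1.0]))

    def test_max_imfs_cap(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x, EMDConfig(max_imfs=1))
        assert d.n_imfs == 1

    def test_reconstruction_exact(self, two_tone, rng):
        _, x, _ = two_tone
        for sig in (x, np.cumsum(rng.normal(size=400))):
            d = decompose(sig)
            assert np.max(np.abs(reconstruct(d) - sig)) < 1e-9

    def test_empty_imf_list_reconstructs_residual(self):
        ramp = np.linspace(0, 9, 50)
        d = decompose(ramp)
        np.testing.assert_array_equal(reconstruct(d), d.residual)

    def test_dropping_one_imf_changes_reconstruction_linearly(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x)
        partial = reconstruct(d) - d.imfs[0].c
        err = np.abs(partial - x)
        k = np.argmax(np.abs(d.imfs[0].c))
        assert err[k] == pytest.approx(np.abs(d.imfs[0].c)[k])

    def test_every_returned_imf_is_valid(self, rng):
        cfg = EMDConfig()
        for _ in range(5):
            x = np.cumsum(rng.normal(size=300))
            d = decompose(x, cfg)
            for imf in d.imfs:
                ok, diag = is_imf(imf.c, cfg.envelope_tol, cfg.boundary_policy)
                assert ok, diag

    def test_mean_frequency_cascade_on_tone_mixture(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x)
        means = []
        for imf in d.imfs:
            _, freq, _, _ = instantaneous_spectrum(imf.c, sample_rate=500.0)
            n = freq.size
            means.append(np.mean(freq[n // 10:-n // 10]))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_orthogonality_index_small_on_two_tone(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x)
        assert orthogonality_index(d, x) < 0.1


class TestAgainstReferenceImplementation:
    def test_canonical_two_tone_agrees_with_reference(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x)
        modes = reference_emd(x)
        assert np.corrcoef(d.imfs[0].c, modes[0])[0, 1] > 0.9

    def test_leading_imf_agrees_on_random_mixtures(self):
        from multilstm.synthetic import ToneMixtureSpec, ToneSpec, make_tone_mixture

        rng = np.random.default_rng(3)
        for s in range(5):
            f_fast = rng.uniform(4, 8)
            f_slow = rng.uniform(0.4, 0.9)
            _, x, _ = make_tone_mixture(
                ToneMixtureSpec(
                    [ToneSpec(f_fast), ToneSpec(f_slow)], 2.0, 1000, seed=100 + s
                )
            )
            d = decompose(x)
            modes = reference_emd(x)
            assert np.corrcoef(d.imfs[0].c, modes[0])[0, 1] > 0.9


class TestSpectrum:
    def test_tone_instantaneous_frequency(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 3.0 * t)
        amp, freq, f_max, res = instantaneous_spectrum(x, sample_rate=fs)
        n = t.size
        interior = slice(n // 10, -n // 10)
        assert abs(np.median(freq[interior]) - 3.0) / 3.0 < 0.02

    def test_tone_amplitude(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        amp, *_ = instantaneous_spectrum(2.5 * np.sin(2 * np.pi * 3.0 * t), fs)
        n = t.size
        np.testing.assert_allclose(amp[n // 10:-n // 10], 2.5, rtol=0.02)

    def test_resolution_is_fmax_over_n(self):
        fs = 500.0
        t = np.arange(1000) / fs
        _, _, f_max, res = instantaneous_spectrum(np.sin(2 * np.pi * 10 * t), fs)
        assert res == pytest.approx(f_max / 1000)
        assert f_max == pytest.approx(10.0, rel=0.05)

    def test_short_imf_rejected(self):
        with pytest.raises(ValueError, match="short"):
            instantaneous_spectrum(np.ones(5))


class TestComponentCorrelation:
    def test_self_and_negated(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x)
        rhos = component_correlation(d, x)
        assert rhos.size == d.n_imfs + 1

    def test_constant_component_gives_nan(self):
        from multilstm.emd import Decomposition, IMF

        c = np.sin(np.linspace(0, 20, 100))
        d = Decomposition(
            imfs=[IMF(c=np.ones(100), index=1, n_extrema=0, n_zero_crossings=0)],
            residual=c,
        )
        rhos = component_correlation(d, c)
        assert np.isnan(rhos[0])
        assert rhos[1] == pytest.approx(1.0)

    def test_variance_recovered_on_two_tone(self, two_tone):
        _, x, _ = two_tone
        d = decompose(x)
        comp_var = sum(np.var(c) for c in d.components())
        assert abs(comp_var - np.var(x)) / np.var(x) < 0.05


@settings(deadline=None, max_examples=20)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(50, 400))
def test_completeness_property(seed, n):
    """sum IMFs + residual == input for arbitrary random walks."""
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(size=n))
    d = decompose(x)
    assert np.max(np.abs(reconstruct(d) - x)) < 1e-9
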