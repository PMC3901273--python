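"""Probability product kernel: closed form, variants, Gram matrices."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

from specfp.kernels import (
    GramMatrix,
    KernelParams,
    ProbabilityProductKernel,
    combined_kernel_value,
    estimate_peak_variances,
    gram_matrix,
    kernel_value,
    normalize_and_combine,
    peak_pair_integral,
    to_diff_spectrum,
    to_loss_spectrum,
)
from specfp.spectra import Peak, Spectrum, normalize_intensities
from conftest import random_spectrum


def quadrature_integral(p1, p2, params):
    """Independent numerical oracle: 2-D quadrature of the Gaussian product.

    Integrates in standardised coordinates u = m / sigma_m, v = i / sigma_i
    (the Jacobian contributes 1 / (sigma_m * sigma_i)), which keeps the
    integrand well conditioned for sharp peak models.
    """
    sm, si = params.sigma_mass, params.sigma_intensity
    a1, a2 = p1[0] / sm, p2[0] / sm
    b1, b2 = p1[1] / si, p2[1] / si

    def phi(x):
        return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)

    val, _ = dblquad(
        lambda v, u: phi(u - a1) * phi(u - a2) * phi(v - b1) * phi(v - b2),
        min(a1, a2) - 8, max(a1, a2) + 8,
        min(b1, b2) - 8, max(b1, b2) + 8,
        epsabs=1e-14, epsrel=1e-10,
    )
    return val / (sm * si)


def brute_force_kernel(s1, s2, variant, params):
    """Explicit double loop over peak pairs (oracle for kernel_value)."""
    from specfp.kernels import to_diff_spectrum, to_loss_spectrum

    def rep(s):
        s = normalize_intensities(s)
        if variant == "mloss":
            s = to_loss_spectrum(s)
        elif variant == "diff":
            s = to_diff_spectrum(s)
        return s

    a, b = rep(s1), rep(s2)
    total = 0.0
    for p in a.peaks:
        for q in b.peaks:
            total += peak_pair_integral(p, q, params)
    return total / (len(a) * len(b))


class TestPeakPairIntegral:
    def test_self_product_identity(self, params):
        v = peak_pair_integral(Peak(100.0, 0.5), Peak(100.0, 0.5), params)
        assert v == pytest.approx(1 / (4 * math.pi * params.sigma_mass * params.sigma_intensity))

    def test_matches_quadrature(self, rng):
        for _ in range(10):
            p = KernelParams(
                sigma_mass=float(rng.uniform(0.005, 0.3)),
                sigma_intensity=float(rng.uniform(0.02, 0.3)),
            )
            p1 = (float(rng.uniform(90, 110)), float(rng.uniform(0, 1)))
            p2 = (p1[0] + float(rng.normal(0, p.sigma_mass)), float(rng.uniform(0, 1)))
            closed = peak_pair_integral(p1, p2, p)
            quad = quadrature_integral(p1, p2, p)
            assert closed == pytest.approx(quad, rel=1e-8)

    def test_decays_monotonically_with_mass_distance(self, params):
        vals = [
            peak_pair_integral(Peak(100.0, 0.5), Peak(100.0 + d, 0.5), params)
            for d in [0.0, 0.01, 0.05, 0.2, 1.0]
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-6 * vals[0]

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(sigma_mass=0.0)
        with pytest.raises(ValueError):
            KernelParams(sigma_intensity=-1.0)


class TestLossAndDiff:
    def test_loss_subtraction(self):
        s = Spectrum(peaks=[Peak(100.05, 0.3)], precursor_mass=181.07)
        loss = to_loss_spectrum(s)
        assert loss.mz[0] == pytest.approx(81.02)
        assert loss.intensity[0] == pytest.approx(0.3)

    def test_peak_at_precursor_gives_zero_loss(self):
        s = Spectrum(peaks=[Peak(181.07, 0.5), Peak(100.0, 0.5)], precursor_mass=181.07)
        assert to_loss_spectrum(s).mz[0] == pytest.approx(0.0)

    def test_involution(self, rng):
        s = random_spectrum(rng, 6)
        twice = to_loss_spectrum(to_loss_spectrum(s))
        assert np.allclose(np.sort(twice.mz), np.sort(s.mz))

    def test_negative_losses_dropped_with_warning(self, caplog):
        s = Spectrum(
            peaks=[Peak(100.0, 0.5), Peak(250.0, 0.5)],
            precursor_mass=200.0,
            spectrum_id="S1",
        )
        with caplog.at_level("WARNING"):
            loss = to_loss_spectrum(s)
        assert len(loss) == 1
        assert "S1" in caplog.text

    def test_missing_precursor_errors(self):
        s = Spectrum(peaks=[Peak(100.0, 1.0)], spectrum_id="noprec")
        with pytest.raises(ValueError, match="noprec"):
            to_loss_spectrum(s)

    def test_diff_pseudo_peak_count_quadratic(self, rng):
        # operation-count property: l peaks -> l(l-1)/2 pseudo-peaks
        for n in [2, 5, 9]:
            s = random_spectrum(rng, n)
            assert len(to_diff_spectrum(s)) <= n * (n - 1) // 2
            # (equality up to merged duplicate difference masses)
            assert len(to_diff_spectrum(s)) >= n - 1

    def test_diff_single_peak_errors(self):
        with pytest.raises(ValueError):
            to_diff_spectrum(Spectrum(peaks=[Peak(100.0, 1.0)]))


class TestKernelValue:
    def test_single_peak_reduction(self, params):
        s1 = Spectrum(peaks=[Peak(100.0, 1.0)])
        s2 = Spectrum(peaks=[Peak(100.02, 1.0)])
        expected = peak_pair_integral(Peak(100.0, 1.0), Peak(100.02, 1.0), params)
        assert kernel_value(s1, s2, "peaks", params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("variant", ["peaks", "mloss", "diff"])
    def test_matches_brute_force(self, variant, rng, params):
        for _ in range(5):
            s1, s2 = random_spectrum(rng, 5), random_spectrum(rng, 5)
            v = kernel_value(s1, s2, variant, params)
            assert v == pytest.approx(brute_force_kernel(s1, s2, variant, params), rel=1e-12)

    @pytest.mark.parametrize("variant", ["peaks", "mloss", "diff"])
    def test_symmetric_and_positive(self, variant, rng, params):
        for _ in range(5):
            s1, s2 = random_spectrum(rng, 4), random_spectrum(rng, 6)
            v12 = kernel_value(s1, s2, variant, params)
            v21 = kernel_value(s2, s1, variant, params)
            assert v12 == pytest.approx(v21, rel=1e-12)
            # cross values are non-negative (may underflow to exactly 0 for
            # spectra with no peaks within a few sigma of each other);
            # self-similarity is strictly positive
            assert v12 >= 0
            assert kernel_value(s1, s1, variant, params) > 0

    def test_empty_spectrum_errors(self, params):
        with pytest.raises(ValueError):
            kernel_value(Spectrum(peaks=[]), Spectrum(peaks=[Peak(1.0, 1.0)]), "peaks", params)


class TestNormalizeAndCombine:
    def test_identical_spectra_give_variant_count(self, rng):
        s = random_spectrum(rng, 5)
        for variants in [("peaks",), ("peaks", "mloss"), ("peaks", "mloss", "diff")]:
            p = KernelParams(variants=variants)
            assert combined_kernel_value(s, s, p) == pytest.approx(len(variants))

    def test_peaks_only_pass_through(self, rng, params):
        s1, s2 = random_spectrum(rng, 4), random_spectrum(rng, 4)
        p = KernelParams(variants=("peaks",))
        v = combined_kernel_value(s1, s2, p)
        raw = kernel_value(s1, s2, "peaks", p)
        self1 = kernel_value(s1, s1, "peaks", p)
        self2 = kernel_value(s2, s2, "peaks", p)
        assert v == pytest.approx(raw / math.sqrt(self1 * self2))

    def test_bounded_by_variant_count(self, rng):
        p = KernelParams(variants=("peaks", "mloss", "diff"))
        for _ in range(10):
            s1, s2 = random_spectrum(rng, 5), random_spectrum(rng, 5)
            v = combined_kernel_value(s1, s2, p)
            assert 0 <= v <= len(p.variants) + 1e-12

    def test_normalized_value_in_unit_interval(self, rng):
        p = KernelParams(variants=("peaks",))
        for _ in range(10):
            s1, s2 = random_spectrum(rng, 5), random_spectrum(rng, 5)
            assert 0 <= combined_kernel_value(s1, s2, p) <= 1 + 1e-12

    def test_zero_self_similarity_errors(self, params):
        with pytest.raises(ValueError):
            normalize_and_combine({"peaks": 1.0}, {"peaks": 0.0}, {"peaks": 1.0},
                                  KernelParams(variants=("peaks",)))


class TestGram:
    def test_square_gram_properties(self, rng):
        spectra = [random_spectrum(rng, 5, spectrum_id=f"G{i}") for i in range(10)]
        g = gram_matrix(spectra)
        assert np.allclose(g.values, g.values.T, atol=1e-10)
        assert np.allclose(np.diagonal(g.values), len(g.params.variants), atol=1e-10)
        eig = np.linalg.eigvalsh(g.values)
        assert eig.min() >= -1e-9 * np.trace(g.values) / len(spectra)

    def test_cross_gram_is_block_of_pooled(self, rng, params):
        a = [random_spectrum(rng, 4, spectrum_id=f"A{i}") for i in range(4)]
        b = [random_spectrum(rng, 4, spectrum_id=f"B{i}") for i in range(3)]
        pooled = gram_matrix(a + b)
        cross = gram_matrix(a, b)
        assert np.allclose(cross.values, pooled.values[:4, 4:], atol=1e-12)

    def test_tsv_round_trip(self, rng, tmp_path):
        spectra = [random_spectrum(rng, 3, spectrum_id=f"T{i}") for i in range(4)]
        g = gram_matrix(spectra)
        path = tmp_path / "gram.tsv"
        g.to_tsv(path)
        g2 = GramMatrix.from_tsv(path)
        assert g2.row_ids == g.row_ids
        assert np.allclose(g2.values, g.values)

    def test_transformer_matches_gram_matrix(self, rng):
        spectra = [random_spectrum(rng, 4, spectrum_id=f"K{i}") for i in range(6)]
        tr = ProbabilityProductKernel()
        K = tr.fit_transform(spectra)
        assert np.allclose(K, gram_matrix(spectra, params=tr.params_).values)
        K2 = tr.transform(spectra[:2])
        assert np.allclose(K2, K[:2], atol=1e-10)


class TestVarianceEstimation:
    def test_identical_replicates_hit_floors(self, rng):
        s = random_spectrum(rng, 6)
        sm, si = estimate_peak_variances([[s, s, s]])
        assert sm == pytest.approx(1e-4)
        assert si == pytest.approx(1e-3)

    def test_recovers_known_mass_jitter(self, rng):
        true_sigma = 0.01
        base = random_spectrum(rng, 8)

        def jitter():
            return base.replace(
                peaks=[Peak(m + float(rng.normal(0, true_sigma)), i)
                       for m, i in zip(base.mz, base.intensity)]
            )

        groups = [[jitter(), jitter()] for _ in range(100)]
        sm, _ = estimate_peak_variances(groups)
        assert sm == pytest.approx(true_sigma, rel=0.2)

    def test_single_spectrum_group_errors(self, rng):
        with pytest.raises(ValueError):
            estimate_peak_variances([[random_spectrum(rng, 5)]])
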