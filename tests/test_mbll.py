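"""MBLL chromophore reconstruction: attenuation, pseudoinverse, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import nirstwin as nt
from nirstwin.mbll import AttenuationSeries


def forward_attenuation(system, conc, n_chromophores):
    """Independent forward model: dA = ln10*eps*dC * DPF * L per wavelength."""
    return (system.weighted_matrix(n_chromophores) @ conc) * (
        system.dpf[:, None] * system.pathlength
    )


class TestDeltaAttenuation:
    def test_reference_intensity_gives_zero(self):
        I = np.full((4, 10), 2.0)
        da = nt.delta_attenuation(I)
        assert np.all(da.delta_a == 0)

    def test_tenfold_intensity_drop_gives_ln10(self):
        I = np.array([[1.0, 0.1]])
        da = nt.delta_attenuation(I, wavelengths=(774.0,))
        assert da.delta_a[0, 1] == pytest.approx(np.log(10.0), rel=1e-12)

    def test_backlight_subtracted_before_the_log(self):
        b = 0.5
        I = np.array([[1.5, 1.0]])  # corrected: 1.0 -> 0.5, i.e. a factor 2
        da = nt.delta_attenuation(I, backlight=b, wavelengths=(774.0,))
        assert da.delta_a[0, 1] == pytest.approx(np.log(2.0), rel=1e-12)

    def test_nonpositive_corrected_intensity_names_the_sample(self):
        I = np.array([[1.0, 0.2]])
        with pytest.raises(ValueError, match="sample 1"):
            nt.delta_attenuation(I, backlight=0.3, wavelengths=(774.0,))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        logI=hnp.arrays(
            float,
            (2, 25),
            elements=st.floats(-1.0, 1.0, allow_nan=False),
        )
    )
    def test_previous_sample_mode_telescopes_to_baseline_mode(self, logI):
        I = np.exp(logI)
        base = nt.delta_attenuation(I, wavelengths=(774.0, 817.0))
        prev = nt.delta_attenuation(I, wavelengths=(774.0, 817.0), mode="previous")
        assert np.allclose(
            prev.to_baseline().delta_a, base.delta_a, atol=1e-12, rtol=0
        )


class TestPseudoinverse:
    def test_square_invertible_matrix_gives_ordinary_inverse(self, rng):
        M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        assert np.allclose(nt.pseudoinverse(M), np.linalg.inv(M), atol=1e-10)

    def test_tall_full_rank_matrix_left_inverse_property(self, rng):
        E = rng.standard_normal((4, 2))
        assert np.allclose(nt.pseudoinverse(E) @ E, np.eye(2), atol=1e-10)

    def test_agrees_with_normal_equations_oracle(self, rng):
        """For tall full-column-rank E the pseudoinverse solution equals the
        brute-force normal-equations solution (E'E)^-1 E' y."""
        E = rng.standard_normal((4, 3))
        y = rng.standard_normal((3, 4, 7))
        oracle = np.linalg.solve(E.T @ E, E.T @ y)
        assert np.allclose(nt.pseudoinverse(E) @ y, oracle, atol=1e-10)

    def test_rank_deficient_matrix_reports_condition_number(self):
        E = np.ones((4, 2))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            nt.pseudoinverse(E)


class TestReconstruct:
    @pytest.mark.parametrize("n_chrom", [2, 3])
    def test_forward_inverse_roundtrip_exact(self, default_system, n_chrom):
        conc = np.array([[1.0, 0.5, -0.2], [-0.3, 0.1, 0.4], [0.05, -0.02, 0.01]])[
            :n_chrom
        ]
        da = AttenuationSeries(
            default_system.wavelengths,
            forward_attenuation(default_system, conc, n_chrom),
        )
        rec = nt.reconstruct(da, default_system, n_chrom)
        assert np.allclose(rec, conc, atol=1e-10, rtol=0)

    def test_zero_attenuation_gives_zero_concentrations(self, default_system):
        da = AttenuationSeries(default_system.wavelengths, np.zeros((4, 5)))
        assert np.all(nt.reconstruct(da, default_system, 3) == 0)

    def test_least_squares_residual_orthogonal_to_columns(self, default_system, rng):
        """Off-range attenuation: the returned concentrations solve the
        normal equations (residual orthogonal to the weighted columns)."""
        y = rng.standard_normal((4, 6))
        da = AttenuationSeries(default_system.wavelengths, y)
        conc = nt.reconstruct(da, default_system, 2)
        Ew = default_system.weighted_matrix(2)
        resid = y / default_system.dpf[:, None] - Ew @ conc * default_system.pathlength
        assert np.allclose(Ew.T @ resid, 0.0, atol=1e-10)

    def test_wavelength_count_mismatch_rejected(self, default_system):
        da = AttenuationSeries((774.0, 817.0), np.zeros((2, 5)))
        with pytest.raises(ValueError, match="wavelength"):
            nt.reconstruct(da, default_system)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
    )
    def test_linearity(self, default_system, a, b):
        rng = np.random.default_rng(99)
        d1 = rng.standard_normal((4, 5))
        d2 = rng.standard_normal((4, 5))
        rec = lambda d: nt.reconstruct(
            AttenuationSeries(default_system.wavelengths, d), default_system
        )
        assert np.allclose(
            rec(a * d1 + b * d2), a * rec(d1) + b * rec(d2), atol=1e-8
        )


class TestSubsetReconstruct:
    def test_full_subset_equals_reconstruct(self, default_system, rng):
        y = rng.standard_normal((4, 5))
        da = AttenuationSeries(default_system.wavelengths, y)
        full = nt.reconstruct(da, default_system, 2)
        sub = nt.subset_reconstruct(da, default_system, default_system.wavelengths, 2)
        assert np.allclose(full, sub, atol=1e-12)

    def test_two_wavelength_subset_exact_on_noiseless_data(self, default_system):
        conc = np.array([[0.8, -0.4], [-0.2, 0.6]])
        da = AttenuationSeries(
            default_system.wavelengths, forward_attenuation(default_system, conc, 2)
        )
        sub = nt.subset_reconstruct(da, default_system, (770.0, 850.0), 2)
        assert np.allclose(sub, conc, atol=1e-10)

    def test_nominal_wavelengths_alias_measured_peaks(self, default_system):
        assert default_system.wavelength_indices((770.0, 850.0)) == [0, 2]
        assert default_system.wavelength_indices((774.0, 865.0)) == [0, 2]

    def test_subset_smaller_than_chromophore_count_rejected(self, default_system):
        da = AttenuationSeries(default_system.wavelengths, np.zeros((4, 3)))
        with pytest.raises(ValueError):
            nt.subset_reconstruct(da, default_system, (774.0,), 2)

    def test_four_wavelengths_beat_two_under_iid_noise(self, default_system, rng):
        """Monte-Carlo with 1e4 replicates of iid attenuation noise: the
        four-wavelength least-squares estimate has lower variance than the
        two-wavelength exact solve for both hemoglobins."""
        n_rep = 10_000
        noise = 1e-3 * rng.standard_normal((4, n_rep))
        da = AttenuationSeries(default_system.wavelengths, noise)
        c2 = nt.subset_reconstruct(da, default_system, (770.0, 850.0), 2)
        c4 = nt.reconstruct(da, default_system, 2)
        assert c4.var(axis=1)[0] < c2.var(axis=1)[0]
        assert c4.var(axis=1)[1] < c2.var(axis=1)[1]
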