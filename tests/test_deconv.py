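"""Optimal-transport distance and deconvolution LP, against generic-LP oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from otmsi.chem import TheoreticalSpectrum, isotopic_envelope, parse_formula
from otmsi.deconv import (
    DeconvolutionConfig,
    WassersteinDeconvolver,
    deconvolve_dataset,
    fit_proportions,
    ot_distance,
)
from otmsi.spectra import MSIDataset, Spectrum


def stick_spectrum(mz, intensity):
    order = np.argsort(mz)
    return Spectrum(np.asarray(mz)[order], np.asarray(intensity)[order], "centroid")


def transport_lp_oracle(a_mz, a_w, b_mz, b_w):
    """Full dense transport LP between two unit measures (generic solver)."""
    n, m = len(a_mz), len(b_mz)
    cost = np.abs(np.subtract.outer(a_mz, b_mz)).ravel()
    A_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1
        A_eq.append(row)
    for j in range(m):
        row = np.zeros(n * m)
        row[j::m] = 1
        A_eq.append(row)
    b_eq = np.concatenate([a_w, b_w])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def dense_deconv_oracle(exp_mz, exp_w, components, km, kc):
    """The full (unpruned, dense) deconvolution LP built independently."""
    comp_mz = np.concatenate([c.mz for c in components])
    comp_p = np.concatenate([c.intensity for c in components])
    comp_id = np.concatenate([np.full(len(c.mz), i) for i, c in enumerate(components)])
    n, m, k = len(exp_mz), len(comp_mz), len(components)
    n_var = n * m + n + m + k  # plan, exp trash, theo trash, scales
    cost = np.concatenate(
        [
            np.abs(np.subtract.outer(exp_mz, comp_mz)).ravel(),
            np.full(n, km),
            np.full(m, kc),
            np.zeros(k),
        ]
    )
    A_eq = np.zeros((n + m, n_var))
    for i in range(n):
        A_eq[i, i * m : (i + 1) * m] = 1
        A_eq[i, n * m + i] = 1
    for j in range(m):
        A_eq[n + j, j::m][: n] = 1
        A_eq[n + j, n * m + n + j] = 1
        A_eq[n + j, n * m + n + m + comp_id[j]] = -comp_p[j]
    b_eq = np.concatenate([exp_w, np.zeros(m)])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success
    return res


class TestOtDistance:
    def test_point_mass_translation(self):
        a = stick_spectrum([100.0], [1.0])
        b = stick_spectrum([100.5], [1.0])
        assert ot_distance(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_identity(self):
        a = stick_spectrum([100.0, 101.0, 103.0], [0.2, 0.3, 0.5])
        assert ot_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(1)
        specs = [
            stick_spectrum(np.sort(rng.uniform(100, 110, 4)), rng.dirichlet(np.ones(4)))
            for _ in range(3)
        ]
        a, b, c = specs
        assert ot_distance(a, b) == pytest.approx(ot_distance(b, a), abs=1e-12)
        assert ot_distance(a, c) <= ot_distance(a, b) + ot_distance(b, c) + 1e-12

    def test_matches_transport_lp_on_three_peaks(self):
        a = stick_spectrum([100.0, 101.0, 102.0], [0.5, 0.25, 0.25])
        b = stick_spectrum([100.2, 101.5, 103.0], [0.3, 0.3, 0.4])
        oracle = transport_lp_oracle(a.mz, a.intensity, b.mz, b.intensity)
        assert ot_distance(a, b) == pytest.approx(oracle, abs=1e-10)


@pytest.fixture(scope="module")
def lipid_envelopes():
    return [
        isotopic_envelope(parse_formula("C46H90NO8PK", 1), label="A"),
        isotopic_envelope(parse_formula("C30H50", 0), label="B"),  # ~410 Da
    ]


class TestFitProportions:
    CFG = DeconvolutionConfig(0.012, 0.016)

    def test_perfect_self_fit(self, lipid_envelopes):
        mu = lipid_envelopes[0]
        exp = stick_spectrum(mu.mz, mu.intensity)
        r = fit_proportions(exp, [mu], self.CFG)
        assert r.proportions[0] == pytest.approx(1.0, abs=1e-8)
        assert r.unexplained_experimental == pytest.approx(0.0, abs=1e-8)
        assert r.transport_cost == pytest.approx(0.0, abs=1e-8)

    def test_exact_recovery_disjoint_mixture(self, lipid_envelopes):
        mu1, mu2 = lipid_envelopes
        exp = stick_spectrum(
            np.concatenate([mu1.mz, mu2.mz]),
            np.concatenate([0.6 * mu1.intensity, 0.4 * mu2.intensity]),
        )
        r = fit_proportions(exp, [mu1, mu2], self.CFG)
        assert r.proportions == pytest.approx([0.6, 0.4], abs=1e-6)
        assert r.unexplained_experimental == pytest.approx(0.0, abs=1e-6)

    def test_stray_peak_is_trashed(self, lipid_envelopes):
        mu = lipid_envelopes[0]
        exp = stick_spectrum(
            np.concatenate([mu.mz, [mu.mz[-1] + 1.0]]),
            np.concatenate([0.9 * mu.intensity, [0.1]]),
        )
        r = fit_proportions(exp, [mu], self.CFG)
        assert r.proportions[0] == pytest.approx(0.9, abs=1e-6)
        assert r.unexplained_experimental == pytest.approx(0.1, abs=1e-6)

    def test_requires_normalized_input(self, lipid_envelopes):
        exp = stick_spectrum([854.6], [2.0])
        with pytest.raises(ValueError):
            fit_proportions(exp, lipid_envelopes, self.CFG)

    def test_empty_spectrum_flagged_not_raised(self, lipid_envelopes):
        empty = Spectrum(np.empty(0), np.empty(0), "centroid")
        r = fit_proportions(empty, lipid_envelopes, self.CFG)
        assert r.degenerate
        assert np.all(r.proportions == 0)

    def test_translation_invariance(self, lipid_envelopes):
        mu1, mu2 = lipid_envelopes
        exp = stick_spectrum(
            np.concatenate([mu1.mz, mu2.mz]),
            np.concatenate([0.7 * mu1.intensity, 0.3 * mu2.intensity]),
        )
        r0 = fit_proportions(exp, [mu1, mu2], self.CFG)
        delta = 5.0
        shifted = [
            TheoreticalSpectrum(c.mz + delta, c.intensity, c.label)
            for c in (mu1, mu2)
        ]
        exp_shifted = stick_spectrum(exp.mz + delta, exp.intensity)
        r1 = fit_proportions(exp_shifted, shifted, self.CFG)
        assert r1.proportions == pytest.approx(r0.proportions, abs=1e-8)

    def test_trash_monotone_in_kappa_mixture(self, lipid_envelopes):
        mu = lipid_envelopes[0]
        # half the signal sits 0.02 Da off every theoretical peak
        exp = stick_spectrum(
            np.concatenate([mu.mz, mu.mz + 0.02]),
            np.concatenate([0.5 * mu.intensity, 0.5 * mu.intensity]),
        )
        trashed = [
            fit_proportions(
                exp, [mu], DeconvolutionConfig(km, 0.016)
            ).unexplained_experimental
            for km in (0.005, 0.012, 0.05, 0.5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(trashed, trashed[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_objective_matches_dense_lp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_exp = rng.integers(2, 7)
        exp = stick_spectrum(
            np.sort(rng.uniform(100, 102, n_exp)), rng.dirichlet(np.ones(n_exp))
        )
        comps = []
        for label in "ab":
            k = rng.integers(1, 4)
            comps.append(
                TheoreticalSpectrum(
                    np.sort(rng.uniform(100, 102, k)),
                    rng.dirichlet(np.ones(k)),
                    label,
                )
            )
        km, kc = 0.3, 0.4
        r = fit_proportions(exp, comps, DeconvolutionConfig(km, kc))
        oracle = dense_deconv_oracle(exp.mz, exp.intensity, comps, km, kc)
        assert r.objective == pytest.approx(oracle.fun, abs=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_proportions_and_unexplained_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        exp = stick_spectrum(
            np.sort(rng.uniform(850, 860, n)), rng.dirichlet(np.ones(n))
        )
        comp = TheoreticalSpectrum(
            np.sort(rng.uniform(850, 860, 3)), rng.dirichlet(np.ones(3)), "c"
        )
        r = fit_proportions(exp, [comp], DeconvolutionConfig(0.1, 0.2))
        assert r.proportions.sum() + r.unexplained_experimental == pytest.approx(
            1.0, abs=1e-6
        )
        assert np.all(r.proportions >= -1e-12)


class TestDeconvolveDataset:
    def test_constant_dataset_gives_constant_images(self, lipid_envelopes):
        mu = lipid_envelopes[0]
        s = stick_spectrum(mu.mz, 5.0 * mu.intensity)
        ds = MSIDataset(
            [(x, y, s) for x in range(3) for y in range(2)], 3, 2, "centroid"
        )
        images = deconvolve_dataset(ds, [mu], DeconvolutionConfig(0.1, 0.2))
        assert np.allclose(images[mu.label].values, 5.0, atol=1e-6)

    def test_single_pixel_matches_direct_fit(self, lipid_envelopes):
        mu1, mu2 = lipid_envelopes
        s = stick_spectrum(
            np.concatenate([mu1.mz, mu2.mz]),
            np.concatenate([0.8 * mu1.intensity, 0.2 * mu2.intensity]),
        )
        ds = MSIDataset([(0, 0, s)], 1, 1, "centroid")
        cfg = DeconvolutionConfig(0.012, 0.016)
        images = deconvolve_dataset(ds, [mu1, mu2], cfg, scale="proportion")
        direct = fit_proportions(s, [mu1, mu2], cfg)
        assert images["A"].values[0, 0] == pytest.approx(direct.proportions[0], abs=1e-9)
        assert images["B"].values[0, 0] == pytest.approx(direct.proportions[1], abs=1e-9)

    def test_zero_pixel_flagged(self, lipid_envelopes):
        mu = lipid_envelopes[0]
        good = stick_spectrum(mu.mz, mu.intensity)
        empty = Spectrum(np.empty(0), np.empty(0), "centroid")
        ds = MSIDataset([(0, 0, good), (1, 0, empty)], 2, 1, "centroid")
        images = deconvolve_dataset(ds, [mu], DeconvolutionConfig(0.1, 0.2))
        assert images[mu.label].values[0, 1] == 0.0
        assert not images[mu.label].mask[0, 1]
        assert images[mu.label].mask[0, 0]


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self, lipid_envelopes):
        dec = WassersteinDeconvolver(lipid_envelopes, 0.1, 0.2)
        params = dec.get_params()
        assert params["kappa_mixture"] == 0.1
        dec.set_params(kappa_mixture=0.5)
        assert dec.kappa_mixture == 0.5

    def test_transform_rows_sum_to_one(self, lipid_envelopes):
        mu1, mu2 = lipid_envelopes
        exp = stick_spectrum(
            np.concatenate([mu1.mz, mu2.mz]),
            np.concatenate([0.5 * mu1.intensity, 0.5 * mu2.intensity]),
        )
        dec = WassersteinDeconvolver(lipid_envelopes, 0.012, 0.016).fit()
        out = dec.transform([exp, exp])
        assert out.shape == (2, 3)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_fit_requires_components(self):
        with pytest.raises(ValueError):
            WassersteinDeconvolver(None).fit()
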