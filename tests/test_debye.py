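import numpy as np
import pytest

from saxsfit.core import Atom, BeadModel, ScatteringCurve, StructureModel
from saxsfit.debye import (add_hydration_layer, coarse_grain, debye_intensity,
                           fit_scale_background)
from saxsfit.tables import RESIDUE_TABLE, SOLVENT_EDENS
from saxsfit.validation import sphere_form_factor
from saxsfit.synth import grid_sphere_beads


def _random_blob(n=300, scale=20.0, seed=0, sig=2.0):
    rng = np.random.default_rng(seed)
    return BeadModel(rng.normal(scale=scale, size=(n, 3)),
                     np.ones(n), np.full(n, sig))


class TestDebyeIntensity:
    def test_two_point_interference_exact(self):
        bm = BeadModel(np.array([[0.0, 0, 0], [10.0, 0, 0]]),
                       np.ones(2), np.zeros(2))
        q = np.array([0.0, 0.05, np.pi / 10.0])
        I = debye_intensity(bm, q).I
        expected = 2.0 * (1.0 + np.sinc(q * 10.0 / np.pi))
        np.testing.assert_allclose(I, expected, rtol=1e-12)
        assert I[2] == pytest.approx(2.0, abs=1e-12)

    def test_forward_scattering_sum_rule(self):
        bm = _random_blob(n=200)
        I0 = debye_intensity(bm, np.array([0.0])).I[0]
        assert I0 == pytest.approx(bm.b_eff.sum() ** 2, rel=1e-12)

    def test_sphere_form_factor_to_first_minimum(self):
        beads = grid_sphere_beads(50.0, spacing=2.5)
        q = np.linspace(0.005, 0.90 * 4.493 / 50.0, 40)
        I = debye_intensity(beads, q, method="hist", dr=0.25).I
        Iref = beads.b_eff.sum() ** 2 * sphere_form_factor(q, 50.0)
        assert np.max(np.abs(I / Iref - 1.0)) < 0.02

    def test_hist_converges_to_exact(self):
        bm = _random_blob(n=300)
        q = np.linspace(0.0, 0.35, 80)
        Ie = debye_intensity(bm, q, method="exact").I
        errs = []
        for dr in (2.0, 1.0, 0.5, 0.25):
            Ih = debye_intensity(bm, q, method="hist", dr=dr).I
            errs.append(np.max(np.abs(Ih / Ie - 1.0)))
        assert all(a > b for a, b in zip(errs, errs[1:]))  # monotone decrease
        assert errs[-1] < 0.005

    def test_rigid_transform_invariance(self):
        bm = _random_blob(n=150)
        q = np.linspace(0.01, 0.3, 40)
        I1 = debye_intensity(bm, q).I
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = BeadModel(bm.positions @ R.T + np.array([5.0, -3.0, 11.0]),
                          bm.b_eff, bm.gauss_width)
        I2 = debye_intensity(moved, q).I
        np.testing.assert_allclose(I2, I1, rtol=1e-10)

    def test_nonnegative_for_uniform_sign(self):
        bm = _random_blob(n=100, seed=3)
        I = debye_intensity(bm, np.linspace(0.0, 1.0, 120)).I
        assert np.all(I >= 0)

    def test_empty_model_raises(self):
        bm = _random_blob(n=5)
        with pytest.raises(ValueError):
            debye_intensity(BeadModel(bm.positions[:0].reshape(0, 3),
                                      np.zeros(0), np.zeros(0)),
                            np.array([0.01]))


class TestCoarseGrain:
    def _poly(self, resname, n=10):
        return StructureModel([
            Atom("A", i + 1, resname, "CA", "C", (3.8 * i, 0.0, 0.0))
            for i in range(n)])

    def test_polyglycine_uniform_beads(self):
        beads = coarse_grain(self._poly("GLY"))
        assert len(beads) == 10
        assert np.ptp(beads.b_eff) == 0.0

    def test_alanine_contrast_matches_table(self):
        beads = coarse_grain(self._poly("ALA", n=1))
        ne, vol, _ = RESIDUE_TABLE["ALA"]
        assert beads.b_eff[0] == pytest.approx(ne - SOLVENT_EDENS * vol)

    def test_unknown_residue_falls_back(self):
        beads = coarse_grain(self._poly("XYZ", n=3))
        assert len(beads) == 3
        assert np.all(np.isfinite(beads.b_eff))

    def test_atom_level_one_bead_per_heavy_atom(self):
        st = StructureModel([
            Atom("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            Atom("A", 1, "ALA", "N", "N", (1.5, 0, 0)),
            Atom("A", 1, "ALA", "O", "O", (2.5, 0, 0))])
        beads = coarse_grain(st, level="atom")
        assert len(beads) == 3
        assert beads.b_eff[0] != beads.b_eff[1]


class TestHydration:
    def test_null_layer_leaves_intensity_unchanged(self):
        bm = _random_blob(n=60, scale=8.0, seed=2)
        hyd = add_hydration_layer(bm, contrast_fraction=0.0)
        q = np.linspace(0.01, 0.3, 30)
        np.testing.assert_allclose(debye_intensity(hyd, q).I,
                                   debye_intensity(bm, q).I, rtol=1e-9)

    def test_single_bead_shell_at_expected_radius(self):
        bm = BeadModel(np.zeros((1, 3)), np.ones(1), np.array([5.0]))
        hyd = add_hydration_layer(bm, thickness=3.0)
        shell = hyd.positions[hyd.kind == "hydration"]
        r = np.linalg.norm(shell, axis=1)
        np.testing.assert_allclose(r, np.sqrt(5.0) * 5.0 + 3.0, rtol=1e-6)

    def test_extended_conformer_has_more_shell_beads(self):
        compact = _random_blob(n=80, scale=8.0, seed=4, sig=2.0)
        extended = BeadModel(compact.positions * np.array([4.0, 1.0, 1.0]),
                             compact.b_eff, compact.gauss_width)
        n_c = add_hydration_layer(compact).meta["n_hydration"]
        n_e = add_hydration_layer(extended).meta["n_hydration"]
        assert n_e >= n_c

    def test_bad_thickness_raises(self):
        with pytest.raises(ValueError):
            add_hydration_layer(_random_blob(n=10), thickness=0.0)


class TestFitScaleBackground:
    def test_exact_linear_recovery(self):
        q = np.linspace(0.01, 0.3, 50)
        im = np.exp(-q * 10)
        model = ScatteringCurve(q, im, np.zeros_like(q),
                                meta={"sigma_is_placeholder": True})
        data = ScatteringCurve(q, 3.0 * im + 7.0, np.ones_like(q))
        fit = fit_scale_background(model, data)
        assert fit.scale == pytest.approx(3.0, rel=1e-9)
        assert fit.background == pytest.approx(7.0, rel=1e-9)
        assert fit.chi2_red == pytest.approx(0.0, abs=1e-18)

    def test_chi2_expectation_under_noise(self):
        q = np.linspace(0.01, 0.3, 100)
        im = 100 * np.exp(-(q * 30) ** 2 / 3)
        sig = 0.02 * im
        model = ScatteringCurve(q, im, np.zeros_like(q),
                                meta={"sigma_is_placeholder": True})
        rng = np.random.default_rng(0)
        chis = []
        for _ in range(200):
            data = ScatteringCurve(q, im + rng.normal(size=q.size) * sig, sig)
            chis.append(fit_scale_background(model, data).chi2_red)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.15)

    def test_uncorrelated_model_large_chi2(self):
        q = np.linspace(0.01, 0.3, 50)
        model = ScatteringCurve(q, np.sin(40 * q) + 2.0, np.zeros_like(q),
                                meta={"sigma_is_placeholder": True})
        data = ScatteringCurve(q, 100 * np.exp(-(q * 30) ** 2 / 3),
                               0.01 * np.ones_like(q))
        assert fit_scale_background(model, data).chi2_red > 100

    def test_too_few_points_raises(self):
        q = np.array([0.01, 0.02])
        c = ScatteringCurve(q, q * 0 + 1, q * 0 + 1)
        with pytest.raises(ValueError):
            fit_scale_background(c, c)
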