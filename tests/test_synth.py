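import numpy as np
import pytest

from saxsfit.core import BeadModel, StructureModel
from saxsfit.debye import coarse_grain, debye_intensity, fit_scale_background
from saxsfit.mapfit import map_to_dummy_atoms
from saxsfit.synth import (SyntheticSpec, grid_sphere_beads, make_model,
                           make_toy_map, simulate_curve)


class TestMakeModel:
    def test_sphere_rg(self):
        spec = SyntheticSpec(shape="sphere", radius=50.0, n_beads=5000, seed=1)
        beads = make_model(spec)
        assert beads.radius_of_gyration() == pytest.approx(
            np.sqrt(3.0 / 5.0) * 50.0, rel=0.01)

    def test_seed_determinism(self):
        spec = SyntheticSpec(shape="multidomain_dimer", n_domains=2,
                             n_res_domain=30, n_linker=5, seed=9)
        m1, m2 = make_model(spec), make_model(spec)
        np.testing.assert_array_equal(m1.xyz, m2.xyz)

    def test_dumbbell_extent(self):
        spec = SyntheticSpec(shape="dumbbell", radius=20.0, separation=80.0,
                             n_beads=2000, seed=0)
        beads = make_model(spec)
        extent = np.ptp(beads.positions[:, 0])
        assert extent == pytest.approx(80.0 + 2 * 20.0, rel=0.05)

    def test_dimer_chains_and_residue_types(self):
        spec = SyntheticSpec(shape="multidomain_dimer", n_domains=2,
                             n_res_domain=30, n_linker=5, seed=2)
        st = make_model(spec)
        assert isinstance(st, StructureModel)
        assert st.chains == ["A", "B"]
        beads = coarse_grain(st)  # residue-typed, so this must work
        assert len(beads) == len(st.atoms)

    def test_unknown_shape_raises(self):
        with pytest.raises(ValueError):
            make_model(SyntheticSpec(shape="torus"))


class TestSimulateCurve:
    def test_zero_noise_chi2_zero(self):
        spec = SyntheticSpec(shape="sphere", radius=25.0, n_beads=500,
                             seed=4, noise_sigma0=0.0, n_q=60, q_max=0.25)
        beads = make_model(spec)
        curve = simulate_curve(beads, spec)
        model = debye_intensity(beads, curve.q)
        fit = fit_scale_background(model, curve)
        assert fit.chi2_red == pytest.approx(0.0, abs=1e-6)
        assert fit.scale == pytest.approx(1.0, rel=1e-9)

    def test_noise_model_calibrated(self):
        """Pooled χ² of the generating model over seeds ≈ 1."""
        spec0 = SyntheticSpec(shape="sphere", radius=25.0, n_beads=400,
                              seed=0, n_q=80, q_max=0.3)
        beads = make_model(spec0)
        model = debye_intensity(beads, spec0.q_grid())
        chis = []
        for seed in range(40):
            spec = SyntheticSpec(shape="sphere", radius=25.0, n_beads=400,
                                 seed=seed, n_q=80, q_max=0.3)
            curve = simulate_curve(beads, spec)
            chis.append(fit_scale_background(model, curve).chi2_red)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.15)

    def test_oligomer_inflates_forward_scattering(self):
        spec = SyntheticSpec(shape="sphere", radius=25.0, n_beads=400, seed=1,
                             noise_sigma0=0.0, q_min=1e-4)
        beads = make_model(spec)
        plain = simulate_curve(beads, spec)
        spec_o = SyntheticSpec(shape="sphere", radius=25.0, n_beads=400, seed=1,
                               noise_sigma0=0.0, q_min=1e-4,
                               oligomer=(0.65, 65.0))
        mixed = simulate_curve(beads, spec_o)
        assert mixed.I[0] / plain.I[0] == pytest.approx(1.65, rel=1e-3)

    def test_sigma_strictly_positive(self):
        spec = SyntheticSpec(shape="sphere", radius=25.0, n_beads=300, seed=2)
        curve = simulate_curve(make_model(spec), spec)
        assert np.all(curve.sigma > 0)


class TestToyMap:
    def test_single_bead_max_at_bead_voxel(self):
        beads = BeadModel(np.array([[3.0, -2.0, 7.0]]), np.ones(1), np.ones(1))
        dmap = make_toy_map(beads, voxel_size=2.0, blur_sigma=2.0)
        idx = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
        center = dmap.origin + np.array(idx) * dmap.voxel_size
        assert np.linalg.norm(center - beads.positions[0]) <= 2.0

    def test_threshold_rg_close_to_bead_rg(self):
        beads = grid_sphere_beads(30.0, spacing=3.0)
        dmap = make_toy_map(beads, voxel_size=3.0, blur_sigma=3.0)
        mask = dmap.grid >= 0.5 * dmap.grid.max()
        pts = dmap.voxel_centers(mask)
        rg = np.sqrt(np.mean(np.sum((pts - pts.mean(0)) ** 2, axis=1)))
        assert rg == pytest.approx(beads.radius_of_gyration(), rel=0.10)

    def test_roundtrip_intensity_fidelity(self):
        """beads → map → dummy atoms reproduces I(q) at low-to-mid q
        (volume-matched threshold, the standard cryo-EM contouring choice)."""
        beads = grid_sphere_beads(30.0, spacing=3.0)
        dmap = make_toy_map(beads, voxel_size=1.5, blur_sigma=1.5)
        n_target = int(4.0 / 3.0 * np.pi * 30.0 ** 3 / 1.5 ** 3)
        thr = np.sort(dmap.grid.ravel())[::-1][n_target]
        dummies = map_to_dummy_atoms(dmap, thr, max_beads=60000)
        q = np.linspace(0.005, 0.1, 30)
        I1 = debye_intensity(beads, q, method="hist", dr=0.3).I
        I2 = debye_intensity(dummies, q, method="hist", dr=0.3).I
        np.testing.assert_allclose(I2 / I2[0], I1 / I1[0], rtol=0.03)

    def test_bad_voxel_size_raises(self):
        beads = BeadModel(np.zeros((1, 3)), np.ones(1), np.ones(1))
        with pytest.raises(ValueError):
            make_toy_map(beads, voxel_size=0.0)
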