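import numpy as np
import pytest

from saxsfit.core import Atom, BeadModel, ScatteringCurve, StructureModel
from saxsfit.debye import debye_intensity
from saxsfit.rigidbody import (OligomerParams, RBConfig, _fit_oligomer,
                               apply_oligomer, decompose, objective,
                               perturb_body_about_hinge, rb_refine,
                               superposed_rmsd)
from saxsfit.synth import SyntheticSpec, make_model, multidomain_dimer_segments


def _chain(n=20, chain="A", start=1):
    return [Atom(chain, start + i, "ALA", "CA", "C", (3.8 * i, 0.0, 0.0))
            for i in range(n)]


class TestDecompose:
    def test_single_body_no_springs(self):
        st = StructureModel(_chain(30))
        d = decompose(st, [("A", (1, 30))])
        assert d.K == 1 and d.springs == []

    def test_contiguous_cut_single_spring(self):
        st = StructureModel(_chain(20))
        d = decompose(st, [("A", (1, 10)), ("A", (11, 20))])
        assert d.K == 2
        assert len(d.springs) == 1
        a, b, rest, slack = d.springs[0]
        assert (a, b) == (9, 10)
        assert rest == pytest.approx(3.8)
        assert slack == pytest.approx(1.5)

    def test_gap_scales_rest_and_slack(self):
        atoms = _chain(10) + [Atom("A", 14 + i, "ALA", "CA", "C",
                                   (3.8 * (13 + i), 0, 0)) for i in range(10)]
        st = StructureModel(atoms)
        d = decompose(st, [("A", (1, 10)), ("A", (14, 23))])
        a, b, rest, slack = d.springs[0]
        assert rest == pytest.approx(3.8 * 4)
        assert slack == pytest.approx(1.5 * 4)

    def test_double_assignment_raises(self):
        st = StructureModel(_chain(20))
        with pytest.raises(ValueError):
            decompose(st, [("A", (1, 12)), ("A", (10, 20))])

    def test_uncovered_residues_assigned_to_nearest(self):
        st = StructureModel(_chain(20))
        d = decompose(st, [("A", (1, 8)), ("A", (13, 20))])
        assert np.all(d.beads.body_id > 0)

    def test_dimer_cut_into_bodies_springs_intra_chain_only(self):
        spec = SyntheticSpec(shape="multidomain_dimer", n_domains=2,
                             n_res_domain=40, n_linker=6, seed=0)
        st = make_model(spec)
        d = decompose(st, multidomain_dimer_segments(spec))
        assert d.K == 4
        assert len(d.springs) == 2  # one cut per chain
        for a, b, _, _ in d.springs:
            assert st.atoms[a].chain == st.atoms[b].chain


class TestObjective:
    @pytest.fixture()
    def two_body(self):
        st = StructureModel(_chain(40))
        return decompose(st, [("A", (1, 20)), ("A", (21, 40))])

    def _data(self, decomp):
        q = np.linspace(0.01, 0.25, 60)
        I = debye_intensity(decomp.beads, q).I
        return ScatteringCurve(q, I, 0.01 * I)

    def test_unperturbed_has_zero_penalties(self, two_body):
        data = self._data(two_body)
        chi2, e_conn, e_ev, total = objective(two_body, data)
        assert e_conn == 0.0
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_separation_beyond_slack_quadratic(self, two_body):
        data = self._data(two_body)
        pos = two_body.beads.positions
        pos[two_body.beads.body_id == 2] += np.array([25.3, 0, 0])
        _, e_conn, _, _ = objective(two_body, data)
        # spring stretched 25.3 Å beyond rest+slack (3.8+1.5) + original 3.8
        d_new = 3.8 + 25.3
        assert e_conn == pytest.approx((d_new - 5.3) ** 2)

    def test_overlap_penalty_monotone_in_depth(self, two_body):
        data = self._data(two_body)
        base = two_body.beads.positions.copy()
        evs = []
        for shift in (16.0, 36.0, 66.0):  # increasingly deep overlaps
            two_body.beads.positions[:] = base
            two_body.beads.positions[two_body.beads.body_id == 2] -= \
                np.array([shift, 0, 0])
            evs.append(objective(two_body, data)[2])
        two_body.beads.positions[:] = base
        assert evs[0] <= evs[1] <= evs[2]
        assert evs[2] > 0


class TestOligomer:
    def test_zero_fraction_identity(self):
        q = np.linspace(0.0, 0.3, 50)
        I = np.exp(-q * 5)
        np.testing.assert_array_equal(
            apply_oligomer(I, q, OligomerParams(0.0, 65.0)), I)

    def test_forward_scattering_doubles_at_full_fraction(self):
        I0 = apply_oligomer(np.array([4.0]), np.array([0.0]),
                            OligomerParams(1.0, 65.0))
        assert I0[0] == pytest.approx(8.0)

    def test_first_node_of_oscillation(self):
        """On flat I_unit = 1, the modulation crosses 1 at q = π/d."""
        d = 65.0
        q = np.linspace(1e-4, 0.3, 20000)
        I = apply_oligomer(np.ones_like(q), q, OligomerParams(0.65, d))
        crossings = q[np.flatnonzero(np.diff(np.sign(I - 1.0)))]
        assert crossings[0] == pytest.approx(np.pi / d, rel=1e-3)

    def test_structure_factor_decays_at_high_q(self):
        q = np.linspace(5.0, 10.0, 50)
        I = apply_oligomer(np.ones_like(q), q, OligomerParams(0.65, 65.0))
        np.testing.assert_allclose(I, 1.0, atol=0.01)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            OligomerParams(1.2, 65.0)
        with pytest.raises(ValueError):
            OligomerParams(0.5, -1.0)

    def test_direct_fit_recovers_parameters(self):
        """Grid + simplex (f, d) fit on noisy modulated data."""
        q = np.linspace(0.005, 0.3, 150)
        I_unit = 1000.0 * np.exp(-(q * 35.0) ** 2 / 3.0) + 5.0
        truth = OligomerParams(0.65, 65.0)
        I = apply_oligomer(I_unit, q, truth)
        sig = 0.01 * I
        rng = np.random.default_rng(3)
        data = ScatteringCurve(q, I + rng.normal(size=q.size) * sig, sig)
        oligo, fit = _fit_oligomer(I_unit, data, background=False)
        assert oligo.f == pytest.approx(0.65, abs=0.05)
        assert oligo.d == pytest.approx(65.0, abs=5.0)
        assert fit.chi2_red < 1.5


class TestRefine:
    def test_self_consistency_stays_at_optimum(self):
        """Data simulated from the start model: refinement keeps χ² ≈ 0 and
        the bodies essentially in place."""
        spec = SyntheticSpec(shape="multidomain_chain", n_domains=2,
                             n_res_domain=30, n_linker=6, seed=1,
                             n_q=60, q_max=0.25, noise_sigma0=0.0)
        st = make_model(spec)
        dec = decompose(st, multidomain_dimer_segments(spec))
        q = spec.q_grid()
        I = debye_intensity(dec.beads, q).I
        data = ScatteringCurve(q, I, 0.005 * I)
        cfg = RBConfig(n_runs=2, n_steps=300, seed=0, T_start=0.05,
                       T_end=0.001, start_rot_deg=0.0, fit_background=False,
                       fixed_bodies=(1,))
        res = rb_refine(dec, data, cfg)
        assert res.best.chi2_red < 0.01
        rmsd = superposed_rmsd(res.best.positions, dec.beads.positions)
        assert rmsd < 1.0

    def test_identical_seeds_identical_trajectories(self):
        spec = SyntheticSpec(shape="multidomain_chain", n_domains=2,
                             n_res_domain=25, n_linker=5, seed=2,
                             n_q=40, q_max=0.2)
        st = make_model(spec)
        dec = decompose(st, multidomain_dimer_segments(spec))
        from saxsfit.synth import simulate_curve
        data = simulate_curve(st, spec)
        cfg = RBConfig(n_runs=2, n_steps=150, seed=7)
        r1 = rb_refine(dec, data, cfg)
        r2 = rb_refine(dec, data, cfg)
        np.testing.assert_array_equal(r1.best.positions, r2.best.positions)
        assert [a.chi2_red for a in r1.runs] == [a.chi2_red for a in r2.runs]

    def test_best_run_minimises_total(self):
        spec = SyntheticSpec(shape="multidomain_chain", n_domains=2,
                             n_res_domain=25, n_linker=5, seed=2,
                             n_q=40, q_max=0.2)
        st = make_model(spec)
        dec = decompose(st, multidomain_dimer_segments(spec))
        from saxsfit.synth import simulate_curve
        data = simulate_curve(st, spec)
        res = rb_refine(dec, data, RBConfig(n_runs=3, n_steps=150, seed=1))
        assert res.best.total == min(r.total for r in res.runs)


def test_hinge_perturbation_preserves_connectivity():
    spec = SyntheticSpec(shape="multidomain_chain", n_domains=2,
                         n_res_domain=30, n_linker=6, seed=1)
    st = make_model(spec)
    dec = decompose(st, multidomain_dimer_segments(spec))
    from saxsfit.rigidbody import _conn_energy
    pos = perturb_body_about_hinge(dec, 2, 40.0, axis=[0, 1, 0])
    assert _conn_energy(pos, dec.springs) == pytest.approx(
        _conn_energy(dec.beads.positions, dec.springs), abs=1e-9)
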