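import numpy as np
import pytest

from ossidrive import fem
from ossidrive.materials import EPS0, build_piezo_constitutive
from conftest import make_stack_system


def _elastic_only():
    """PZT-4 stiffness with piezoelectric coupling switched off."""
    return build_piezo_constitutive(139e9, 77.8e9, 74.3e9, 115e9, 25.6e9,
                                    30.6e9, 0.0, 0.0, 0.0, 370, 635, 7500.0)


class TestMesh:
    def test_designed_device_mesh(self):
        spec = fem.StackSpec()  # 50 layers, 0.04 mm, 2x2 mm
        mesh = fem.mesh_stack(spec)
        assert len(mesh.electrode_sets) == 51
        assert mesh.nodes[:, 2].max() == pytest.approx(2e-3)
        assert spec.total_thickness == pytest.approx(2e-3)

    def test_single_layer_parallel_plate(self):
        mesh = fem.mesh_stack(fem.StackSpec(n_layers=1,
                                            layer_thickness=2e-3))
        assert len(mesh.electrode_sets) == 2

    def test_node_count_formula(self):
        a, b, c, n = 3, 2, 2, 4
        mesh = fem.mesh_stack(fem.StackSpec(n_layers=n,
                                            layer_thickness=0.5e-3,
                                            nx=a, ny=b, nz_per_layer=c))
        assert mesh.n_nodes == (a + 1) * (b + 1) * (n * c + 1)

    def test_alternating_poling(self):
        mesh = fem.mesh_stack(fem.StackSpec(n_layers=4,
                                            layer_thickness=0.5e-3))
        per_layer = [mesh.poling[mesh.elem_layer == l][0] for l in range(4)]
        assert per_layer[0] == -per_layer[1] == per_layer[2] == -per_layer[3]

    def test_zero_subdivision_rejected(self):
        with pytest.raises(ValueError):
            fem.StackSpec(nx=0)


class TestElementMatrices:
    coords = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                       [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                      dtype=float) * 1e-3

    def test_symmetry_and_rigid_nullspace(self, pzt4_mat):
        Kuu, _, _, _ = fem.element_matrices(self.coords, pzt4_mat)
        assert np.allclose(Kuu, Kuu.T)
        rigid = np.zeros(24)
        rigid[0::3] = 1.0  # uniform x translation
        assert np.linalg.norm(Kuu @ rigid) < 1e-6 * np.linalg.norm(Kuu)

    def test_mass_conservation(self, pzt4_mat):
        _, _, _, Muu = fem.element_matrices(self.coords, pzt4_mat)
        vol = 1e-9
        for comp in range(3):
            sel = np.zeros(24)
            sel[comp::3] = 1.0
            assert sel @ Muu @ sel == pytest.approx(pzt4_mat.rho * vol,
                                                    rel=1e-12)

    def test_parallel_plate_capacitance_decoupled(self):
        # unit cube element, e = 0: Kpp-derived capacitance = eps33*A/t
        mat = _elastic_only()
        _, Kup, Kpp, _ = fem.element_matrices(self.coords, mat)
        assert np.all(Kup == 0)
        phi = self.coords[:, 2] / 1e-3  # 1 V across thickness
        # charge = sum of Kpp*phi over the driven (top) nodes
        q = (Kpp @ phi)[4:].sum()
        c_expect = 635 * EPS0 * (1e-3) ** 2 / 1e-3
        assert q == pytest.approx(c_expect, rel=1e-12)

    def test_degenerate_geometry_rejected(self, pzt4_mat):
        bad = self.coords.copy()
        bad[6] = bad[4]  # collapse a top node
        with pytest.raises(ValueError, match="Jacobian"):
            fem.element_matrices(bad, pzt4_mat)


class TestAssembly:
    def test_damping_is_beta_times_stiffness(self, pzt4_mat):
        spec = fem.StackSpec(n_layers=2, layer_thickness=1e-3)
        sys_ = fem.assemble(fem.mesh_stack(spec), pzt4_mat, beta=1e-4)
        assert np.allclose(sys_.Cuu.toarray(), 1e-4 * sys_.Kuu.toarray())
        sys0 = fem.assemble(fem.mesh_stack(spec), pzt4_mat, beta=0.0)
        assert sys0.Cuu.nnz == 0 or np.all(sys0.Cuu.data == 0)

    def test_block_operator_symmetric(self, small_stack):
        A = small_stack.stiffness_operator()
        assert abs(A - A.T).max() < 1e-9 * abs(A).max()

    def test_two_element_column_series_stiffness(self):
        # axial compression of a 2-element column with lateral rollers:
        # tip deflection equals two c33*A/Le springs in series
        mat = _elastic_only()
        spec = fem.StackSpec(n_layers=2, layer_thickness=1e-3,
                             width=2e-3, depth=2e-3)
        sys_ = fem.assemble(fem.mesh_stack(spec), mat, beta=0.0)
        mesh = sys_.mesh
        # rollers: all x and y DOFs fixed; base z fixed
        nodes = np.arange(mesh.n_nodes)
        sys_.constraints.fix(sys_.mech_dofs(nodes, 0))
        sys_.constraints.fix(sys_.mech_dofs(nodes, 1))
        sys_.constraints.fix(sys_.mech_dofs(mesh.face_nodes("bottom"), 2))
        sys_.constraints.fix(sys_.elec_dofs(nodes))  # ground all potentials
        F = 1.0
        b = np.zeros(sys_.ndof)
        top_z = sys_.mech_dofs(mesh.face_nodes("top"), 2)
        b[top_z] = F / len(top_z)
        res = fem.solve_static(sys_, f_ext=b)
        k_layer = 115e9 * spec.cross_section_area / spec.layer_thickness
        expect = F / (k_layer / 2)  # two springs in series
        assert res.elongation() == pytest.approx(expect, rel=1e-9)


class TestElectrodes:
    def test_equipotential_in_solution(self, small_stack):
        small_stack.minimal_supports()
        res = fem.solve_static(small_stack)
        for s in small_stack.mesh.electrode_sets:
            pots = res.potentials[s]
            assert np.ptp(pots) < 1e-12 * max(1.0, abs(pots).max())

    def test_zero_drive_zero_solution(self, pzt4_mat):
        sys_ = make_stack_system(pzt4_mat, v_rms=0.0, n_layers=2,
                                 layer_thickness=1e-3)
        sys_.minimal_supports()
        res = fem.solve_static(sys_)
        assert np.allclose(res.u, 0.0)

    def test_voltage_limit_warning(self, pzt4_mat):
        import warnings
        spec = fem.StackSpec(n_layers=2, layer_thickness=1e-3)
        sys_ = fem.assemble(fem.mesh_stack(spec), pzt4_mat)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # boundary value must not warn
            fem.apply_electrodes(sys_, 10.5)
        sys2 = fem.assemble(fem.mesh_stack(spec), pzt4_mat)
        with pytest.warns(UserWarning, match="safety"):
            fem.apply_electrodes(sys2, 10.6)


class TestStaticSolve:
    def test_free_stroke_oracle(self, pzt4_mat, d_matrix):
        sys_ = make_stack_system(pzt4_mat, v_rms=1.0, n_layers=4,
                                 layer_thickness=0.5e-3, nx=2, ny=2)
        sys_.minimal_supports()
        res = fem.solve_static(sys_)
        d33 = d_matrix[2, 2]
        assert res.elongation() == pytest.approx(4 * d33 * 1.0, rel=0.01)

    def test_blocked_force_oracle(self, pzt4_mat):
        sys_ = make_stack_system(pzt4_mat, v_rms=1.0, n_layers=4,
                                 layer_thickness=0.5e-3, nx=2, ny=2)
        sys_.blocked_supports()
        res = fem.solve_static(sys_)
        spec = sys_.mesh.spec
        expect = spec.cross_section_area * pzt4_mat.e[2, 2] / spec.layer_thickness
        assert res.blocked_force() == pytest.approx(expect, rel=0.01)

    def test_linearity_in_voltage(self, pzt4_mat):
        kw = dict(n_layers=2, layer_thickness=1e-3)
        r1 = fem.solve_static(_supported(make_stack_system(pzt4_mat, 1.0, **kw)))
        r2 = fem.solve_static(_supported(make_stack_system(pzt4_mat, 2.0, **kw)))
        assert np.allclose(r2.displacements, 2 * r1.displacements,
                           rtol=1e-9, atol=1e-25)


def _supported(system):
    system.minimal_supports()
    return system


def _fixed(system):
    system.fix_base()
    return system


class TestHarmonic:
    def test_static_limit(self, pzt4_mat):
        sys_ = make_stack_system(pzt4_mat, v_rms=1.0, n_layers=4,
                                 layer_thickness=0.5e-3)
        sys_.fix_base()
        stat = fem.solve_static(sys_)
        harm = fem.solve_harmonic(sys_, [0.01])
        rel = abs(abs(harm.elongation_spectrum()[0]) - abs(stat.elongation()))
        assert rel / abs(stat.elongation()) < 1e-6

    def test_linearity_in_voltage(self, pzt4_mat):
        kw = dict(n_layers=2, layer_thickness=1e-3)
        f = [500.0, 2000.0]
        h1 = fem.solve_harmonic(_fixed(make_stack_system(pzt4_mat, 1.0, **kw)), f)
        h3 = fem.solve_harmonic(_fixed(make_stack_system(pzt4_mat, 3.0, **kw)), f)
        assert np.allclose(np.abs(h3.elongation_spectrum()),
                           3 * np.abs(h1.elongation_spectrum()), rtol=1e-9)

    def test_rejects_nonpositive_frequency(self, small_stack):
        small_stack.fix_base()
        with pytest.raises(ValueError):
            fem.solve_harmonic(small_stack, [0.0])

    def test_electrical_input_power_nonnegative(self, pzt4_mat):
        # passivity: with beta >= 0 the terminal never delivers net power
        sys_ = make_stack_system(pzt4_mat, v_rms=1.0, n_layers=4,
                                 layer_thickness=0.5e-3)
        sys_.fix_base()
        res = fem.solve_harmonic(sys_, fem.default_frequency_grid(10))
        I = res.terminal_current()
        p_active = np.real(1.0 * np.conj(I))
        assert np.all(p_active >= -1e-12 * np.abs(I))


class TestSdofDampingRatio:
    def test_half_power_bandwidth(self):
        """Rayleigh-damped oscillator: half-power bandwidth inverts to
        zeta = beta*omega_n/2 (exact relations, not the small-zeta rule)."""
        import scipy.sparse as sp
        from scipy.optimize import brentq
        m, k, beta = 1.0e-3, 4.0e3, 1e-4   # omega_n = 2000 rad/s, zeta = 0.1
        wn = np.sqrt(k / m)
        zeta = beta * wn / 2
        T = sp.identity(1, format="csr")
        g = np.zeros(1)

        def amp(f):
            w = 2 * np.pi * f
            A = sp.csc_matrix(
                np.array([[k - w * w * m + 1j * w * beta * k]]))
            u = fem.constrained_solve(A, np.array([1.0 + 0j]), T, g)
            return abs(u[0])

        fr = wn * np.sqrt(1 - 2 * zeta ** 2) / (2 * np.pi)
        peak = amp(fr)
        target = peak / np.sqrt(2)
        f1 = brentq(lambda f: amp(f) - target, fr / 10, fr, xtol=1e-12)
        f2 = brentq(lambda f: amp(f) - target, fr, fr * 10, xtol=1e-12)
        w1, w2 = 2 * np.pi * f1, 2 * np.pi * f2
        r = (w2 ** 2 - w1 ** 2) / (w1 ** 2 + w2 ** 2)
        zeta_est = np.sqrt((1 - 1 / np.sqrt(1 + r ** 2)) / 2)
        assert zeta_est == pytest.approx(zeta, rel=1e-3)


class TestCapacitance:
    def test_clamped_matches_formula(self, small_stack):
        spec = small_stack.mesh.spec
        caps = fem.model_capacitance(small_stack)
        expect = (spec.n_layers * EPS0 * 635 * spec.cross_section_area
                  / spec.layer_thickness)
        assert caps["clamped"] == pytest.approx(expect, rel=0.01)

    def test_area_scaling(self, pzt4_mat):
        kw = dict(n_layers=2, layer_thickness=1e-3)
        c1 = fem.model_capacitance(make_stack_system(pzt4_mat, 1.0, **kw))
        c2 = fem.model_capacitance(make_stack_system(
            pzt4_mat, 1.0, width=4e-3, **kw))
        assert c2["clamped"] == pytest.approx(2 * c1["clamped"], rel=1e-6)
        assert c2["free"] == pytest.approx(2 * c1["free"], rel=1e-6)

    def test_free_exceeds_clamped(self, small_stack):
        caps = fem.model_capacitance(small_stack)
        assert caps["free"] > caps["clamped"]

    def test_refinement_does_not_worsen(self, pzt4_mat):
        spec = small_stack_spec = fem.StackSpec(n_layers=2,
                                                layer_thickness=1e-3)
        expect = (2 * EPS0 * 635 * spec.cross_section_area
                  / spec.layer_thickness)
        errs = []
        for nxy in (1, 2):
            sys_ = make_stack_system(pzt4_mat, 1.0, n_layers=2,
                                     layer_thickness=1e-3, nx=nxy, ny=nxy)
            c = fem.model_capacitance(sys_)["clamped"]
            errs.append(abs(c - expect) / expect)
        assert errs[1] <= errs[0] + 1e-10
        assert max(errs) < 1e-8
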