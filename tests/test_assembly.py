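"""Structural assembly: element matrices, global system, damping, BCs."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from oocmech import assembly, materials, pipeline
from oocmech.assembly import (_frame_matrices, assemble_structure,
                              default_rayleigh_beta, rayleigh_damping)


class TestFrameElement:
    def test_cantilever_tip_deflection(self):
        """Euler-Bernoulli closed form P L^3 / 3EI within 0.1%."""
        e, i_z, length, p_tip = 1e6, 2e-24, 100e-6, 1e-9
        n_el = 8
        ndof = (n_el + 1) * 4
        k = np.zeros((ndof, ndof))
        for el in range(n_el):
            p1 = np.array([el * length / n_el, 0.0])
            p2 = np.array([(el + 1) * length / n_el, 0.0])
            k_el, _ = _frame_matrices(p1, p2, ea=1.0, ei=e * i_z, rho_a=0.0,
                                      k_oop=1.0)
            dofs = list(range(el * 4, el * 4 + 8))
            k[np.ix_(dofs, dofs)] += k_el
        free = np.arange(4, ndof)
        f = np.zeros(ndof)
        f[-3] = p_tip  # transverse tip load
        u = np.linalg.solve(k[np.ix_(free, free)], f[free])
        tip = u[-3]
        assert tip == pytest.approx(p_tip * length ** 3 / (3 * e * i_z),
                                    rel=1e-3)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            _frame_matrices(np.zeros(2), np.zeros(2), 1.0, 1.0, 1.0)


class TestGlobalSystem:
    def test_stiffness_symmetric(self, small_system):
        k = small_system.k
        assert abs(k - k.T).max() < 1e-12 * abs(k).max()

    def test_mass_positive_definite_on_free_dofs(self, small_system):
        free = small_system.free
        m = small_system.m.tocsr()[free][:, free]
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.standard_normal(m.shape[0])
            assert x @ (m @ x) > 0

    def test_maxwell_betti_reciprocity(self, small_system):
        """u_j from a unit force at i equals u_i from a unit force at j."""
        from oocmech.solver import solve_point_load
        sys_ = small_system
        s = sys_.mid_section
        d1 = sys_.dof(s, materials.DC_ROOTS[0], 1)
        d2 = sys_.dof(s, materials.N_OHC2_APEX, 0)
        f1 = np.zeros(sys_.n_dofs)
        f1[d1] = 1e-9
        f2 = np.zeros(sys_.n_dofs)
        f2[d2] = 1e-9
        u12 = solve_point_load(sys_, f1).values[d2]
        u21 = solve_point_load(sys_, f2).values[d1]
        assert u12 == pytest.approx(u21, rel=1e-9)

    def test_end_sections_and_edges_fixed(self, small_system):
        sys_ = small_system
        for node in (0, 12, materials.N_TM_ATTACH):
            for s in range(sys_.n_sections):
                assert sys_.fixed[sys_.dof(s, node, 1)]
        for comp in range(4):
            assert sys_.fixed[sys_.dof(0, 6, comp)]
            assert sys_.fixed[sys_.dof(sys_.n_sections - 1, 6, comp)]

    def test_modulus_scaling_is_linear(self, mats):
        """Doubling every elastic modulus halves every static displacement."""
        from oocmech import solver
        doubled = mats.with_overrides(**{
            name: (2 * pa, 2 * pb)
            for name, (pa, pb) in mats.properties.items()
            if "modulus" in name or name == "hb_stiffness"})
        kwargs = dict(span_mm=0.2, with_fluid=False)
        base, _ = pipeline.build_model(pipeline.ModelConfig(**kwargs), mats)
        stiff, _ = pipeline.build_model(pipeline.ModelConfig(**kwargs),
                                        doubled)
        u1 = solver.solve_static(base, 5.6).values
        u2 = solver.solve_static(stiff, 5.6).values
        sel = np.abs(u1) > 1e-18
        assert np.allclose(u1[sel], 2.0 * u2[sel], rtol=1e-9)

    def test_rigid_body_modes_without_constraints(self, mats):
        """A free-free short model has exactly four zero-energy modes:
        three translations and the in-plane rotation."""
        secs = [materials.build_section(x, mats)
                for x in [8.49, 8.5, 8.51]]
        system = assemble_structure(secs, 10.0, materials=mats)
        # nondimensionalize rotations by a 100 um moment arm so zero-energy
        # modes are separable from merely-soft rotational stiffness
        scale = np.ones(system.n_dofs)
        scale[3::4] = 1e4
        k = system.k.toarray() * np.outer(scale, scale)
        w = np.linalg.eigvalsh(k)
        n_zero = int(np.sum(w < 1e-12 * w.max()))
        assert n_zero == 4
        # constrained system: no zero modes remain
        free = system.free
        wc = np.linalg.eigvalsh(k[np.ix_(free, free)])
        assert wc.min() > 0

    def test_grid_convergence_static_peak(self, mats):
        from oocmech import solver, vibrometry
        peaks = []
        for spacing in (10.0, 5.0):
            cfg = pipeline.ModelConfig(span_mm=0.3, spacing_um=spacing,
                                       with_fluid=False)
            system, _ = pipeline.build_model(cfg, mats)
            fld = solver.solve_static(system, 5.6)
            prof = vibrometry.bm_profile(fld, pressure_pa=5.6)
            peaks.append(prof.displacement_nm.max())
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.02


class TestDamping:
    def test_rayleigh_trivial_cases(self, small_system):
        m, k = small_system.m, small_system.k
        assert abs(rayleigh_damping(m, k, 0.0, 0.0)).max() == 0.0
        assert abs(rayleigh_damping(m, k, 1.0, 0.0) - m).max() == 0.0
        with pytest.raises(ValueError):
            rayleigh_damping(m, k, -1.0, 0.0)

    def test_c_equals_alpha_m_plus_beta_k(self, mats):
        secs = [materials.build_section(x, mats) for x in (8.49, 8.5, 8.51)]
        system = assemble_structure(secs, 10.0, alpha=3.0, beta=2e-6,
                                    materials=mats,
                                    membrane_damping_per_area=0.0,
                                    subtectorial_damping=0.0,
                                    subtectorial_squeeze=0.0,
                                    tm_loss_eta=0.0)
        resid = system.c - (3.0 * system.m + 2e-6 * system.k)
        assert abs(resid).max() < 1e-12 * abs(system.c).max()

    def test_ohc_damping_calibration(self, mats):
        """beta*k_OHC reproduces ~5 nN s/m per 10 um of cell length."""
        x = 8.5
        beta = default_rayleigh_beta(mats, x)
        l_ohc = mats.value("ohc_length", x)
        d = mats.value("ohc_diameter", x)
        k_ohc = materials._axial_k(mats.value("ohc_modulus", x),
                                  np.pi * d * d / 4, l_ohc) * 1e-3
        target = 5e-9 * l_ohc / 10.0
        assert beta * k_ohc == pytest.approx(target, rel=0.2)
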