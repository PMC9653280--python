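"""Coupled static/frequency solver and OHC force-couple loading."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from oocmech import materials, pipeline, solver
from oocmech.solver import (apply_ohc_force_couple, effective_system,
                            solve_frequency, solve_static)


class TestStatic:
    def test_zero_pressure_zero_field(self, small_system):
        fld = solve_static(small_system, 0.0)
        assert np.all(fld.values == 0.0)

    def test_linearity_in_pressure(self, small_system):
        u1 = solve_static(small_system, 5.6).values
        u2 = solve_static(small_system, 11.2).values
        assert np.allclose(u2, 2.0 * u1, rtol=1e-12)

    def test_fixed_dofs_zero_and_field_real(self, small_system):
        fld = solve_static(small_system, 5.6)
        assert np.all(fld.values[small_system.fixed] == 0.0)
        assert np.isrealobj(fld.values)

    def test_nonfinite_pressure_rejected(self, small_system):
        with pytest.raises(ValueError):
            solve_static(small_system, float("nan"))


@pytest.fixture(scope="module")
def tiny(mats):
    """Coupled model small enough for dense-matrix oracles."""
    cfg = pipeline.ModelConfig(span_mm=0.08, spacing_um=20.0,
                               fluid_refinement=1.0, far_cell_mm=1.0)
    return pipeline.build_model(cfg, mats)


class TestEffectiveSystem:
    def test_meff_matches_dense_oracle(self, tiny):
        system, coupling = tiny
        op, _ = effective_system(system, coupling)
        app_inv = np.linalg.inv(coupling.a_pp.toarray())
        m_dense = system.m.toarray() + coupling.a_ap.toarray() @ app_inv \
            @ coupling.a_pa.toarray()
        rng = np.random.default_rng(3)
        for _ in range(3):
            v = rng.standard_normal(system.n_dofs)
            assert np.allclose(op @ v, m_dense @ v, rtol=1e-9, atol=1e-22)

    def test_zero_density_reduces_to_structural_mass(self, tiny, mats):
        import oocmech.fluid as fl
        system, coupling = tiny
        cpl0 = fl.assemble_coupling(coupling.mesh, system.interface,
                                    system.n_dofs, rho=0.0)
        op, _ = effective_system(system, cpl0)
        v = np.ones(system.n_dofs)
        assert np.allclose(op @ v, system.m @ v, rtol=1e-12, atol=1e-30)

    def test_zero_boundary_load_zero_feff(self, tiny):
        import oocmech.fluid as fl
        system, coupling = tiny
        cpl = fl.assemble_coupling(coupling.mesh, system.interface,
                                   system.n_dofs,
                                   bc_values={"input": 0.0})
        _, f_eff = effective_system(system, cpl)
        assert np.allclose(f_eff, 0.0, atol=1e-18)


class TestFrequencyDomain:
    def test_nonpositive_frequency_rejected(self, coupled_model):
        system, coupling = coupled_model
        with pytest.raises(ValueError):
            solve_frequency(system, coupling, 0.0)

    def test_low_frequency_limit_matches_static(self, coupled_model):
        """The 1 Hz harmonic solution equals the static solution for the
        same effective fluid-borne load within 1%."""
        system, coupling = coupled_model
        fld = solve_frequency(system, coupling, 1.0, 1.0)
        _, f_eff = effective_system(system, coupling)
        free = system.free
        k = system.k.tocsr()[free][:, free].tocsc()
        u = np.zeros(system.n_dofs)
        u[free] = spla.splu(k).solve(f_eff[free])
        probe = system.dof(system.mid_section, materials.DC_ROOTS[0], 1)
        assert abs(fld.values[probe] - u[probe]) < 0.01 * abs(u[probe])

    def test_undamped_response_phase_is_zero_or_pi(self, mats):
        cfg = pipeline.ModelConfig(span_mm=0.2, beta=0.0,
                                   membrane_damping_per_area=0.0,
                                   subtectorial_damping=0.0,
                                   subtectorial_squeeze=0.0, tm_loss_eta=0.0)
        system, coupling = pipeline.build_model(cfg, mats)
        fld = solve_frequency(system, coupling, 700.0, 1.0)
        vals = fld.values[system.free]
        assert np.abs(vals.imag).max() < 1e-9 * np.abs(vals.real).max()

    def test_fluid_loading_lowers_resonance(self, mats):
        """Entrained fluid adds inertia: with light damping the wet
        resonance peak sits below the dry one."""
        import oocmech.fluid as fl
        freqs = np.geomspace(300, 8000, 25)
        peaks = []
        cfg = pipeline.ModelConfig(span_mm=0.3,
                                   membrane_damping_per_area=10.0,
                                   subtectorial_squeeze=1e-6)
        system, coupling = pipeline.build_model(cfg, mats)
        probe = system.dof(system.mid_section, materials.DC_ROOTS[0], 1)
        for rho in (1000.0, 0.0):
            cpl = fl.assemble_coupling(coupling.mesh, system.interface,
                                       system.n_dofs, rho=rho)
            amps = np.array([abs(solve_frequency(system, cpl, f,
                                                 1.0).values[probe])
                             for f in freqs])
            peaks.append(freqs[np.argmax(amps)])
        assert peaks[0] < peaks[1]


class TestForceCouple:
    def test_net_force_and_moment_vanish(self, small_system):
        s = small_system.mid_section
        load = apply_ohc_force_couple(small_system, (s, s + 1), rows=(1, 2, 3),
                                      f_ohc=1e-9)
        f_r = load[0::4].sum()
        f_t = load[1::4].sum()
        assert abs(f_r) < 1e-24 and abs(f_t) < 1e-24
        # net moment about the origin (forces are collinear per cell)
        moment = 0.0
        for s_i in range(small_system.n_sections):
            for n in range(23):
                p = small_system.node_position(s_i, n)
                fr = load[small_system.dof(s_i, n, 0)]
                ft = load[small_system.dof(s_i, n, 1)]
                moment += p[0] * ft - p[1] * fr
        assert abs(moment) < 1e-28

    def test_invalid_arguments_rejected(self, small_system):
        with pytest.raises(ValueError, match="section range"):
            apply_ohc_force_couple(small_system, (0, 999))
        with pytest.raises(ValueError, match="rows"):
            apply_ohc_force_couple(small_system, (1, 2), rows=(4,))
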