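"""Static and frequency-domain solution of the coupled fluid-structure model.

The structural system ``M x'' + C x' + K x = f_FLD`` is coupled to the
incompressible chamber fluid through ``A_pp p + A_pa a = b`` and
``f_FLD = A_ap p``.  Eliminating the pressure yields the effective system
``M_EFF x'' + C x' + K x = f_EFF`` with ``M_EFF = M + A_ap A_pp^-1 A_pa``
(structural plus entrained fluid inertia) and ``f_EFF = A_ap A_pp^-1 b``.
Frequency-domain solves keep the pressure explicit and factorize the sparse
block system instead of densifying ``M_EFF``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import AssembledSystem
from .fluid import CouplingOperators
from .materials import DC_ROOTS, N_JOINT1, N_OHC1_APEX, N_OHC2_APEX

__all__ = ["DisplacementField", "solve_static", "effective_system",
           "solve_frequency", "apply_ohc_force_couple", "frequency_sweep"]


@dataclass
class DisplacementField:
    """Nodal displacements over the full DOF vector (fixed DOFs are zero).

    ``values`` is real for static solutions (frequency 0) and complex for
    frequency-domain solutions; displacements in meters, rotations in rad.
    """

    values: np.ndarray
    frequency: float
    load: str
    system: AssembledSystem

    def motion(self, section: int, node: int) -> np.ndarray:
        """(radial, transverse) displacement of a node (complex or real)."""
        d0 = self.system.dof(section, node, 0)
        return self.values[d0:d0 + 2]


def _solve_constrained(system: AssembledSystem, matrix: sp.spmatrix,
                       load: np.ndarray) -> np.ndarray:
    free = system.free
    a = matrix.tocsr()[free][:, free].tocsc()
    try:
        lu = spla.splu(a)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "singular stiffness matrix: an unconstrained rigid-body mode "
            "remains after applying boundary conditions") from exc
    x = np.zeros(system.n_dofs, dtype=load.dtype)
    u = lu.solve(load[free])
    # one step of iterative refinement: the stiffness spans ~10 decades
    # between rotational and translational entries
    u += lu.solve(load[free] - a @ u)
    x[free] = u
    return x


def static_pressure_load(system: AssembledSystem, dp: float) -> np.ndarray:
    """Tributary-area-weighted transepithelial load: BM-facing side only."""
    f = np.zeros(system.n_dofs)
    for patch in system.interface:
        if patch.side == "bm":
            f[patch.dof] += dp * patch.area
    return f


def solve_static(system: AssembledSystem, dp: float,
                 extra_load: np.ndarray | None = None) -> DisplacementField:
    """Static solution ``K x = f`` under a hydrostatic pressure step (Pa)."""
    if not np.isfinite(dp):
        raise ValueError("pressure step must be finite")
    f = static_pressure_load(system, dp)
    if extra_load is not None:
        f = f + extra_load
    x = _solve_constrained(system, system.k, f)
    return DisplacementField(values=x, frequency=0.0,
                             load=f"hydrostatic dP={dp} Pa", system=system)


def solve_point_load(system: AssembledSystem, load: np.ndarray,
                     label: str = "point load") -> DisplacementField:
    """Static solution for an arbitrary nodal load vector (N)."""
    x = _solve_constrained(system, system.k, load)
    return DisplacementField(values=x, frequency=0.0, load=label,
                             system=system)


def effective_system(system: AssembledSystem, coupling: CouplingOperators
                     ) -> tuple[spla.LinearOperator, np.ndarray]:
    """Effective-inertia operator ``x -> M_EFF x`` and load ``f_EFF``.

    ``A_pp`` is factorized once (cached on the coupling object) and reused;
    no dense inverse is formed.
    """
    lu = coupling.lu
    m = system.m

    def matvec(v: np.ndarray) -> np.ndarray:
        return m @ v + coupling.a_ap @ lu.solve(coupling.a_pa @ v)

    op = spla.LinearOperator(shape=m.shape, matvec=matvec, dtype=float)
    f_eff = coupling.a_ap @ lu.solve(coupling.b)
    return op, f_eff


def solve_frequency(system: AssembledSystem, coupling: CouplingOperators,
                    frequency: float, stimulus_pa: float = 1.0,
                    with_pressure: bool = False):
    """Harmonic response at ``frequency`` Hz to a unit-scaled port pressure.

    Solves the sparse block system for structural displacement and fluid
    pressure simultaneously (equivalent to the effective-mass formulation):

        [K + i w C - w^2 M   -A_ap] [x]   [0]
        [     -w^2 A_pa       A_pp] [p] = [b * stimulus]

    Returns the displacement field, or ``(field, pressure)`` when
    ``with_pressure`` is set (e.g. to read a hydrophone cell).
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * frequency
    free = system.free
    z_ss = (system.k + 1j * w * system.c - w * w * system.m).tocsr()
    z_ss = z_ss[free][:, free]
    a_ap = coupling.a_ap.tocsr()[free]
    a_pa = coupling.a_pa.tocsr()[:, free]
    block = sp.bmat([[z_ss, -a_ap],
                     [-w * w * a_pa, coupling.a_pp]], format="csc",
                    dtype=complex)
    rhs = np.concatenate([np.zeros(z_ss.shape[0], dtype=complex),
                          coupling.b.astype(complex) * stimulus_pa])
    try:
        sol = spla.splu(block).solve(rhs)
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(
            f"dynamic matrix singular at f={frequency} Hz") from exc
    n_free = z_ss.shape[0]
    x = np.zeros(system.n_dofs, dtype=complex)
    x[free] = sol[:n_free]
    field = DisplacementField(values=x, frequency=frequency,
                              load=f"boundary pressure {stimulus_pa} Pa",
                              system=system)
    if with_pressure:
        return field, sol[n_free:]
    return field


def frequency_sweep(system: AssembledSystem, coupling: CouplingOperators,
                    frequencies: np.ndarray, stimulus_pa: float = 1.0
                    ) -> list[DisplacementField]:
    return [solve_frequency(system, coupling, f, stimulus_pa)
            for f in np.asarray(frequencies, dtype=float)]


_ROW_NODES = {1: (N_OHC1_APEX, N_JOINT1),
              2: (N_OHC2_APEX, DC_ROOTS[1]),
              3: (N_OHC2_APEX, DC_ROOTS[2])}


def apply_ohc_force_couple(system: AssembledSystem,
                           section_range: tuple[int, int],
                           rows: tuple[int, ...] = (1,),
                           f_ohc: float = 1e-9) -> np.ndarray:
    """Equal-and-opposite force pair along the OHC axis, per selected cell.

    A contraction of magnitude ``f_ohc`` (N) pulls the apical and basal ends
    of each selected outer hair cell toward each other; the couple has zero
    net force and zero net moment per cell.  Rows 2 and 3 act along their
    combined OHC+DC column axis.
    """
    s0, s1 = section_range
    if s0 < 0 or s1 > system.n_sections or s0 >= s1:
        raise ValueError(f"section range {section_range} outside the model")
    if not set(rows) <= {1, 2, 3}:
        raise ValueError("rows must be a subset of {1, 2, 3}")
    if not np.isfinite(f_ohc):
        raise ValueError("force magnitude must be finite")
    f = np.zeros(system.n_dofs)
    for s in range(s0, s1):
        sec = system.sections[s]
        for row in rows:
            apex, base = _ROW_NODES[row]
            axis = sec.nodes[base] - sec.nodes[apex]
            axis = axis / np.linalg.norm(axis)
            for comp in range(2):
                f[system.dof(s, apex, comp)] += f_ohc * axis[comp]
                f[system.dof(s, base, comp)] -= f_ohc * axis[comp]
    return f
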