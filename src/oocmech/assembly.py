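"""Assembly of the multi-section structural model of the organ of Corti.

Each radial section contributes planar frame elements (axial + Euler-
Bernoulli bending) with four DOFs per node: radial and transverse
translation in the section plane, longitudinal translation out of it, and
in-plane rotation.  The longitudinal DOF carries out-of-plane bending/shear
of the in-section members, the stretch and bending of the BM/TM/RL plate
strips between adjacent sections, and the true three-dimensional axis of
the Deiters-cell phalangeal process, which runs from the row-1 OHC/DC
joint of one section to the reticular lamina a few sections apically,
closing the Y-shaped truss.  Under long-wavelength (in-phase) motion the
slanted process couples with its full in-plane projection; under a
single-cell load the joint can yield longitudinally, which relieves it.

Boundary conditions follow the excised-preparation protocol: both
longitudinal ends fully fixed, the medial and lateral BM edges clamped (no
translation or rotation) in every section, and the TM clamped at its
spiral-limbus attachment.  Damping is Rayleigh, ``C = alpha M + beta K``,
with ``beta`` calibrated by default so an OHC dissipates about 5 nN s/m per
10 um of cell length.

All assembled matrices are SI (N, m, kg, s); section coordinates in um are
converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .fluid import InterfacePatch
from .materials import (CELL_PITCH_UM, DC_ROOTS, N_JOINT1, N_OHC1_APEX,
                        N_OHC2_APEX, N_TM, N_TM_ATTACH, N_TUNNEL_TIP, Element,
                        MaterialTable, SectionGeometry, _axial_k)

__all__ = ["AssembledSystem", "assemble_structure", "rayleigh_damping",
           "default_rayleigh_beta"]

RHO_TISSUE = 1000.0  # kg/m^3
N_NODES = 23
DOF_PER_NODE = 4     # radial, transverse, longitudinal, in-plane rotation
OHC_DAMPING_PER_10UM = 5e-9  # N s/m per 10 um cell length

_BM_CHAIN = list(range(13))
_RL_CHAIN = [N_TUNNEL_TIP, N_OHC1_APEX, N_OHC2_APEX]
_TM_CHAIN = list(N_TM)


def rayleigh_damping(m: sp.spmatrix, k: sp.spmatrix, alpha: float,
                     beta: float) -> sp.csr_matrix:
    """Rayleigh damping ``C = alpha M + beta K`` (alpha in 1/s, beta in s)."""
    if alpha < 0 or beta < 0:
        raise ValueError("Rayleigh coefficients must be non-negative")
    return (alpha * m + beta * k).tocsr()


def default_rayleigh_beta(materials: MaterialTable, x: float) -> float:
    """Stiffness-proportional coefficient reproducing the nominal OHC damping.

    With ``C = beta K`` an element of stiffness k dissipates with coefficient
    ``beta k``; beta is set so the OHC soma at ``x`` has a damping coefficient
    of 5 nN s/m per 10 um of its length.
    """
    import math
    l_ohc = materials.value("ohc_length", x)
    d = materials.value("ohc_diameter", x)
    a = math.pi * d * d / 4.0
    k_ohc = _axial_k(materials.value("ohc_modulus", x), a, l_ohc) * 1e-3  # N/m
    c_target = OHC_DAMPING_PER_10UM * (l_ohc / 10.0)
    return c_target / k_ohc


@dataclass
class AssembledSystem:
    """Structural M, C, K with DOF bookkeeping and fluid-interface patches."""

    m: sp.csr_matrix
    c: sp.csr_matrix
    k: sp.csr_matrix
    sections: list[SectionGeometry]
    spacing: float                    # m
    fixed: np.ndarray                 # bool mask over all DOFs
    alpha: float
    beta: float
    interface: list[InterfacePatch] = field(default_factory=list)
    slit_x0: float = 0.0              # m, fluid x of section 0

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def n_dofs(self) -> int:
        return self.k.shape[0]

    @property
    def free(self) -> np.ndarray:
        return ~self.fixed

    def dof(self, section: int, node: int, comp: int) -> int:
        """Global DOF index; components 0=radial, 1=transverse,
        2=longitudinal, 3=in-plane rotation."""
        return (section * N_NODES + node) * DOF_PER_NODE + comp

    @property
    def mid_section(self) -> int:
        return self.n_sections // 2

    def section_at(self, x_mm: float) -> int:
        """Index of the section closest to ``x_mm``."""
        xs = np.array([s.x for s in self.sections])
        return int(np.argmin(np.abs(xs - x_mm)))

    def node_position(self, section: int, node: int) -> np.ndarray:
        """In-plane node position in meters."""
        return self.sections[section].nodes[node] * 1e-6


def _frame_matrices(p1: np.ndarray, p2: np.ndarray, ea: float, ei: float,
                    rho_a: float, k_oop: float = 0.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """8x8 stiffness and mass of a planar frame element with a longitudinal DOF.

    Per-node DOFs (r, t, y, rot): the (r, t, rot) block is the standard
    axial + Euler-Bernoulli frame; ``k_oop`` is the out-of-plane stiffness
    coupling the two longitudinal DOFs (beam out-of-plane bending for
    circular members, in-plane plate shear for strip members).  ``ea`` (N),
    ``ei`` (N m^2), ``rho_a`` (kg/m) in SI; ``p1, p2`` in meters.
    """
    d = p2 - p1
    length = float(np.hypot(*d))
    if length <= 0:
        raise ValueError("zero-length element")
    cx, cy = d / length
    k_loc = np.zeros((6, 6))
    k_loc[0, 0] = k_loc[3, 3] = ea / length
    k_loc[0, 3] = k_loc[3, 0] = -ea / length
    w = ei / length ** 3
    kb = np.array([
        [12 * w, 6 * w * length, -12 * w, 6 * w * length],
        [6 * w * length, 4 * w * length ** 2, -6 * w * length, 2 * w * length ** 2],
        [-12 * w, -6 * w * length, 12 * w, -6 * w * length],
        [6 * w * length, 2 * w * length ** 2, -6 * w * length, 4 * w * length ** 2]])
    idx = [1, 2, 4, 5]
    k_loc[np.ix_(idx, idx)] += kb

    ml = rho_a * length
    m_loc = np.zeros((6, 6))
    m_loc[0, 0] = m_loc[3, 3] = ml / 3.0
    m_loc[0, 3] = m_loc[3, 0] = ml / 6.0
    mb = (ml / 420.0) * np.array([
        [156, 22 * length, 54, -13 * length],
        [22 * length, 4 * length ** 2, 13 * length, -3 * length ** 2],
        [54, 13 * length, 156, -22 * length],
        [-13 * length, -3 * length ** 2, 22 * length, 4 * length ** 2]])
    m_loc[np.ix_(idx, idx)] += mb

    t = np.zeros((6, 6))
    r = np.array([[cx, cy, 0], [-cy, cx, 0], [0, 0, 1]])
    t[:3, :3] = r
    t[3:, 3:] = r
    k6 = t.T @ k_loc @ t
    m6 = t.T @ m_loc @ t

    planar = [0, 1, 3, 4, 5, 7]   # embed (r, t, rot) of each node
    k8 = np.zeros((8, 8))
    m8 = np.zeros((8, 8))
    k8[np.ix_(planar, planar)] = k6
    m8[np.ix_(planar, planar)] = m6
    k8[2, 2] = k8[6, 6] = k_oop
    k8[2, 6] = k8[6, 2] = -k_oop
    m8[2, 2] = m8[6, 6] = ml / 2.0
    return k8, m8


def _link_stiffness(p1: np.ndarray, p2: np.ndarray, k_axial: float,
                    k_shear: float = 0.0,
                    axis: np.ndarray | None = None,
                    k_long: float = 0.0) -> np.ndarray:
    """6x6 two-node translational spring over the (r, t, y) DOFs.

    ``axis`` is the axial direction, a 2-vector (in-plane) or 3-vector;
    it defaults to the in-plane chord p1 -> p2.  ``k_shear`` acts along the
    in-plane perpendicular of the axial direction, ``k_long`` along the
    longitudinal axis (e.g. the longitudinal shear of a deflecting hair
    bundle).
    """
    if axis is not None:
        a = np.asarray(axis, dtype=float)
        e_ax = np.zeros(3)
        e_ax[:len(a)] = a
    else:
        d = p2 - p1
        length = float(np.hypot(*d))
        e_ax = np.array([*(d / length), 0.0]) if length > 0 \
            else np.array([0.0, 1.0, 0.0])
    e_ax = e_ax / np.linalg.norm(e_ax)
    e_sh = np.array([-e_ax[1], e_ax[0], 0.0])
    if np.linalg.norm(e_sh) > 0:
        e_sh = e_sh / np.linalg.norm(e_sh)
    e_y = np.array([0.0, 0.0, 1.0])
    kk = (k_axial * np.outer(e_ax, e_ax) + k_shear * np.outer(e_sh, e_sh)
          + k_long * np.outer(e_y, e_y))
    out = np.zeros((6, 6))
    out[:3, :3] = kk
    out[3:, 3:] = kk
    out[:3, 3:] = -kk
    out[3:, :3] = -kk
    return out


def _tributary_widths(sec: SectionGeometry, chain: list[int]) -> dict[int, float]:
    """Half-sum of adjacent chain spans per node, in meters."""
    pos = sec.nodes[chain] * 1e-6
    spans = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    trib = {}
    for idx, node in enumerate(chain):
        w = 0.0
        if idx > 0:
            w += spans[idx - 1] / 2
        if idx < len(spans):
            w += spans[idx] / 2
        trib[node] = w
    return trib


def assemble_structure(sections: list[SectionGeometry], spacing_um: float,
                       alpha: float = 0.0, beta: float | None = None,
                       materials: MaterialTable | None = None,
                       php_span: int = 3,
                       damping_scale_dc: float = 1.0,
                       membrane_damping_per_area: float = 1000.0,
                       subtectorial_damping: float = 100e-9,
                       subtectorial_squeeze: float = 1e-4,
                       tm_loss_eta: float = 0.3,
                       tm_loss_ref_hz: float = 1000.0
                       ) -> AssembledSystem:
    """Assemble the global system from a list of radial sections.

    ``damping_scale_dc`` multiplies the damping of the Deiters-cell and OHC
    column elements (used by the c_DC sweep): implemented by adding
    ``(scale-1) * beta * k_el`` for those elements into C.

    Besides Rayleigh damping, two standard dissipation channels of cochlear
    models are included: viscous drag on the fluid-facing membranes,
    ``membrane_damping_per_area`` (N s/m^3, the classic ~1 kN s/m^3 scale,
    i.e. ~300 nN s/m per 300 um x 10 um section), applied to the BM and TM
    transverse DOFs by tributary area; and shear dissipation of the
    subtectorial gap,
    ``subtectorial_damping`` (N s/m per 10 um section) acting on the
    relative TM-RL sliding across each hair bundle, plus the far stronger
    squeeze-film resistance ``subtectorial_squeeze`` (N s/m per 10 um
    section) against normal (gap-thickness) TM-RL motion — a conservative
    fraction of the continuum squeeze-film estimate mu b^3/g^3 for
    micron-scale gaps.  The tectorial membrane itself is a poroelastic gel
    with a loss tangent of order ``tm_loss_eta`` at audio frequencies; the
    material loss is added as extra stiffness-proportional damping
    ``eta/(2 pi f_ref) * k`` on the TM elements.
    """
    if len(sections) < 3:
        raise ValueError("need at least 3 sections")
    n_nodes = {len(s.nodes) for s in sections}
    if n_nodes != {N_NODES}:
        raise ValueError("inconsistent node counts across sections")

    mats = materials or MaterialTable()
    h = spacing_um * 1e-6
    n_sec = len(sections)
    ndof = n_sec * N_NODES * DOF_PER_NODE

    rows: list[int] = []
    cols: list[int] = []
    k_vals: list[float] = []
    m_vals: list[float] = []
    c_extra_vals: list[float] = []
    c_extra_rows: list[int] = []
    c_extra_cols: list[int] = []

    def dof(s: int, n: int, c: int) -> int:
        return (s * N_NODES + n) * DOF_PER_NODE + c

    def add_block(dofs: list[int], k_el: np.ndarray,
                  m_el: np.ndarray | None = None,
                  c_scale: float = 0.0) -> None:
        for a, da in enumerate(dofs):
            for bi, db in enumerate(dofs):
                rows.append(da)
                cols.append(db)
                k_vals.append(k_el[a, bi])
                m_vals.append(m_el[a, bi] if m_el is not None else 0.0)
                if c_scale:
                    c_extra_rows.append(da)
                    c_extra_cols.append(db)
                    c_extra_vals.append(c_scale * k_el[a, bi])

    if beta is None:
        beta = default_rayleigh_beta(mats, sections[len(sections) // 2].x)

    _long_modulus = {"bm": "bm_modulus_long", "rl": "rl_modulus_long",
                     "tm": "tm_modulus_long"}

    for s, sec in enumerate(sections):
        pts = sec.nodes * 1e-6
        for el in sec.elements:
            if el.role == "dc-php":
                continue  # assembled below as a cross-section truss member
            i, j = el.nodes
            dofs8 = [dof(s, i, 0), dof(s, i, 1), dof(s, i, 2), dof(s, i, 3),
                     dof(s, j, 0), dof(s, j, 1), dof(s, j, 2), dof(s, j, 3)]
            dofs6 = [dof(s, i, 0), dof(s, i, 1), dof(s, i, 2),
                     dof(s, j, 0), dof(s, j, 1), dof(s, j, 2)]
            is_dc_path = el.role in ("ohc-row1", "dc-base", "ohc-row2",
                                     "ohc-row3")
            c_scale = beta * (damping_scale_dc - 1.0) if is_dc_path else 0.0
            if el.role.startswith("tm") and tm_loss_eta > 0:
                c_scale += tm_loss_eta / (2.0 * np.pi * tm_loss_ref_hz)
            if el.k_direct is not None:
                k_ax = el.k_direct * 1e-3  # mN/m -> N/m
                if el.role.startswith("hb"):
                    sec_factor = getattr(sec, "hb_axial_factor", 100.0)
                    bundle_axis = np.array([0.0, 1.0])
                    # bundles deflect as easily longitudinally as radially
                    k_el = _link_stiffness(pts[i], pts[j],
                                           k_axial=sec_factor * k_ax,
                                           k_shear=k_ax, axis=bundle_axis,
                                           k_long=k_ax)
                    if subtectorial_damping > 0 or subtectorial_squeeze > 0:
                        c_st = subtectorial_damping * spacing_um / 10.0
                        c_sq = subtectorial_squeeze * spacing_um / 10.0
                        c_el = _link_stiffness(pts[i], pts[j], k_axial=c_sq,
                                               k_shear=c_st,
                                               axis=bundle_axis, k_long=c_st)
                        for a, da in enumerate(dofs6):
                            for bi, db in enumerate(dofs6):
                                c_extra_rows.append(da)
                                c_extra_cols.append(db)
                                c_extra_vals.append(c_el[a, bi])
                else:
                    k_el = _link_stiffness(pts[i], pts[j], k_axial=k_ax)
                m_el = np.zeros((6, 6))
                if el.extra_mass_area > 0:
                    length = np.linalg.norm(pts[j] - pts[i])
                    m_half = RHO_TISSUE * el.extra_mass_area * 1e-12 * length / 2
                    np.fill_diagonal(m_el, m_half)
                add_block(dofs6, k_el, m_el, c_scale)
            else:
                ea = el.modulus * 1e6 * el.area * 1e-12
                ei = el.modulus * 1e6 * el.second_moment * 1e-24
                rho_a = RHO_TISSUE * (el.area + el.extra_mass_area) * 1e-12
                length = float(np.linalg.norm(pts[j] - pts[i]))
                layer = _long_modulus.get(el.role.split("-")[0])
                if layer is not None:
                    # strip member: out-of-plane coupling is in-plane shear
                    # of the plate with the soft longitudinal modulus
                    g_long = mats.value(layer, sec.x) * 1e6 / 3.0
                    k_oop = g_long * el.area * 1e-12 / length
                else:
                    # circular member: out-of-plane beam bending
                    k_oop = 12.0 * el.modulus * 1e6 \
                        * el.second_moment * 1e-24 / length ** 3
                k_el, m_el = _frame_matrices(pts[i], pts[j], ea, ei, rho_a,
                                             k_oop=k_oop)
                add_block(dofs8, k_el, m_el, c_scale)

        # longitudinal coupling of the BM/RL/TM plate strips: transverse
        # plate bending via a convergent second-difference stencil,
        # in-plane shear and longitudinal stretch via pairwise springs
        x = sec.x
        for chain, e_long, thick in (
                (_BM_CHAIN, mats.value("bm_modulus_long", x),
                 mats.value("bm_fiber_thickness", x)),
                (_RL_CHAIN, mats.value("rl_modulus_long", x),
                 mats.value("rl_thickness", x)),
                (_TM_CHAIN, mats.value("tm_modulus_long", x),
                 mats.value("tm_body_thickness", x))):
            trib = _tributary_widths(sec, chain)
            e_si = e_long * 1e6
            t_si = thick * 1e-6
            for node in chain:
                b = trib[node]
                if 0 < s < n_sec - 1:
                    # energy (EI/2h^3) (w_{s-1} - 2 w_s + w_{s+1})^2
                    ei = e_si * b * t_si ** 3 / 12.0
                    stencil = np.array([1.0, -2.0, 1.0])
                    k_bend = (ei / h ** 3) * np.outer(stencil, stencil)
                    dd = [dof(s - 1, node, 1), dof(s, node, 1),
                          dof(s + 1, node, 1)]
                    add_block(dd, k_bend)
                if s + 1 < n_sec:
                    k_r = (e_si / 3.0) * (t_si * b) / h    # in-plane shear
                    k_y = e_si * (t_si * b) / h            # stretch
                    for comp, kv in ((0, k_r), (2, k_y)):
                        d1, d2 = dof(s, node, comp), dof(s + 1, node, comp)
                        add_block([d1, d2],
                                  np.array([[kv, -kv], [-kv, kv]]))

        # phalangeal process: 3-D truss from the row-1 joint to the RL
        # `php_span` cell pitches apically
        php_offset = max(int(round(php_span * CELL_PITCH_UM / spacing_um)), 1)
        if s + php_offset < n_sec:
            tgt = sections[s + php_offset]
            php = next(el for el in sec.elements if el.role == "dc-php")
            k_ax = php.k_direct * 1e-3
            p1 = sec.nodes[N_JOINT1] * 1e-6
            p2 = tgt.nodes[N_OHC2_APEX] * 1e-6
            run = php_span * CELL_PITCH_UM * 1e-6
            axis3 = np.array([*(p2[:2] - p1[:2]), run])
            k_el = _link_stiffness(p1, p2, k_axial=k_ax, axis=axis3)
            dofs6 = [dof(s, N_JOINT1, 0), dof(s, N_JOINT1, 1),
                     dof(s, N_JOINT1, 2),
                     dof(s + php_offset, N_OHC2_APEX, 0),
                     dof(s + php_offset, N_OHC2_APEX, 1),
                     dof(s + php_offset, N_OHC2_APEX, 2)]
            add_block(dofs6, k_el)

    # viscous drag on the fluid-facing membrane surfaces (BM and TM),
    # by tributary area
    if membrane_damping_per_area > 0:
        for s, sec in enumerate(sections):
            for chain in (_BM_CHAIN, _TM_CHAIN):
                trib = _tributary_widths(sec, chain)
                for node in chain:
                    d = dof(s, node, 1)
                    c_extra_rows.append(d)
                    c_extra_cols.append(d)
                    c_extra_vals.append(
                        membrane_damping_per_area * trib[node] * h)

    k = sp.csr_matrix((k_vals, (rows, cols)), shape=(ndof, ndof))
    m = sp.csr_matrix((m_vals, (rows, cols)), shape=(ndof, ndof))
    c = rayleigh_damping(m, k, alpha, beta)
    if c_extra_vals:
        c = (c + sp.csr_matrix((c_extra_vals, (c_extra_rows, c_extra_cols)),
                               shape=(ndof, ndof))).tocsr()

    fixed = np.zeros(ndof, dtype=bool)
    for s, sec in enumerate(sections):
        if s in (0, n_sec - 1):
            lo, hi = dof(s, 0, 0), dof(s, N_NODES - 1, DOF_PER_NODE - 1)
            fixed[lo:hi + 1] = True
        for node in sec.fixed_nodes:
            for comp in range(DOF_PER_NODE):
                fixed[dof(s, node, comp)] = True

    system = AssembledSystem(m=m.tocsr(), c=c, k=k.tocsr(),
                             sections=sections, spacing=h, fixed=fixed,
                             alpha=alpha, beta=beta)
    system.interface = _interface_patches(system)
    return system


def _interface_patches(system: AssembledSystem) -> list[InterfacePatch]:
    """Fluid-facing transverse DOFs with tributary areas (BM and TM sides)."""
    patches: list[InterfacePatch] = []
    h = system.spacing
    for s, sec in enumerate(system.sections):
        x = system.slit_x0 + (s + 0.5) * h
        r0 = sec.nodes[0, 0]
        for chain, side in ((_BM_CHAIN, "bm"), (_TM_CHAIN, "tm")):
            trib = _tributary_widths(sec, chain)
            for node in chain:
                d = system.dof(s, node, 1)
                if system.fixed[d]:
                    continue
                patches.append(InterfacePatch(
                    dof=d, x=x, area=trib[node] * h, side=side,
                    y=(sec.nodes[node, 0] - r0) * 1e-6))
    return patches
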