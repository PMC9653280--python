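"""Two-compartment microchamber fluid as a discrete Laplace problem.

The excised cochlear turn seals a slit in the partition between two
rectangular fluid channels.  The fluid is incompressible and inviscid, so
the pressure obeys ``lap p = 0`` with boundary conditions: prescribed
pressure at the stimulus port (left end of the bottom channel), zero
pressure at the pressure-release port (right end) and at the top-channel
ends open to ambient air, zero normal gradient at rigid walls (chamber
sides, bottom, and the coverslip above), and ``dp/dn = -rho a`` on the
fluid-structure interfaces: the basilar membrane faces the bottom channel
and the tectorial membrane the top one.

Discretization is a cell-centered finite-volume scheme on a tensor-product
grid.  The grid spans the flow direction ``x`` (finest at the slit, graded
toward the ports), the out-of-plane depth ``y`` and the transverse axis
``z``.  With a single cell across the depth the model reduces to the planar
vertical-plane chamber; with the slit resolved in ``y`` it becomes a 3-D
box in which the fluid can also circulate radially around the narrow
vibrating strip, which controls the entrained (added) mass of a membrane
much narrower than the chamber.

In matrix form ``A_pp p + A_pa a = b``: ``A_pp`` is the symmetric positive
definite discrete Laplacian with boundary conditions folded in, ``A_pa``
maps interface accelerations to pressure-equation sources, ``b`` carries
the prescribed port pressures, and the interface force is ``f = A_ap p``
with ``A_ap = A_pa^T / rho`` (adjacent-compartment pressure times tributary
area).  The added-mass operator ``A_ap A_pp^-1 A_pa`` is symmetric positive
semidefinite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["FluidMesh", "CouplingOperators", "build_fluid_mesh",
           "assemble_coupling", "InterfacePatch"]

RHO_WATER = 1000.0  # kg/m^3
G_STANDARD = 9.81   # m/s^2


def water_column_pressure(delta_h_mm: float, rho: float = RHO_WATER,
                          g: float = G_STANDARD) -> float:
    """Hydrostatic pressure (Pa) of a water-column height change (mm)."""
    return rho * g * delta_h_mm * 1e-3


def _graded(total: float, d0: float, d_max: float,
            ratio: float = 1.4) -> np.ndarray:
    """Cell sizes growing geometrically from d0 toward d_max over `total`."""
    sizes = []
    acc, d = 0.0, d0
    while acc < total - 1e-12:
        d = min(d, total - acc)
        sizes.append(d)
        acc += d
        d = min(d * ratio, d_max)
    return np.asarray(sizes)


@dataclass
class FluidMesh:
    """Tensor-product finite-volume mesh of the two-channel chamber (SI)."""

    x_edges: np.ndarray          # m, flow direction, shared by compartments
    y_edges: np.ndarray          # m, out-of-plane depth (length 2 => planar)
    z_sizes_bottom: np.ndarray   # m, cell heights below the partition
    z_sizes_top: np.ndarray      # m, cell heights above the partition
    slit_x: tuple[float, float]  # m
    slit_y: tuple[float, float]  # m
    refinement: float

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def depth(self) -> float:
        return float(self.y_edges[-1] - self.y_edges[0])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def nz(self, compartment: str) -> int:
        return len(self.z_sizes_bottom if compartment == "bottom"
                   else self.z_sizes_top)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * (self.nz("bottom") + self.nz("top"))

    def cell_id(self, compartment: str, i: int, j: int, k: int) -> int:
        """Flat cell index; k = 0 is the layer adjacent to the partition."""
        nzb, nzt = self.nz("bottom"), self.nz("top")
        if compartment == "bottom":
            return (i * self.ny + j) * nzb + k
        return self.nx * self.ny * nzb + (i * self.ny + j) * nzt + k

    def slit_cell(self, compartment: str, x: float, y: float) -> int:
        """Partition-layer cell of the column containing (x, y) in the slit."""
        x0, x1 = self.slit_x
        if not (x0 - 1e-9 <= x <= x1 + 1e-9):
            raise ValueError(f"interface x={x} m outside slit {self.slit_x}")
        y = min(max(y, self.slit_y[0] + 1e-12), self.slit_y[1] - 1e-12)
        i = int(np.clip(np.searchsorted(self.x_edges, x) - 1, 0, self.nx - 1))
        j = int(np.clip(np.searchsorted(self.y_edges, y) - 1, 0, self.ny - 1))
        return self.cell_id(compartment, i, j, 0)


def build_fluid_mesh(chamber_length_mm: float = 10.0,
                     channel_height_mm: float = 1.0,
                     slit_span_mm: float = 4.0,
                     refinement: float = 25.0,
                     far_cell_mm: float = 0.5,
                     depth_mm: float = 1.0,
                     slit_center_mm: float | None = None,
                     slit_width_mm: float | None = None,
                     ny_slit: int = 6) -> FluidMesh:
    """Two rectangular compartments with a centered slit and graded spacing.

    ``refinement`` sets the minimum cell size at the slit to
    ``far_cell_mm / refinement``; cells grow geometrically away from the
    slit toward the far-field size.  With ``slit_width_mm`` unset the mesh
    is the planar vertical-plane chamber with an out-of-plane ``depth_mm``;
    with it set, the slit strip is resolved across the depth by ``ny_slit``
    cells (3-D box variant).
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    if slit_span_mm > chamber_length_mm:
        raise ValueError("slit span exceeds the partition span")
    if min(chamber_length_mm, channel_height_mm, slit_span_mm,
           depth_mm) <= 0:
        raise ValueError("chamber dimensions must be positive")

    length = chamber_length_mm * 1e-3
    height = channel_height_mm * 1e-3
    depth = depth_mm * 1e-3
    far = far_cell_mm * 1e-3
    d_slit = far / refinement
    xc = (slit_center_mm * 1e-3 if slit_center_mm is not None else length / 2)
    x0, x1 = xc - slit_span_mm * 1e-3 / 2, xc + slit_span_mm * 1e-3 / 2
    if x0 < -1e-12 or x1 > length + 1e-12:
        raise ValueError("slit does not fit inside the chamber")

    n_slit = max(int(round((x1 - x0) / d_slit)), 1)
    xs_slit = np.linspace(x0, x1, n_slit + 1)
    left = _graded(x0, d_slit, far)
    right = _graded(length - x1, d_slit, far)
    x_edges = np.concatenate([
        x0 - np.cumsum(left)[::-1], xs_slit, x1 + np.cumsum(right)])
    x_edges[0], x_edges[-1] = 0.0, length

    if slit_width_mm is None:
        y_edges = np.array([0.0, depth])
        slit_y = (0.0, depth)
    else:
        w = slit_width_mm * 1e-3
        if w > depth:
            raise ValueError("slit width exceeds the chamber depth")
        y0 = (depth - w) / 2
        ys_slit = np.linspace(y0, y0 + w, ny_slit + 1)
        dy0 = w / ny_slit
        side = _graded(y0, dy0, far)
        y_edges = np.concatenate([
            y0 - np.cumsum(side)[::-1], ys_slit, y0 + w + np.cumsum(side)])
        y_edges[0], y_edges[-1] = 0.0, depth
        slit_y = (y0, y0 + w)

    # the vertical grid must resolve the near field of the slit strip: its
    # pressure decays over the strip width, not the (coarser) slit-span cells
    near_scale = (slit_width_mm * 1e-3 / ny_slit if slit_width_mm is not None
                  else d_slit)
    dz0 = min(max(near_scale, height / 50), height / 4)
    z_sizes = _graded(height, dz0, far)
    return FluidMesh(x_edges=x_edges, y_edges=y_edges,
                     z_sizes_bottom=z_sizes, z_sizes_top=z_sizes.copy(),
                     slit_x=(x0, x1), slit_y=slit_y, refinement=refinement)


@dataclass(frozen=True)
class InterfacePatch:
    """One fluid-facing structural DOF: index, position and tributary area.

    ``x`` is the longitudinal position in the fluid frame; ``y`` the radial
    position measured from the medial slit edge (used only by the 3-D box).
    """

    dof: int
    x: float        # m
    area: float     # m^2
    side: str       # "bm" (bottom channel) or "tm" (top channel)
    y: float = 0.0  # m, radial offset within the slit strip


@dataclass
class CouplingOperators:
    """Pressure operator and fluid-structure coupling matrices."""

    a_pp: sp.csr_matrix
    a_pa: sp.csr_matrix        # (n_fluid, n_struct)
    a_ap: sp.csr_matrix        # (n_struct, n_fluid)
    b: np.ndarray
    rho: float
    mesh: FluidMesh
    _lu: spla.SuperLU | None = field(default=None, repr=False, compare=False)

    @property
    def lu(self) -> spla.SuperLU:
        if self._lu is None:
            object.__setattr__(self, "_lu", spla.splu(self.a_pp.tocsc()))
        return self._lu

    def solve_pressure(self, accel: np.ndarray | None = None,
                       p_scale: float = 1.0) -> np.ndarray:
        """Pressure for prescribed-port scale and interface accelerations."""
        rhs = self.b * p_scale
        if accel is not None:
            rhs = rhs - self.a_pa @ accel
        return self.lu.solve(rhs)

    def interface_force(self, pressure: np.ndarray) -> np.ndarray:
        return self.a_ap @ pressure


def assemble_coupling(mesh: FluidMesh, interface: list[InterfacePatch],
                      n_struct_dofs: int, rho: float = RHO_WATER,
                      bc_values: dict[str, float] | None = None
                      ) -> CouplingOperators:
    """Assemble ``A_pp``, ``A_pa``, ``A_ap`` and ``b`` for the chamber.

    ``bc_values`` overrides the prescribed boundary pressures (defaults:
    ``input`` 1 Pa at the stimulus port, ``release`` 0, ``open`` 0).
    """
    bc = {"input": 1.0, "release": 0.0, "open": 0.0}
    if bc_values:
        bc.update(bc_values)
    for patch in interface:
        if patch.area <= 0:
            raise ValueError(f"interface DOF {patch.dof} has no tributary area")

    dx, dy = mesh.dx, mesh.dy
    nx, ny = mesh.nx, mesh.ny
    n = mesh.n_cells
    b = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def pairs(ca: np.ndarray, cb: np.ndarray, t: np.ndarray) -> None:
        rows.extend((ca, cb, ca, cb))
        cols.extend((ca, cb, cb, ca))
        vals.extend((t, t, -t, -t))

    for comp in ("bottom", "top"):
        nz = mesh.nz(comp)
        dz = (mesh.z_sizes_bottom if comp == "bottom" else mesh.z_sizes_top)
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        cid = np.vectorize(lambda i, j, k: mesh.cell_id(comp, i, j, k))(
            ii, jj, kk)
        # x-direction interior faces
        if nx > 1:
            area = dy[None, :, None] * dz[None, None, :]
            dist = 0.5 * (dx[:-1] + dx[1:])
            t = (area / dist[:, None, None]) * np.ones((nx - 1, ny, nz))
            pairs(cid[:-1].ravel(), cid[1:].ravel(), t.ravel())
        # y-direction interior faces (rigid side walls: nothing at j bounds)
        if ny > 1:
            area = dx[:, None, None] * dz[None, None, :]
            dist = 0.5 * (dy[:-1] + dy[1:])
            t = (area / dist[None, :, None]) * np.ones((nx, ny - 1, nz))
            pairs(cid[:, :-1].ravel(), cid[:, 1:].ravel(), t.ravel())
        # z-direction interior faces (partition and far wall are Neumann)
        if nz > 1:
            area = dx[:, None, None] * dy[None, :, None]
            dist = 0.5 * (dz[:-1] + dz[1:])
            t = (area / dist[None, None, :]) * np.ones((nx, ny, nz - 1))
            pairs(cid[:, :, :-1].ravel(), cid[:, :, 1:].ravel(), t.ravel())
        # x-end Dirichlet faces
        for side_idx, tag in ((0, "input" if comp == "bottom" else "open"),
                              (nx - 1, "release" if comp == "bottom"
                               else "open")):
            cells = cid[side_idx].ravel()
            area = (dy[:, None] * dz[None, :]).ravel()
            t = area / (0.5 * dx[side_idx])
            rows.append(cells)
            cols.append(cells)
            vals.append(np.broadcast_to(t, cells.shape).copy())
            b[cells] += t * bc[tag]

    a_pp = sp.csr_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))

    # interface coupling: the volume flux of each structural patch enters
    # the adjacent compartment's partition-layer cell at its (x, y)
    pa_rows, pa_cols, pa_vals = [], [], []
    for patch in interface:
        y_abs = mesh.slit_y[0] + patch.y
        if patch.side == "bm":
            # bottom-channel pressure pushes the BM up; an upward BM
            # acceleration rarefies the bottom channel
            c = mesh.slit_cell("bottom", patch.x, y_abs)
            sgn = 1.0
        elif patch.side == "tm":
            c = mesh.slit_cell("top", patch.x, y_abs)
            sgn = -1.0
        else:
            raise ValueError(f"unknown interface side {patch.side!r}")
        pa_rows.append(c)
        pa_cols.append(patch.dof)
        pa_vals.append(sgn * patch.area)
    coupl = sp.csr_matrix((pa_vals, (pa_rows, pa_cols)),
                          shape=(n, n_struct_dofs))
    a_pa = (rho * coupl).tocsr()
    a_ap = coupl.T.tocsr()
    return CouplingOperators(a_pp=a_pp, a_pa=a_pa, a_ap=a_ap, b=b, rho=rho,
                             mesh=mesh)


def hydrophone_cell(mesh: FluidMesh) -> int:
    """Fluid cell of a hydrophone mounted in the chamber floor under the slit.

    The experiment's pressure reference is an electret microphone installed
    beneath the tissue; the corresponding cell is the deepest bottom-channel
    cell under the slit center.
    """
    xc = 0.5 * (mesh.slit_x[0] + mesh.slit_x[1])
    yc = 0.5 * (mesh.slit_y[0] + mesh.slit_y[1])
    i = int(np.clip(np.searchsorted(mesh.x_edges, xc) - 1, 0, mesh.nx - 1))
    j = int(np.clip(np.searchsorted(mesh.y_edges, yc) - 1, 0, mesh.ny - 1))
    return mesh.cell_id("bottom", i, j, mesh.nz("bottom") - 1)


def pressure_table(coupling: CouplingOperators, pressure: np.ndarray):
    """Flat table (x, y, z, Re p, Im p) of a solved pressure field."""
    import pandas as pd

    mesh = coupling.mesh
    recs = []
    for comp, dz, sign in (("bottom", mesh.z_sizes_bottom, -1.0),
                           ("top", mesh.z_sizes_top, 1.0)):
        zc = np.cumsum(dz) - 0.5 * dz
        for i, x in enumerate(mesh.x_centers):
            for j, y in enumerate(mesh.y_centers):
                for k in range(len(dz)):
                    p = pressure[mesh.cell_id(comp, i, j, k)]
                    recs.append((x, y, sign * zc[k], np.real(p), np.imag(p)))
    return pd.DataFrame(recs, columns=["x_m", "y_m", "z_m", "re_p", "im_p"])
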