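"""Longitudinal material gradients and radial-section geometry of the organ of Corti.

The gerbil cochlea is parameterized by the distance ``x`` (mm) from the basal
end (full length 12 mm).  Mechanical properties of the organ-of-Corti (OoC)
complex are anchored at two longitudinal positions, ``x_a = 10`` mm (apical)
and ``x_b = 2`` mm (basal), and vary exponentially in between, so that the
stiffness gradient that underlies cochlear tonotopy is built in.

A radial section of the model has 23 nodes: 13 on the basilar membrane (BM),
6 on the tectorial membrane (TM) and 5 in the OoC interior.  The inner-pillar
root lies on the BM and is simultaneously the medial foot of the tunnel-of-
Corti truss, so it carries both the BM and OoC tags.  The first outer-hair-
cell (OHC) row — the row on which all deformation-ratio measurements are
made — is modeled in full anatomical detail: its apex sits on the reticular
lamina nearly collinear with its Deiters cell, and it has an explicit
OHC/Deiters-cell joint node.  Rows 2 and 3 are soft series OHC+DC links
from the lamina down to their BM roots, with the third row lumped onto the
second-row apex.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialTable",
    "Element",
    "SectionGeometry",
    "interpolate_property",
    "build_section",
    "element_stiffness",
    "default_landmarks",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "LANDMARK_LABELS",
]

# Anchored properties: name -> (value at x_a = 10 mm, value at x_b = 2 mm).
# Lengths/thicknesses in um, Young's moduli in MPa, direct stiffness in mN/m.
_DEFAULT_PROPERTIES: dict[str, tuple[float, float]] = {
    "bm_width": (330.0, 180.0),
    "bm_fiber_thickness": (0.7, 3.2),      # pectinate zone; arcuate is half
    "bm_mid_thickness": (55.0, 35.0),      # mid-pectinate layer, mass only
    "bm_modulus_radial": (2000.0, 2000.0),
    "bm_modulus_long": (0.4, 0.4),
    "ohc_diameter": (7.0, 9.0),
    "ohc_length": (56.0, 24.0),
    "ohc_modulus": (0.005, 0.005),
    "hb_height": (10.0, 4.0),
    "hb_stiffness": (3.0, 40.0),           # mN/m, direct bundle stiffness
    "pillar_diameter": (4.0, 6.0),
    "pillar_modulus": (400.0, 400.0),
    "dc_base_diameter": (10.0, 10.0),
    "dc_process_diameter": (1.0, 1.5),
    "dc_base_modulus": (0.01, 0.01),
    "dc_process_modulus": (40.0, 40.0),
    "rl_thickness": (2.0, 2.0),            # over the OHC region
    "rl_thickness_tunnel": (5.0, 5.0),
    "rl_modulus_radial": (500.0, 500.0),
    "rl_modulus_long": (0.2, 0.2),
    "tm_width": (156.0, 110.0),
    "tm_root_thickness": (25.0, 20.0),
    "tm_body_thickness": (50.0, 30.0),
    "tm_root_modulus": (0.018, 0.29),      # radial
    "tm_body_modulus": (0.0044, 0.074),    # radial
    "tm_modulus_long": (0.002, 0.002),
}

X_ANCHOR_A = 10.0  # mm, apical anchor
X_ANCHOR_B = 2.0   # mm, basal anchor


def interpolate_property(p_a: float, p_b: float, x_a: float, x_b: float,
                         x: float) -> float:
    """Exponential (log-linear) interpolation of a property along the cochlea.

    ``p(x) = p_b * exp(s (x - x_b))`` with ``s = (ln p_b - ln p_a)/(x_b - x_a)``,
    which is exact at both anchors and monotone in between.

    Raises
    ------
    ValueError
        If either anchored value is non-positive (the log interpolation is
        undefined) or the anchors coincide.
    """
    if p_a <= 0 or p_b <= 0:
        raise ValueError(
            f"exponential interpolation requires positive anchors, got "
            f"p_a={p_a}, p_b={p_b}")
    if x_a == x_b:
        raise ValueError("anchor positions must differ")
    s = (math.log(p_b) - math.log(p_a)) / (x_b - x_a)
    return p_b * math.exp(s * (x - x_b))


@dataclass(frozen=True)
class MaterialTable:
    """Anchored OoC material properties with the exponential gradient rule."""

    properties: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PROPERTIES))
    x_a: float = X_ANCHOR_A
    x_b: float = X_ANCHOR_B

    def __post_init__(self) -> None:
        for name, (pa, pb) in self.properties.items():
            if pa <= 0 or pb <= 0:
                raise ValueError(f"property {name!r} has non-positive anchor")

    def value(self, name: str, x: float) -> float:
        """Property value at position ``x`` (mm from the basal end)."""
        p_a, p_b = self.properties[name]
        return interpolate_property(p_a, p_b, self.x_a, self.x_b, x)

    def with_overrides(self, **overrides: tuple[float, float]) -> "MaterialTable":
        props = dict(self.properties)
        props.update(overrides)
        return MaterialTable(properties=props, x_a=self.x_a, x_b=self.x_b)


# ---------------------------------------------------------------------------
# Section geometry
# ---------------------------------------------------------------------------

LANDMARK_LABELS = (
    "bm_medial", "ipc_root", "opc_root", "tunnel_tip",
    "ohc1_top", "ohc1_bottom", "ohc2_top", "ohc2_bottom",
    "ohc3_top", "ohc3_bottom", "hb2_tip", "hb3_tip",
    "bm_lateral", "tm_medial",
)

# Radial stations of the 13 BM nodes as fractions of the BM width.  Stations
# 2 and 4 are the pillar roots; 6, 7, 8 the three Deiters-cell roots.
_BM_FRACTIONS = np.array(
    [0.0, 0.085, 0.17, 0.25, 0.33, 0.415, 0.50, 0.58, 0.67,
     0.75, 0.835, 0.92, 1.0])

# Node ids (fixed layout)
N_BM = list(range(13))
N_TUNNEL_TIP = 13          # pillar head, root of the reticular lamina
N_OHC1_APEX = 14
N_OHC2_APEX = 15           # also carries the lumped third row
N_JOINT1 = 16              # row-1 OHC / Deiters-cell joint
N_TM = list(range(17, 23))
N_TM_ATTACH = 17           # spiral-limbus attachment (clamped)
N_TM_JUNCTION = 18         # TM root/body junction
N_TM_HB1 = 19
N_TM_HB2 = 20
N_TM_HB3 = 21
N_TM_LATERAL = 22

IPC_ROOT = 2
OPC_ROOT = 4
DC_ROOTS = (6, 7, 8)

OHC_TILT_DEG = 25.0        # lean of the OHC axis from the transverse axis
CELL_PITCH_UM = 10.0       # longitudinal spacing of the cellular columns


@dataclass(frozen=True)
class Element:
    """A structural element of a radial section.

    ``modulus`` is a Young's modulus in MPa for beam/truss elements; for
    direct-stiffness links (hair bundles, combined OHC+DC columns) it is
    ``None`` and ``k_direct`` holds the stiffness in mN/m.
    """

    nodes: tuple[int, int]
    role: str
    area: float = 0.0            # um^2
    second_moment: float = 0.0   # um^4
    modulus: float | None = None  # MPa
    k_direct: float | None = None  # mN/m
    extra_mass_area: float = 0.0  # um^2 of additional (mass-only) section


@dataclass
class SectionGeometry:
    """A 23-node radial section of the OoC model at longitudinal position x."""

    x: float                       # mm from the basal end
    nodes: np.ndarray              # (23, 2) [radial, transverse] in um
    node_tags: list[frozenset[str]]
    elements: list[Element]
    bm_width: float                # um
    fixed_nodes: tuple[int, ...]   # fully clamped node ids
    landmarks: dict[str, tuple[float, float]]

    def node_index(self, name: str) -> int:
        return _NAMED_NODES[name]

    def validate(self) -> None:
        if self.nodes.shape != (23, 2):
            raise ValueError("section must have exactly 23 nodes")
        counts = {"bm": 0, "tm": 0, "ooc": 0}
        for tags in self.node_tags:
            for t in tags:
                counts[t] += 1
        if counts != {"bm": 13, "tm": 6, "ooc": 5}:
            raise ValueError(f"bad tag counts {counts}")
        _check_connectivity(self)


_NAMED_NODES = {
    "bm_medial": 0, "ipc_root": IPC_ROOT, "opc_root": OPC_ROOT,
    "bm_lateral": 12, "tunnel_tip": N_TUNNEL_TIP, "ohc1_apex": N_OHC1_APEX,
    "ohc2_apex": N_OHC2_APEX,
    "ohc1_joint": N_JOINT1,
    "dc1_root": DC_ROOTS[0], "dc2_root": DC_ROOTS[1], "dc3_root": DC_ROOTS[2],
    "tm_attach": N_TM_ATTACH, "tm_junction": N_TM_JUNCTION,
    "tm_hb1": N_TM_HB1, "tm_hb2": N_TM_HB2, "tm_hb3": N_TM_HB3,
    "tm_lateral": N_TM_LATERAL,
}


def _check_connectivity(sec: SectionGeometry) -> None:
    """Every TM node must reach the limbal attachment; every OoC node the BM."""
    adj: dict[int, set[int]] = {i: set() for i in range(23)}
    for el in sec.elements:
        i, j = el.nodes
        adj[i].add(j)
        adj[j].add(i)

    def reachable(start: set[int]) -> set[int]:
        seen, stack = set(start), list(start)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen

    whole = reachable({0})
    if len(whole) != 23:
        missing = sorted(set(range(23)) - whole)
        raise ValueError(f"element graph is disconnected; isolated {missing}")
    from_limbus = reachable({N_TM_ATTACH})
    if not set(N_TM) <= from_limbus:
        raise ValueError("a TM node is unreachable from the limbal attachment")
    from_bm = reachable(set(N_BM))
    interior = {N_TUNNEL_TIP, N_OHC1_APEX, N_OHC2_APEX, N_JOINT1}
    if not interior <= from_bm:
        raise ValueError("an OoC node is unreachable from the BM")


def default_landmarks(x: float, materials: MaterialTable | None = None
                      ) -> dict[str, tuple[float, float]]:
    """Mean-anatomy landmark positions (um) at position ``x``.

    The 14 landmarks are generated parametrically from the interpolated
    dimensions so that sections built anywhere in 2-10 mm share a consistent
    anatomy: pillar roots at fixed fractions of the BM width, tunnel height
    proportional to the width, OHC axes leaning laterally by ~25 deg from the
    transverse axis, and the TM overlying the bundles at the interpolated
    bundle height.
    """
    mats = materials or MaterialTable()
    w = mats.value("bm_width", x)
    l_ohc = mats.value("ohc_length", x)
    h_hb = mats.value("hb_height", x)
    w_tm = mats.value("tm_width", x)
    t_tm = mats.value("tm_body_thickness", x)

    ipc = (0.17 * w, 0.0)
    opc = (0.33 * w, 0.0)
    tip_r = 0.25 * w
    tip_t = 0.21 * w                       # tunnel height scales with width
    tilt = math.radians(OHC_TILT_DEG)
    dr, dt = l_ohc * math.sin(tilt), l_ohc * math.cos(tilt)

    # OHC apexes are placed so each soma lands close to its Deiters-cell
    # root on the BM (roots at 0.50/0.58/0.67 of the width): the first-row
    # OHC and Deiters cell are then nearly collinear, as in the anatomy
    apex = {}
    for i, (row, root_frac) in enumerate(zip((1, 2, 3), (0.50, 0.58, 0.67))):
        r = root_frac * w - 0.03 * w - dr
        t = tip_t - 0.012 * w * (i + 1)
        apex[row] = (r, t)

    lm: dict[str, tuple[float, float]] = {
        "bm_medial": (0.0, 0.0),
        "bm_lateral": (w, 0.0),
        "ipc_root": ipc,
        "opc_root": opc,
        "tunnel_tip": (tip_r, tip_t),
    }
    for row in (1, 2, 3):
        r, t = apex[row]
        lm[f"ohc{row}_top"] = (r, t)
        lm[f"ohc{row}_bottom"] = (r + dr, t - dt)
    lm["hb2_tip"] = (apex[2][0], apex[2][1] + h_hb)
    lm["hb3_tip"] = (apex[3][0], apex[3][1] + h_hb)
    tm_t = apex[3][1] + h_hb + 0.5 * t_tm
    lm["tm_medial"] = (apex[3][0] - w_tm, tm_t + 0.05 * w_tm)
    return lm


def read_landmarks_csv(path) -> dict[str, tuple[float, float]]:
    """Read a landmark table (columns: label, r_um, t_um)."""
    out: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["label"]] = (float(row["r_um"]), float(row["t_um"]))
    return out


def write_landmarks_csv(path, landmarks: dict[str, tuple[float, float]]) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["label", "r_um", "t_um"])
        for label, (r, t) in landmarks.items():
            wr.writerow([label, f"{r:.4f}", f"{t:.4f}"])


def _circle(d: float) -> tuple[float, float]:
    return math.pi * d * d / 4.0, math.pi * d ** 4 / 64.0


def build_section(x: float, materials: MaterialTable | None = None,
                  landmarks: dict[str, tuple[float, float]] | None = None,
                  spacing_um: float = 10.0,
                  tm_scale: float = 1.0, dc_scale: float = 1.0,
                  bm_scale: float = 1.0, rl_scale: float = 1.0,
                  php_scale: float = 1.0,
                  hb_axial_factor: float = 100.0,
                  php_span: int = 3) -> SectionGeometry:
    """Build the 23-node radial section at ``x`` mm from the basal end.

    ``spacing_um`` is the longitudinal tributary width of the section (the
    out-of-plane width of plate-like elements).  The ``*_scale`` factors
    multiply the Young's moduli of the corresponding structure and are the
    handles used by the stiffness-ratio sweeps.

    Parameters
    ----------
    hb_axial_factor : float
        Stiffness of the hair bundle along its axis (compression of the
        stereocilia) expressed as a multiple of its deflection (shear)
        stiffness.  Stereocilia are far stiffer axially than in bending.
    php_span : int
        Longitudinal span of the Deiters-cell phalangeal process in cell
        spacings (the process reaches the reticular lamina two to four cells
        apically); used here only to set the process rest length.
    """
    if not (X_ANCHOR_B - 1e-9 <= x <= X_ANCHOR_A + 1e-9):
        raise ValueError(
            f"x={x} mm outside the anchored range "
            f"[{X_ANCHOR_B}, {X_ANCHOR_A}] (no extrapolation)")
    mats = materials or MaterialTable()
    lm = dict(landmarks) if landmarks is not None else default_landmarks(x, mats)
    missing = [lab for lab in LANDMARK_LABELS if lab not in lm]
    if missing:
        raise ValueError(f"missing landmarks: {missing}")

    h = spacing_um
    w = abs(lm["bm_lateral"][0] - lm["bm_medial"][0])

    nodes = np.zeros((23, 2))
    r0 = lm["bm_medial"][0]
    nodes[N_BM, 0] = r0 + _BM_FRACTIONS * w
    nodes[N_BM, 1] = 0.0
    # honor the measured pillar-root positions
    nodes[IPC_ROOT] = lm["ipc_root"]
    nodes[OPC_ROOT] = lm["opc_root"]
    nodes[N_TUNNEL_TIP] = lm["tunnel_tip"]
    nodes[N_OHC1_APEX] = lm["ohc1_top"]
    nodes[N_OHC2_APEX] = lm["ohc2_top"]
    nodes[N_JOINT1] = lm["ohc1_bottom"]

    # TM chain: attachment, root/body junction, nodes above the three bundle
    # rows, lateral end.
    tm_med = np.asarray(lm["tm_medial"])
    w_tm = mats.value("tm_width", x)
    tm_end_r = lm["ohc3_top"][0] + 0.02 * w_tm
    hb_rs = np.array([nodes[N_OHC1_APEX, 0], nodes[N_OHC2_APEX, 0],
                      lm["ohc3_top"][0]])
    junction_r = tm_med[0] + w_tm / 3.0
    # the TM centerline is kept straight (radial), so its radial stiffness
    # is the axial series of root and body with no spurious bending softness
    tm_rs = [tm_med[0], junction_r, *hb_rs, tm_end_r]
    for nid, r in zip(N_TM, tm_rs):
        nodes[nid] = (r, tm_med[1])

    node_tags: list[frozenset[str]] = []
    for i in range(23):
        tags = set()
        if i in N_BM:
            tags.add("bm")
        if i in N_TM:
            tags.add("tm")
        if i in (IPC_ROOT, N_TUNNEL_TIP, N_OHC1_APEX, N_OHC2_APEX, N_JOINT1):
            tags.add("ooc")
        node_tags.append(frozenset(tags))

    # --- element list -----------------------------------------------------
    els: list[Element] = []
    t_fib = mats.value("bm_fiber_thickness", x)
    t_mid = mats.value("bm_mid_thickness", x)
    e_bm = mats.value("bm_modulus_radial", x) * bm_scale
    # pars arcuata runs from the spiral lamina to the outer-pillar foot;
    # pars pectinata from there to the spiral ligament
    for i in range(12):
        arcuate = i < OPC_ROOT
        t_eff = t_fib / 2.0 if arcuate else t_fib
        els.append(Element(
            (i, i + 1), "bm-arcuate" if arcuate else "bm-pectinate",
            area=t_eff * h, second_moment=h * t_eff ** 3 / 12.0,
            modulus=e_bm,
            extra_mass_area=(t_mid * h if not arcuate else 0.0)))

    # cellular members occur once per CELL_PITCH_UM of cochlear length;
    # a section of tributary width h carries h/pitch of each
    cells = h / CELL_PITCH_UM
    a_p, i_p = _circle(mats.value("pillar_diameter", x))
    a_p, i_p = a_p * cells, i_p * cells
    e_p = mats.value("pillar_modulus", x)
    els.append(Element((IPC_ROOT, N_TUNNEL_TIP), "ipc", a_p, i_p, e_p))
    els.append(Element((OPC_ROOT, N_TUNNEL_TIP), "opc", a_p, i_p, e_p))

    t_rl = mats.value("rl_thickness", x)
    e_rl = mats.value("rl_modulus_radial", x) * rl_scale
    for n1, n2 in ((N_TUNNEL_TIP, N_OHC1_APEX), (N_OHC1_APEX, N_OHC2_APEX)):
        els.append(Element((n1, n2), "rl-ohc", t_rl * h,
                           h * t_rl ** 3 / 12.0, e_rl))

    a_ohc, i_ohc = _circle(mats.value("ohc_diameter", x))
    a_ohc, i_ohc = a_ohc * cells, i_ohc * cells
    e_ohc = mats.value("ohc_modulus", x)
    els.append(Element((N_OHC1_APEX, N_JOINT1), "ohc-row1",
                       a_ohc, i_ohc, e_ohc))
    a_dc, i_dc = _circle(mats.value("dc_base_diameter", x))
    a_dc, i_dc = a_dc * cells, i_dc * cells
    e_dc = mats.value("dc_base_modulus", x) * dc_scale
    els.append(Element((N_JOINT1, DC_ROOTS[0]), "dc-base", a_dc, i_dc, e_dc))

    # rows 2 and 3: OHC and DC base in series, as a direct axial link from
    # the RL down to the Deiters-cell root on the BM (the third row is
    # lumped onto the second-row apex)
    l_ohc = mats.value("ohc_length", x)
    k_ohc = _axial_k(e_ohc, a_ohc, l_ohc)
    for apex, root, role in ((N_OHC2_APEX, DC_ROOTS[1], "ohc-row2"),
                             (N_OHC2_APEX, DC_ROOTS[2], "ohc-row3")):
        l_dc = max(np.linalg.norm(nodes[N_JOINT1] - nodes[DC_ROOTS[0]]), 1.0)
        k_dc = _axial_k(e_dc, a_dc, l_dc)
        k_series = 1.0 / (1.0 / k_ohc + 1.0 / k_dc)  # mN/m
        els.append(Element((apex, root), role, k_direct=k_series,
                           extra_mass_area=a_ohc))

    # phalangeal process: slanted truss from the row-1 joint to the RL at
    # the second-row apex `php_span` cells apically; the tabulated
    # stiffness is EA/L over its true 3-D length, at the per-section cell
    # density (the assembler orients the member)
    a_php, i_php = _circle(mats.value("dc_process_diameter", x))
    e_php = mats.value("dc_process_modulus", x) * php_scale
    run = php_span * CELL_PITCH_UM
    l_inplane = np.linalg.norm(nodes[N_OHC2_APEX] - nodes[N_JOINT1])
    l_php = math.hypot(l_inplane, run)
    k_php = _axial_k(e_php, a_php, l_php) * cells
    els.append(Element((N_JOINT1, N_OHC2_APEX), "dc-php",
                       a_php * cells, i_php * cells, k_direct=k_php))

    # hair bundles: direct links, stiffness k_HB against deflection (radial
    # shear between TM and RL), hb_axial_factor*k_HB along the bundle axis
    k_hb = mats.value("hb_stiffness", x) * cells
    for tm_n, rl_n, role in ((N_TM_HB1, N_OHC1_APEX, "hb-row1"),
                             (N_TM_HB2, N_OHC2_APEX, "hb-row2"),
                             (N_TM_HB3, N_OHC2_APEX, "hb-row3")):
        els.append(Element((tm_n, rl_n), role, k_direct=k_hb))

    t_root = mats.value("tm_root_thickness", x)
    t_body = mats.value("tm_body_thickness", x)
    e_root = mats.value("tm_root_modulus", x) * tm_scale
    e_body = mats.value("tm_body_modulus", x) * tm_scale
    els.append(Element((N_TM_ATTACH, N_TM_JUNCTION), "tm-root",
                       t_root * h, h * t_root ** 3 / 12.0, e_root))
    chain = [N_TM_JUNCTION, N_TM_HB1, N_TM_HB2, N_TM_HB3, N_TM_LATERAL]
    for n1, n2 in zip(chain[:-1], chain[1:]):
        els.append(Element((n1, n2), "tm-body",
                           t_body * h, h * t_body ** 3 / 12.0, e_body))

    sec = SectionGeometry(
        x=x, nodes=nodes, node_tags=node_tags, elements=els,
        bm_width=w, fixed_nodes=(0, 12, N_TM_ATTACH),
        landmarks=lm)
    sec.validate()
    # the hair-bundle axial factor is consumed by the assembler; stash it
    sec.hb_axial_factor = hb_axial_factor  # type: ignore[attr-defined]
    return sec


def _axial_k(e_mpa: float, a_um2: float, l_um: float) -> float:
    """EA/L in mN/m for modulus in MPa, area in um^2, length in um."""
    # MPa * um^2 / um = 1e6 N/m^2 * 1e-12 m^2 / (1e-6 m) = 1 N/m = 1e3 mN/m
    return e_mpa * a_um2 / l_um * 1e3


def element_stiffness(element: Element, nodes: np.ndarray | None = None
                      ) -> tuple[float, float]:
    """Axial (EA/L) and bending (3EI/L^3) stiffness of an element, in mN/m.

    Direct-stiffness links return their tabulated stiffness for both entries.
    ``nodes`` supplies end coordinates (um) for beam elements.
    """
    if element.k_direct is not None:
        return element.k_direct, element.k_direct
    if nodes is None:
        raise ValueError("node coordinates required for beam elements")
    i, j = element.nodes
    length = float(np.linalg.norm(nodes[j] - nodes[i]))
    if length <= 0:
        raise ValueError("zero-length element")
    axial = _axial_k(element.modulus, element.area, length)
    bending = 3.0 * element.modulus * element.second_moment / length ** 3 * 1e3
    return axial, bending


def section_to_json(sec: SectionGeometry) -> str:
    """Structured JSON export of a section (nodes, elements, tags, BCs)."""
    payload = {
        "x_mm": sec.x,
        "bm_width_um": sec.bm_width,
        "nodes": [{"id": i, "r_um": float(r), "t_um": float(t),
                   "tags": sorted(sec.node_tags[i]),
                   "fixed": i in sec.fixed_nodes}
                  for i, (r, t) in enumerate(sec.nodes)],
        "elements": [{"nodes": [int(n) for n in el.nodes], "role": el.role,
                      "area_um2": float(el.area),
                      "I_um4": float(el.second_moment),
                      "E_MPa": None if el.modulus is None else float(el.modulus),
                      "k_mN_per_m": (None if el.k_direct is None
                                     else float(el.k_direct))}
                     for el in sec.elements],
    }
    return json.dumps(payload, indent=1)
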