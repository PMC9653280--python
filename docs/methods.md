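# Methods

## Model summary

The package simulates an excised gerbil cochlear turn sealing the slit of
a two-channel microfluidic chamber, and the analysis chain applied to
two-angle OCT vibrometry of that preparation. The solid is linear
elastic, the fluid incompressible and inviscid, and all solutions are
static or time-harmonic; there is no electromotile transduction — OHC
forces, when present, are prescribed force couples.

### Structure

Radial sections with 23 nodes (13 basilar-membrane, 6 tectorial-membrane,
5 organ-of-Corti nodes; the inner-pillar root carries both the BM and OoC
tags) are repeated along the cochlea and coupled longitudinally. Each
node has four DOFs: radial and transverse translations, a longitudinal
translation, and the in-plane rotation. In-section members are planar
frame elements (axial + Euler–Bernoulli); the longitudinal DOF carries
the members' out-of-plane bending/shear, the stretch and in-plane shear
of the BM/TM/RL plate strips between sections, and the true 3-D axis of
the Deiters-cell phalangeal process. Longitudinal plate bending uses a
second-difference stencil, which converges under section refinement
(pairwise "beam" springs between sections do not). Cellular members
(pillars, OHCs, DCs, bundles, processes) occur once per 10 µm of
cochlear length; their sectional properties scale with the section
spacing so that line densities are mesh-independent.

The first OHC row is modeled in full: apex on the reticular lamina,
nearly collinear OHC–DC column, and an explicit OHC/DC joint node — the
row on which all deformation-ratio measurements are made. Rows 2 and 3
are series OHC+DC links, with row 3 lumped onto the row-2 apex to respect
the 23-node budget. Hair bundles are direct-stiffness links whose stiff
axis is the anatomical bundle axis (normal to the RL), with the
tabulated deflection stiffness in shear; their axial stiffness is 100×
the deflection stiffness (stereocilia are far stiffer in compression
than in pivoting — results are insensitive to this factor once ≫1).

Boundary conditions: both longitudinal ends clamped, BM medial and
lateral edges clamped in every section, TM clamped at the spiral limbus.

### Materials

Properties are anchored at x = 10 and 2 mm from the base and interpolated
exponentially, p(x) = p_b·exp(s(x−x_b)), s = (ln p_b − ln p_a)/(x_b−x_a)
— exact at the anchors and log-linear in between. The arcuate zone
(spiral lamina to outer-pillar foot) carries half the pectinate fiber
thickness; the mid-pectinate layer contributes mass only. The TM is split
into root and body regions, the root half as long and half as thick as
the body, each with its own radial modulus; the TM centerline is kept
straight so its radial stiffness is the pure axial series of the two
regions.

### Damping

`C = αM + βK` with α = 0 and β calibrated so an OHC soma dissipates
5 nN·s/m per 10 µm of its length (≈24 nN·s/m at x = 8.5 mm). Three
further dissipation channels, each at its standard literature scale, are
required for the model to reproduce the smooth second-order behavior the
preparation exhibits; without them the model rings with internal TM/RL
modes:

* viscous drag of 1 kN·s/m³ on each fluid-facing membrane surface (BM
  and TM), by tributary area — the classic per-area damping of cochlear
  partition models;
* squeeze-film resistance of the subtectorial gap against normal TM–RL
  motion, 1e-4 N·s/m per 10 µm section — a conservative fraction of the
  continuum estimate µb³/g³ for micron-scale gaps;
* shear of the subtectorial film, 100 nN·s/m per 10 µm section, and a
  TM material loss tangent of 0.3 at 1 kHz (TM gels show loss tangents
  of 0.3–1 at audio frequencies), added as stiffness-proportional
  damping on the TM elements.

### Fluid

Two rectangular channels (10 mm long, 1 mm high, 4 mm deep — the chamber
must seat the ≈3 mm turn) separated by a partition with a slit sealed by
the tissue. The pressure Laplacian is discretized cell-centered
finite-volume on a tensor grid graded toward the slit; the default is a
3-D box in which the slit strip (the BM width) is resolved across the
chamber depth, because a strip much narrower than the chamber entrains
far less fluid than a planar (flow × transverse) reduction suggests. The
planar variant remains available. Coupling matrices are built so the
added-mass operator A_ap A_pp⁻¹ A_pa is symmetric positive semidefinite
by construction. The vertical grid near the partition resolves the strip
near-field (cell height ≈ strip width / 6).

Hydrostatic loads act on the BM-facing interface only (scala-tympani
pressurization); harmonic runs drive the stimulus port and, following the
experimental normalization, report BM motion relative to the pressure at
a hydrophone cell in the chamber floor beneath the tissue (an electret
microphone is wall-mounted). Port normalization is available.

## Operational definitions

* k_HB — tabulated bundle stiffness per cell;
* k_TM — radial series stiffness of TM root+body per 10 µm section;
* k_OHC, k_DC — EA/L of the row-1 OHC soma and DC base;
* sweeps rescale exactly one modulus set so the named ratio takes each
  grid value (default 9 points, log-spaced over 0.1–10), solve at 1 kHz
  (x = 8.5 mm), and record Δ_TM/Δ_HB, θ_TM, Δ_DC/Δ_OHC, θ_DC at the
  measured anatomic points; inference is log-log interpolation of the
  measured ratio (±SD propagated through the same curve);
* corner frequency — the −3 dB crossing relative to the low-frequency
  asymptote, located by log-log interpolation; the high-frequency slope
  is fitted over 2.5–5 kHz; phase span is the unwrapped phase drop over
  0.3–5 kHz;
* contact stiffness — unit transverse point force at the first-row
  DC root (the measured peak-displacement location), force over local
  displacement, after the BM fiber modulus is scaled so the model's
  static volume compliance equals the measured 16.1 mm⁴/N (fixed-point
  iteration, <0.5% residual);
* k_OoC,OHC — f_OHC/Δ_OHC − k_OHC under a single-cell force couple, with
  Δ_OHC the axial apex→joint length change.

## Problem sizes

Sweeps and static analyses use a 0.6 mm span at 10 µm spacing
(≈5600 DOFs); frequency-response studies use the full 4 mm turn at 20 µm
spacing (≈18500 structural DOFs + ≈16000 fluid cells), centered at
x = 8 mm so the probed section at 8.5 mm lies inside. Convergence was
checked by section-spacing halving (static peak changes <0.5% per
halving) and fluid-cell halving (interface pressure <2%).

## Synthetic data

The generators emulate: two-angle scans (projection of true in-plane
complex motion on two beam axes, default −30°/13°, plus isotropic complex
Gaussian noise of 10% relative magnitude — the stated estimation error at
100 nm); band-limited speckle pairs with exact Fourier subpixel shifts
and 5% sensor noise; and 14-point landmark sets whose scatter reproduces
the measured BM-width SD (12 µm at x = 8.5 mm). They do not emulate OCT
image formation (coherence gating, shadowing, angle-dependent TM
reflectivity) or nonrigid tissue distortion between scan sets, so passing
recovery tests demonstrate correctness of the analysis chain, not
robustness to real-image artifacts. Anatomic-point motions in recovery
studies are averaged over a 25-pixel neighborhood, emulating the
interpolation of scattered M-scan data onto anatomic points.

## Design choices on genuinely open points

* The printed gradient formula does not return the anchored value at the
  anchor; the log-linear form above (which does) is used.
* Angle convention: from the transverse axis, positive toward the lateral
  radial direction, reported in (−90°, 90°]; motion direction is the
  major axis of the displacement ellipse (time-sampled maximization is
  the test oracle for the analytic eigen-decomposition).
* Δ_TM is the end-to-end length change of the limbus→(above second-row
  bundle) chord, not an arc length.
* Chamber dimensions are not published; defaults put the stimulus port a
  tissue-length away from the slit and are configurable.
* The NCC estimator uses windowed cross-correlation with Fourier-upsampled
  peaks (scikit-image). For displacement *fields* use small windows; for
  a global shift the window should approach the frame, since truncation
  noise dominates at 0.05 px shifts.

## Known limitations

* The deformation-ratio curves cross the measured values at r_TM ≈ 3.9
  and r_DC ≈ 1.6, outside the reported 2.1 ± 0.4 and 2.7 ± 0.8. The
  effective number of bundle rows loading the TM root path (≈2.3 here)
  and the force share between the OHC and its Deiters cell depend on
  fine details of the TM/bundle/RL arrangement that anatomy does not pin
  down; the curves' shapes (≈1/r, rotation-center migration) are
  reproduced.
* The log-log sweep slope over r_TM ∈ [0.3, 3] is −1.56: at 1 kHz a TM
  sub-resonance inflates the curve at the soft end of that window; the
  slope approaches −1 for r_TM ≳ 1.
* The stiffness felt by the OHC (r_DC = 2.5) is 2.5–3.0× k_OHC across
  positions, above the 0.5–1.5 band quoted per 10 µm section: the model's
  longitudinally-spread BM support under the DC root is stiffer than a
  per-section normalization implies.
* Above ≈2.5 kHz a damped TM-radial resonance leaves a shelf in the
  frequency response; the fitted top-octave slope is ≈ −10 dB/octave
  rather than −12.
* The force-couple deformation pattern concentrates at the OHC/DC joint;
  the observed pattern in which the reticular lamina moves much more
  than the basilar membrane is not reproduced (the short RL stub to the
  pillar head clamps the apex strongly in this node layout).
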