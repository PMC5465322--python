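# epiboly

A physical model and analysis toolkit for the spreading of embryonic
deep-layer cells (DCL) over the extra-embryonic enveloping layer (EVL)
during teleost epiboly, built for the annual-killifish setting where a
low-density mesenchymal-like cell population disperses over a ~592 μm egg
well before gastrulation.

The core is a three-force interacting-particle model on the egg sphere.
EVL cells are polygonal; their vertices form a spring network (harmonic
edge springs and across-cell "opposite-vertex" springs, elastic constant
U₀) whose free vegetal margin advances at constant speed V₀, stretching the
epithelium vegetally. Deep cells are soft-sphere particles obeying an
overdamped equation of motion

    dr_i/dt = F_rep(U₁) + F_att(U₂, a₂) + drag · v_EVL(r_i) + ξ_i(σ)

with (i) overlap repulsion of amplitude U₁, (ii) a Gaussian attraction well
of amplitude U₂ and width a₂ centred on the EVL cell-border polylines,
(iii) advection by the local EVL velocity field, interpolated with
barycentric weights γ over the Delaunay triangulation of EVL vertices
(Σγ = 1), scaled by the adhesion coupling `drag` ∈ [0, 1], and (iv)
tangential Gaussian noise ξ setting the autonomous random-walk diffusion.
Deep cells divide once each at scheduled times, daughters keeping
(1/2)^(1/3) of the parent radius (volume halving).

Around the model sit the analysis tools used to confront it with tracked
cells: sphere fitting and projection, rotational-drift removal, geodesic
and spherical-polygon measurements, greedy track linking with QC flags,
MSD/diffusion fitting (D = slope/4 for the surface walk), decomposition of
trajectories into EVL-advected and autonomous components via three
deformation models, second-moment shape indices with a protrusion
classifier (1.1 μm² / eccentricity 0.97 / solidity 0.65 cascade), and
Nelder–Mead fitting of free parameters against four track statistics.
Because the original 4D recordings are not archived, a synthetic-data
module generates every input with known ground truth.

## Worked example

`examples/01_simulate_epiboly.py` builds a 55-cell EVL cap with 110 deep
cells and runs 10 hours of simulated epiboly at the fitted optimum
(drag = 1, σ = 2×10⁴, U₂ = 0.3):

```
frame   0 (   0 min): epiboly index  31.9 %, 110 DCL cells, EVL area 1.404 mm², DCL covered area 1.130 mm²
frame  30 ( 300 min): epiboly index  37.9 %, 176 DCL cells, EVL area 1.669 mm², DCL covered area 1.406 mm²
frame  59 ( 590 min): epiboly index  43.9 %, 220 DCL cells, EVL area 1.933 mm², DCL covered area 1.660 mm²
```

The epiboly index is the fractional advance of the EVL margin along the
animal–vegetal axis (50% = equator); the deep-cell count doubles through
asynchronous division while both tissue areas expand together.
`examples/02_track_statistics.py` then measures the spreading statistics
on such a run:

```
random-walk diffusion: D = 32.2 μm²/s (generated at 31.2), r² = 0.9999
distance-to-border mode at 2.5 μm; 65 % of cells within 20 μm of a border (uniform baseline: 31 %)
DCL covered area vs total EVL area: slope 1.12, r² = 0.9967 (tightly coupled spreading)
```

i.e. the model reproduces the hallmark behaviours: near-perfect linear
coupling between DCL and EVL areas, and a strong concentration of deep
cells along EVL cell borders relative to the uniform-placement baseline.
The other examples cover motion decomposition (`03`), parameter recovery
by simplex fitting (`04`) and protrusion morphometrics (`05`).

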