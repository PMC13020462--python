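# Methods

This note documents the models, numerical methods and design choices behind
`thoraxfem`: a quasi-static conduction finite-element pipeline that asks
whether a four-electrode (tetrapolar) surface impedance measurement can
track fluid accumulating in the lower lobes of the lungs.

## Physical model

Within each tissue the potential obeys the quasi-static conduction equation

    div( kappa grad V ) = 0,

with admittivity `kappa = sigma` in real (conduction-only) mode and
`kappa = sigma + i * 2*pi*f * eps0 * eps_r` in complex mode.  All outer
boundaries and the inner surfaces of the airways are insulating
(`J . n = 0`).  Electrodes follow the complete electrode model with zero
contact impedance: each circular patch is an equipotential that exchanges a
prescribed total current with the body.  The drive pair carries +-I0
(default 1 mA peak); sense electrodes float with zero net current.

Transfer impedance is computed two ways:

* voltage route: `Z = (V_C - V_D) / I0` from the drive solution;
* reciprocity route: the volume impedance density
  `z = (1/kappa) (J_AB . J_CD) / I0^2` (non-conjugated dot product in
  complex mode) integrated over the volume.

For a Galerkin P1 discretization the two routes coincide to machine
precision (`V_AB^T K V_CD = I0 (V_C - V_D)`), so their agreement validates
the implementation's internal consistency, not its accuracy; accuracy is
established against closed-form oracles (half-space four-point formula,
1-D cylinder conduction) and the mesh-convergence study.  `z` integrated
over a region gives that region's additive contribution to Z; the sign of
`z` is indefinite (tetrapolar arrays have negative-sensitivity lobes close
to the surface between electrode pairs, which is visible in the
depth-resolved maps).

Both lead solves share one stiffness factorization: the return electrode of
the drive pair is grounded in both systems and the reciprocal solution is
shifted afterwards so its own sink patch reads 0 V — exact for a
conduction problem, whose solution is unique up to a constant.

## Synthetic thorax

The anatomy is parametric (no imaging data) and volume-matched to a
segmented adult thorax: total conductor volume 23.4 L and inflated-lung
volume 4.84 L, both realized by auto-scaling.

* **Torso**: elliptic cylinder, semi-axes auto-scaled at fixed aspect so
  `pi*a*b*h` equals the target volume exactly.  Defaults give chest-like
  proportions (transverse/AP ratio 1.44, 38 cm segment height).  Flat caps
  keep the analytic volume exact and the extruded structured mesh
  conforming; the caps are far from the electrodes.
* **Lungs**: vertically truncated half-ellipsoids, base plane cut below the
  equator (wide diaphragm-side base, tapering apex).  Both sides share one
  in-plane footprint; each side's vertical semi-axis is solved (bisection
  on the closed-form truncated-ellipsoid volume, then a fixed point against
  the carved volume) so realized volumes split 53/47 right/left of the
  4.84 L total.  The left lung is displaced 12 mm posteriorly — the cardiac
  impression — which is what makes left-side measurements less sensitive to
  pooled fluid than right-side ones (the fluid is deeper under the left
  array).
* **Heart**: a 0.73 L ellipsoid, two thirds left of the midline, anterior,
  resting just above the diaphragm level.  Where it overlaps the lung
  solids it takes precedence (cardiac notch); left lower-lobe fluid is
  therefore partly retrocardiac.
* **Ribs**: 12 pairs of 4 mm-radius bars on an elliptical shell at 90% of
  the torso semi-axes, interrupted at sternum and spine; toggleable.
* **Airways**: trachea plus two main bronchi; the lumina are excluded from
  the conductive domain and their exposed walls form the insulating
  `airway_wall` patch.
* **Fluid**: gravity-dependent pooling, `lung AND {z < cut_height}`, with
  the cut height found by bisection on a tabulated volume-vs-height profile
  (midpoint-rule quadrature on a fixed grid, linearized within slabs);
  realized volumes land well inside the 1% contract.
* **Electrodes**: four 1 cm discs at the corners of an 8 cm square in the
  unrolled surface metric (arc length along the anterior ellipse arc x
  height), centred over the chosen lung.  At zero vertical offset the
  bottom row is level with that lung's lower margin.  The default corner
  assignment drives through one vertical edge and senses on the other; the
  assignment is configurable since published tetrapolar layouts differ.

Points are classified by precedence (airway lumen > heart > fluid > lung >
rib > soft tissue), which keeps regions disjoint by construction.

### What the generator does and does not emulate

It reproduces gross volumes, left-right asymmetry of the cardiac anatomy,
rib shielding, airway insulation and dependent pooling.  It does not
reproduce subject-specific lobe shapes, the posterior-dominant anatomy of
the real lower lobes, skin, great vessels, tissue anisotropy or
respiratory motion.  Consequently the absolute impedances (about 13 ohm at
the reference position versus about 15 ohm reported for a CT-derived
anatomy) and regional percentages transfer only at the order-of-magnitude
level, while the robust findings - linearity of Z versus pooled volume,
right-over-left sensitivity, contralateral isolation below the 2% noise
band, spectral behaviour, mesh independence - are reproduced and tested.

One known deviation: with the heart resting at the lung-base level the
left-side vertical profile of baseline impedance is nearly flat rather
than clearly decreasing with height (the conductive heart lowers the
lowest-position reading); the profile still satisfies
`Z(lowest) > Z(highest)`.  The strictly decreasing profile is recovered on
the right side.

## Tissue properties

The 10 kHz values are literature constants used by the single-frequency
studies: inflated lung 0.0932 S/m / 17,174; thoracic soft tissue
0.18233 / 13,497; rib (average of cancellous and cortical bone)
0.0515 / 1,089; heart 0.1542 / 70,054; body fluid 1.5 / 98; stainless
steel 4e6 / 1.  Rows at 5-1000 kHz are representative values following the
beta-dispersion trends of the published tissue-dielectric database family
(sigma non-decreasing, eps_r non-increasing with frequency) and are marked
as such in the table's provenance column; they can be replaced by loading
a user CSV.  Lookup at untabulated frequencies interpolates log-log; no
extrapolation.  Real mode is the default at 10 kHz; frequency sweeps use
complex admittivity and report |Z|.

## Discretization

The torso cross-section is meshed by transfinite interpolation of the
ellipse between corner angles (30/150/210/330 degrees), with interior
nodes relaxed by a weighted graph-Laplace (Tutte) solve — fold-free on a
convex boundary and exactly reproducing graded tensor grids on rectangles.
The section is extruded along z and every hexahedral cell is split into
six tetrahedra (Freudenthal), which is conforming when all cells share the
split orientation.  Gridlines are graded: bulk target size 10.5 mm at the
`normal` level, scaled by 2.2 / 1.5 / 1.0 / 0.7 for the four refinement
levels, with z-lines snapped to the lung-base and fluid-cut planes.

Two choices keep the convergence ladder clean:

* **Pinned electrode patches.** The gridlines inside each electrode band
  are exact multiples of a fixed 2.5 mm patch resolution with snapped band
  edges, identical at every refinement level.  The discrete patch geometry
  therefore does not jitter across the ladder (patch areas sit within 3%
  of the nominal disc at every level); without this, patch-shape jitter of
  1-3% dominated the level-to-level impedance differences.
* **Interface homogenization.** Element admittivity is the volume-fraction
  mixture of the region values, with fractions from fixed barycentric
  samples (11 points, re-sampled on a 165-point lattice for any element
  straddling an interface or within reach of a rib bar).  Airway-lumen
  mass contributes zero.  Binary centroid labelling is kept for reporting
  region volumes and regional contributions.

Linear solves use a sparse direct factorization up to 30k unknowns and
Jacobi-preconditioned CG (BiCGStab for complex systems) beyond, at a 1e-10
relative tolerance - orders of magnitude below every stated acceptance
band, and deterministic.  Meshing and solving contain no random number
draws, so identical inputs give bitwise identical sweeps.

Problem sizes: the four refinement levels carry roughly 0.14, 0.24, 0.45
and 0.90 million tetrahedra; protocol-level trend checks run at the
`coarser` level and the quantitative sweeps at `normal`, which the
convergence study shows is within 0.03% of the `fine` answer.

## Numerical details and edge cases

* Degenerate or inverted elements abort meshing with a descriptive error;
  orientation is normalized element-wise.
* The fluid bisection converges in at most 60 iterations for any target up
  to 90% of a lung volume; a zero target is the identity.
* Terminal currents are reported two ways: consistent (residual-based)
  fluxes, which satisfy the terminal constraint to solver tolerance and
  are the quantity checked at 0.5%, and raw one-sided surface integrals,
  which are edge-ring dominated for centimeter patches and reported only
  as a discretization-quality indicator.
* Planar sensitivity maps sample the element-wise field at the nearest
  element centroid on a 5 mm default grid; points outside the conductive
  domain are NaN.
* Empty sense patches, unknown tissues, frequencies outside 5-1000 kHz,
  overlapping electrodes and infeasible geometry parameters all raise
  descriptive errors rather than producing silent defaults.

## Reported study conditions

The shipped defaults are the study conditions: 10 kHz, 1 mA, 8 cm
separation, 1 cm electrodes, fluid volumes 0-670 mL in six steps, vertical
offsets 0-10 cm in 2 cm steps, frequencies 5-1000 kHz, four-level
convergence at the right lower position.  The 300 mL detectability case
computes a reduction of about 1.7 ohm on this synthetic anatomy; the
corresponding published figure (2 ohm on a subject-specific anatomy whose
impedance-volume relation is exactly linear) is compared at the 20%
tolerance class used for scaled-down reproductions.  The residual
curvature of the impedance-volume relation (r^2 about 0.97-0.98 versus
0.997-0.9998 published) is inherent to horizontal-plane pooling entering
the array's sensitive zone from below and is the main known gap between
the parametric and image-derived anatomies.
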