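# thoraxfem

Finite-element modelling of tetrapolar bioimpedance measurements of
pulmonary fluid accumulation.

Pulmonary edema — fluid collecting in the lower lobes of the lungs — is
common, dangerous, and poorly served by existing monitoring: imaging is
episodic, expensive or ionizing.  Because interstitial fluid (sigma about
1.5 S/m) is far more conductive than inflated lung tissue (about
0.09 S/m), a four-electrode impedance measurement on the chest surface is
a candidate for continuous, non-ionizing monitoring.  `thoraxfem` is a
simulation pipeline for studying that idea quantitatively: it generates a
parametric synthetic thorax (torso, lungs, heart, ribs, airways, pooled
fluid), meshes it, solves the quasi-static conduction problem with
tetrapolar terminal conditions, and runs the measurement protocols a
bench study would run.

It is aimed at bioimpedance and EIT researchers who want a fully
scriptable, dependency-light forward model with testable invariants.

## Model

The potential satisfies `div(kappa grad V) = 0` with insulating outer and
airway boundaries.  Electrodes are equipotential surface patches
(complete electrode model, zero contact impedance); a terminal condition
`int_S J.n dS = I0` drives the A-B pair and the C-D pair floats.  Two
quantities are computed per configuration:

* transfer impedance `Z = (V_C - V_D)/I0`, and
* the volume impedance density
  `z = (1/kappa) (J_AB . J_CD) / I0^2` (ohm/m^3),

whose volume integral equals Z (reciprocity).  `z` maps where tissue
changes actually influence the reading, and its regional sums decompose Z
additively by organ.  Protocols include vertical electrode sweeps,
fluid-volume sweeps with ordinary-least-squares slope and r^2,
frequency sweeps over 5–1000 kHz with complex admittivity, and a
four-level mesh-convergence study.

## Worked example

```python
from thoraxfem import (SolveSpec, assemble_system, build_geometry,
                       carve_fluid_region, default_table, generate_mesh,
                       percent_delta_Z, place_electrode_array,
                       regional_contribution, solve_tetrapolar)
from thoraxfem.thorax import FluidSpec

geometry = build_geometry()                       # 23.4 L torso, 4.84 L lungs
baseline = place_electrode_array(geometry, "right")
mesh = generate_mesh(baseline, "coarser")
result = solve_tetrapolar(assemble_system(mesh, default_table(), SolveSpec()))
print(f"mesh: {mesh.n_tets} tetrahedra")
print(f"Z (reciprocity integral) = {result.Z:.3f} Ohm")
print(f"Z (sense-voltage)        = {result.Z_voltage.Z:.3f} Ohm")
lungs = regional_contribution(result.field, mesh, ["lung_left", "lung_right"])
print(f"lung contribution        = {lungs:.3f} Ohm "
      f"({100 * lungs / result.Z:.1f}% of total)")

fluid = carve_fluid_region(geometry, FluidSpec("right", 0.300e-3))
mesh_f = generate_mesh(place_electrode_array(fluid, "right"), "coarser")
Zf = solve_tetrapolar(assemble_system(mesh_f, default_table(), SolveSpec())).Z
print(f"Z with 300 mL pooled fluid = {Zf:.3f} Ohm "
      f"(reduction {result.Z - Zf:.3f} Ohm, "
      f"{percent_delta_Z(result.Z, Zf):.1f}%)")
```

prints

```
mesh: 140157 tetrahedra
Z (reciprocity integral) = 13.081 Ohm
Z (sense-voltage)        = 13.081 Ohm
lung contribution        = 3.857 Ohm (29.5% of total)
Z with 300 mL pooled fluid = 11.404 Ohm (reduction 1.677 Ohm, 12.8%)
```

The two Z routes agree to machine precision (a property of the P1
discretization); the 300 mL pool of conductive fluid under the array
lowers the reading by about 1.7 ohm — far above the resolution of modern
tetrapolar instruments and above a ±2% measurement-noise band.

There is also a CLI for batch runs driven by a YAML config:

```bash
thoraxfem sweep-volume -c run.yaml      # Z vs fluid volume + line fit
thoraxfem convergence  -c run.yaml      # four-level mesh study
thoraxfem sensitivity-map -c run.yaml   # frontal-plane z maps
```

Each command writes CSV tables (tagged with the config hash), VTK field
exports and a run log into the configured output directory.

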