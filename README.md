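# tibfrac

Finite-element evaluation of tibial plateau fracture stabilization on a
synthetic voxel phantom.

After a split-depression (Schatzker II) tibial plateau fracture, surgeons
choose among stabilization variants — a bi-cortical (70 mm) or uni-cortical
(50 mm) cancellous screw, with or without PMMA cement augmentation — and
must decide how early the patient may bear full weight.  `tibfrac`
implements a patient-specific-modeling workflow for that question as a
reusable, tested pipeline driven by a synthetic phantom instead of a
patient CT: it rasterizes a labeled proximal-tibia phantom with the two
reduced fragments and the hardware, calibrates its density image against
phantom inserts, maps bone mineral density rho (g/cm3) to material
properties through power laws

    cortical:    E = 3890 rho^2.39 MPa,   yield = 141.6 MPa
    trabecular:  E = 6570 rho^1.37 MPa,   log10(yield) = 1.38 + 1.91 log10(rho)

(split at rho = 1.68 g/cm3, the intersection of the two modulus laws),
meshes every region with quadratic tetrahedra, and solves static linear
elasticity under the peak gait load (2.59 x body weight, 37/63% split over
403/374 mm2 condylar patches) with fixed distal supports.  Fracture
interfaces are frictionless contact (early, "mobile" healing), stiff ties
("bonded", callus stage), or merged geometry ("fused", remodeled); screw
and cement contacts are always bonded.  Each of the twelve scenarios
(2 screws x cement yes/no x 3 healing states) is summarized by von Mises
extrema, the volume of bone stressed beyond its local yield strength,
reduction-loss displacements, and interfragmentary strains (relative
interface movement / initial gap; < 10% is the cited stability criterion).

Audience: biomechanics researchers and students who want an end-to-end,
dependency-light reference implementation of the CT-to-FE bone-modeling
chain (calibration, density-modulus mapping, TET10 elasticity, contact,
fracture-stability metrics) that runs on a laptop.

## Worked example

```python
import tibfrac as tf

cfg = tf.RunConfig()                      # default phantom, 3 mm mesh, seed 0
spec = tf.build_scenario_matrix()[3]      # bi-cortical screw, no cement, mobile
report = tf.run_scenario(spec, cfg)
print(f"yield volume      {report.yield_volume_mm3:.1f} mm3")
print(f"depressed strain  {report.max_strain_depressed_pct:.2f} %")
print(f"separated strain  {report.max_strain_separated_pct:.2f} %")
print(f"stable            {report.stable}")
```

prints (about two minutes on one CPU):

```
yield volume      121.5 mm3
depressed strain  1.57 %
separated strain  0.48 %
stable            False
```

Without cement the early-weight-bearing (mobile) scenario overloads
trabecular bone next to the screw — the fragment load funnels through the
narrow screw-bone bearing — so a nonzero bone volume exceeds its local
yield strength and the scenario is flagged unstable.  Re-running with
`tf.build_scenario_matrix()[0]` (the surgeon's actual choice: bi-cortical
screw plus cement) gives a yield volume of 0.0 mm3 and a stable verdict:
the cement sleeve spreads the same load over a much larger interface.  The
full matrix and the comparison table come from:

```python
reports = tf.run_matrix(cfg)
frame, findings = tf.write_report(reports, out_dir="runs/default")
```

`findings` holds the directional checks (cement prevents yield in mobile
scenarios, cement lowers mobile strains, bonded strains are below mobile
strains) together with the measured uni- versus bi-cortical difference in
wedge opening.

The same pipeline is scriptable from the shell:

```sh
tibfrac -v run --out runs/default          # all 12 scenarios + table
tibfrac phantom --out runs/phantom         # just the NIfTI phantom
```

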