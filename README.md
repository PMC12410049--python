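# origamod

Design and analysis tools for **modular DNA-origami subunits**: triangular
origami building blocks whose assembly behaviour is programmed entirely
through 24 replaceable ssDNA strands, while the 204-staple core stays
fixed. For researchers building self-assembling nanostructures (2D
tilings, icosahedral shells, tubes) who want to go from a target geometry
to an orderable oligo list — and back from measured dimer fluctuations to
design conclusions — without redesigning origami from scratch.

## The model

Each subunit is a rigid triangular prism; each of its three faces can
carry four *top* and four *bottom* ssDNA extensions of the form
`anchor ⧺ poly-T ⧺ sticky end`. Two coupled design rules govern assembly:

* **Angle module.** The poly-T length difference between rows sets the
  binding angle between bonded subunits,
  θ = 2·arctan(λ·(l_top − l_bottom)/(2d)), calibrated so the
  demonstrated (l_top, l_bottom) = (14, 3) module gives θ = 41.8° — the
  angle at which five equilateral triangles close a vertex
  (180° − δ, sin(δ/2) = cos(π/5)/sin(π/3)). Equal lengths give planar
  bonds; l_top < l_bottom gives negative (concave) angles. A closed
  Caspar–Klug shell with T = h² + hk + k² needs 20·T subunits.
* **Bond module.** 5–7 nt sticky ends encode specificity and strength.
  Sets are generated orthogonal — every unintended pairing limited to a
  ≤ 3-base complementary run, verified exhaustively — with
  nearest-neighbor ΔG equalized within each length class.

On the analysis side, a bonded dimer is a harmonic torsional spring: its
binding-angle ensemble is Gaussian with spread σ, rescaled across
temperature by σ² ∝ T (cryo ensembles vitrify near 136 K), with
equipartition bending modulus k = (T/T₀)/σ_rad² in k_B·T₀/rad². A target
structure is *accessible* to a joint when its required angle lies within
c·σ of the mean (default c = 2.5); among accessible closed structures,
the smallest assembles first.

## Worked example

Design a T=4 icosahedral shell and analyze a joint ensemble:

```
$ origamod design --shell-T 4 --seed 7 -o t4.json
shell: 2 species, 32 sticky ends, 24/204 variable strands (11.8%), validation: OK

$ origamod simulate-ensemble --mean 21.6 --sigma 12.7 -n 100000 --seed 7 -o angles.csv
$ origamod analyze angles.csv
n=100000: mean 21.6 deg, sigma 12.7 deg at 298 K, bending modulus 20.4 kBT0/rad^2
```

The design line says the T=4 recipe needs two subunit species (mixed
3:1), 32 orthogonal sticky ends, and that only 24 of each subunit's 204
staples (11.8%) differ from the universal core — the economy of the
modular decomposition. The bundle JSON records species, interaction
matrix, angle modules ((14,3) on the convex five-fold faces, (3,3) on
the flat intra-tetramer faces) and the sequences; `origamod emit` turns
it into an oligo CSV/FASTA. The analysis line fits the angle ensemble
and converts the 12.7° spread into a ~20.4 k_BT₀/rad² bending modulus;
with the default 2.5σ window the 41.8° icosahedral bond is accessible
(z ≈ 1.6) while the 70.5° octahedral bond is not (z ≈ 3.8) — flexible
joints close the intended shell without admitting the smaller one.

The same API is available as a library:

```python
from origamod import (TargetStructure, StructureKind, build_design,
                      validate_design, bending_modulus)
bundle = build_design(TargetStructure(StructureKind.TUBE, m=6), seed=7)
assert validate_design(bundle).ok
print(bending_modulus(12.7))   # 20.35 kBT0/rad^2
```

## Layout

| module | contents |
| --- | --- |
| `origamod.geometry` | vertex/shell/tube closure angles, CK numbers, targets |
| `origamod.anglemod` | poly-T ↔ angle lever model, sticky-length rules |
| `origamod.sequences` | NN thermodynamics, cross-talk, orthogonal set search + verifier |
| `origamod.builder` | recipes, validation, economy metrics, oligo emission |
| `origamod.joints` | signed dimer angles, Gaussian fits, rescaling, moduli, modes, ranking, gel yields |
| `origamod.synthetic` | seeded generators for angle/pose/gel fixtures |
| `origamod.cli` | `origamod` command-line tool |

See `docs/methods.md` for the model assumptions, calibrations, numerical
choices and known limitations.
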