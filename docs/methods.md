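# Methods

## The design problem

`origamod` designs and analyzes *modular* triangular DNA-origami subunits.
Each subunit is a rigid right equilateral triangular prism (52 nm edge,
15 × 10 nm cross-section) whose three side faces can each present eight
single-stranded DNA extensions: four on a "top" strand row and four on a
"bottom" row, the rows sitting 10 nm apart on the face. Every extension
is `anchor ⧺ poly-T spacer ⧺ sticky end` (5′→3′). The poly-T lengths of
the two rows (the *angle module*) set the preferred dihedral between two
bonded subunits; the sticky-end sequences (the *bond module*) set which
faces bind and how strongly. Of the 204 core staples only these 24
extended strands change between subunit variants — a ≤ 12% redesign per
variant, which is the economy the modular decomposition buys.

## Geometry

A bevel angle α on a bonded edge corresponds to a binding angle θ = 2α.
Positive θ bends subunit tops toward each other (outward-convex); 0° is
planar. The closure angle of an n-fold vertex of equilateral triangles is
0° for n = 6 (flat) and otherwise 180° − δ where the deltahedral dihedral
δ satisfies sin(δ/2) = cos(π/n)/sin(π/3): 41.81° for n = 5 (icosahedral),
70.53° for n = 4, 109.47° for n = 3. We report the closed form throughout;
some sources round the 4-fold value to 70.7°. Caspar–Klug shells with
T = h² + hk + k² contain 20·T subunits; the bond-class enumeration is
implemented for the demonstrated T = 1 (one class at 41.8°) and T = 4
(a planar intra-tetramer class plus the 41.8° five-fold class). Larger T
is rejected explicitly rather than guessed, since the quasi-equivalent
bond assignment was not demonstrated.

For achiral (m, 0) tubes no exact closure formula is adopted; the
circumferential class defaults to the 360°/m turning model (m subunits in
the shortest self-closing loop turn through 360° in total), documented as
approximate and overridable by an explicit θ_c. The axial class carries
the negative angle of the demonstrated (l_top = 3, l_bottom = 8) module.

## Angle modules: the calibrated lever model

No first-principles map from poly-T lengths to angle exists in the
demonstrated design space (the published guidance is an empirical scan),
so the package uses a two-row lever model

θ = 2·arctan( λ·(l_top − l_bottom) / (2·d) ),

with row separation d = 10 nm and effective extension λ per nucleotide
chosen so the demonstrated anchor (14, 3) → 41.8° exactly
(λ ≈ 0.694 nm/nt, inside the plausible 0.3–0.8 nm/nt range for ssDNA).
Both constants are user-overridable through the calibration config
(`row_separation_nm`, `nt_extension_nm`). The inverse fixes the shorter
row at 3 nt (bottom for positive targets, top for negative), varying the
other and rounding to whole nucleotides; round trips are exact up to the
one-nt quantization. Lengths are clamped to [0, 20] nt and values outside
the demonstrated 3–14 nt range raise an `ExtrapolationWarning`. A
worm-like-chain treatment of the ssDNA end-to-end distribution is
deliberately out of scope.

Sticky-end lengths follow the empirical on/off-rate lookup: 5 bp on
bottom rows, 5 bp on top rows with l_top < 10, 6 bp for l_top = 10–14,
and 7 bp when stronger binding is wanted (hierarchical bonds designed to
form earlier, e.g. the intra-tetramer bond of the T = 4 shell). The
observed correlation between spacer length and required hybridization
length is encoded only as this lookup, not as a continuous model.

## Sticky-end sequences

**Thermodynamics.** Intended duplexes are perfect reverse-complement
pairs scored by unified nearest-neighbor ΔH/ΔS parameters (Biopython's
tables) with duplex initiation and terminal A·T terms, evaluated at the
working temperature. Mg²⁺ is folded into a monovalent equivalent,
[Na⁺]_eq = [Na⁺] + 3.3·√[Mg²⁺] (molar), entering the standard entropy
correction 0.368·(N−1)·ln[Na⁺]_eq. The equivalence factor is a
first-order approximation and is exposed in the salt model; defaults
match the assembly buffer (5 mM NaCl, 20 mM MgCl₂).

**Cross-talk.** Both strands being 5′→3′, the score is the longest
contiguous antiparallel complementary run over all offsets — the longest
common substring of `a` and the reverse complement of `b`. The default
ceiling is 3 for 5–7-mers, two short of the weakest intended duplex
(5 bp). The verifier additionally scans each strand against partners of
*other* bonds, which catches shared-subword cross-talk, and against its
own copy, which excludes self-complementary members.

**Search.** Candidate strands are grown base by base so that no
(max_crosstalk+1)-mer window collides with — or complements — any window
already committed; this is exactly the condition that every unintended
run is within the ceiling, and it lets the search reuse the 4-mer space
efficiently enough for the largest demonstrated demand (the tube recipe:
32 elementary pairs across two length classes, finishing in well under a
second). Intended-duplex ΔG values within each length class are held
inside a window (default 1.0 kcal/mol — "similar binding strength" is
otherwise unquantified) via a running min–max bound. The search is
seeded and byte-reproducible; correctness is defined solely by the
independent exhaustive verifier, which is a separate code path (explicit
offset scan, not the search's k-mer bookkeeping). An exhausted search
raises with the best partial set and its verification report. Whether
unintended-duplex ΔG should gate in addition to run length is an open
choice; both quantities are computable, and run length gates by default.

## Design bundles

`build_design` reproduces the demonstrated recipes: continuous tiling
(one species, one self-complementary bond everywhere, flat (3,3)
modules); tetramer tiling (yellow:green 3:1, bonds A/A*/B vs B*, flat);
T = 1 shell (one species, self-complementary bond at 6/5 bp, (14,3));
T = 4 shell (3:1, A/A* at 6/5 bp on the convex faces, hierarchical 7 bp
B/B* on the flat intra-tetramer faces, plus a single-flexible-module
variant that uses (14,3) for every joint); (m,0) tube (three species
1:1:1, convex (14,3) circumferential faces, concave (3,8) axial faces,
purple S3 passivated); and 5-fold/6-fold vertex subassemblies (one
species with a passivated face; two alternating species so only even
rings close). Assembly conditions (28 °C/36 h tilings, 25 °C/24 h T=1,
30 °C/96 h T=4 and tubes, 20 mM MgCl₂, 5 nM subunits) are advisory
metadata copied from the recipes, not computed. Vertex subassembly
conditions are not specified by the source recipes; the T = 1 values are
used as a default.

Within a row the four strands always carry four different sequences
(anti-offset) and the ordering fixes a chirality. Facing rows meet
antiparallel, so a bond class whose row reads [a, b, b*, a*] binds an
identical row on the partner face: that palindromic motif *is* the
self-complementary bond (sA, sB), realized with two elementary pairs per
row. A heterotypic class (A–A*) instead uses four independent sequences
on the unstarred face and their position-reversed complements on the
starred face — a palindromic row would make the class self-binding and
break the heterotypic interaction matrices. The exact published
position-by-position assignment is not reproduced; this one consistent
assignment is fixed and validated instead.

`validate_design` reports (never raises) violations of: anti-offset,
chirality (palindromic motif for self-complementary classes,
reversed-complement rows across heterotypic pairs, top ≠ bottom),
complementarity closure, sticky-set orthogonality and ΔG window
(delegated to the exhaustive verifier), angle-module compatibility of
paired faces (tops meet tops, so both sides must carry the same module),
and dangling partners of passivated faces.

`emit_oligos` writes one record per variable strand with deterministic
ordering. Anchor segments default to seeded synthetic placeholders —
clearly non-functional stand-ins for the design-specific core anchors,
replaceable via a CSV anchor map. The strand-row placement (rows 2 and 6
of the face) is recorded as metadata only.

## Joint mechanics

**Signed angle from coordinates.** Each face's width/height axes are its
top two principal components; the normal is their cross product. The two
normals are oriented mutually facing (dot ≤ 0, valid for bonded pairs
with |θ| < 90°); the magnitude is 180° minus the inter-normal angle and
the sign is sign((n_a × n_b)·ref) with `ref` the positive hinge
direction. This sign is invariant under the residual simultaneous normal
flip, antisymmetric under body exchange, and invariant under rigid
motion of the pair. Collinear point sets are rejected.

**Gaussian statistics.** Fits are maximum-likelihood on raw samples
(sample mean, 1/n standard deviation), never histogram least squares —
binning is presentation only. A Kolmogorov–Smirnov statistic against the
fitted normal flags distributions the Gaussian summary misrepresents;
degenerate (zero-spread) inputs warn rather than fail.

**Temperature rescaling and modulus.** Ensembles observed after plunge
vitrification are treated as equilibrated at 136 K; under a
temperature-independent harmonic spring, σ²(T₂)/σ²(T₁) = T₂/T₁, and the
equipartition bending modulus is k = (T/T₀)/σ_rad² in units of k_B·T₀/rad²
(T₀ = 298 K). Rescaling then re-applying equipartition commutes exactly
with computing the modulus at the original temperature — both express the
same spring. The temperature-independence assumption is first-order only:
coarse-grained simulations show deviations from both purely entropic and
temperature-independent behaviour, so moduli derived this way carry that
caveat.

**Mode decomposition.** Relative poses (axis-angle + translation) are
reduced to 6-DOF deviations about the mean pose (chordal mean rotation)
and decomposed by PCA. Radians and nanometres are treated as
commensurate; this real-space decomposition is a simplified stand-in for
a full eigen-space-to-real-space calibration, and is labelled as such.
Variances of the projections onto the nominal bend (rotation about the
hinge), twist (rotation about the bond axis) and stretch (translation
along it) axes are reported, with a linear PC1-score→bend-angle fit.

**Accessible structures.** A candidate structure is energetically
reachable when |θ_target − mean| ≤ c·σ; the default c = 2.5 reproduces
the observed selectivity of the flexible joint (mean 21.6°, σ 12.7°):
the icosahedron's 41.8° sits at z ≈ 1.6 (inside) while the octahedron's
70.5° sits at z ≈ 3.8 (outside). Among reachable closed structures the
smallest — largest binding angle, hence smallest curvature radius — is
ranked first (the kinetic rule); unbounded open structures rank last.

**Gel yield.** Lane profiles are background-subtracted, clipped at zero
and normalized; a Gaussian is fitted to the target band inside the peak
window and the yield is the fitted area over the total lane area,
invariant under uniform intensity rescaling. Fits with no credible peak
(non-positive amplitude, centre outside the window, width wider than the
window) raise with diagnostics.

## Synthetic fixtures

The generators emulate the statistical structure of the measured
ensembles, not the measurements themselves: i.i.d. Gaussian bend about
the mean angle (spread given directly or via a modulus through inverse
equipartition), with independent Gaussian twist and stretch — modes are
reported as dominated by bend with minor twist/stretch, and their
correlations are not quantified, so independence is the neutral choice.
The default face template is 8 points in two rows spanning the core's
15 × 10 nm cross-section, and posed dimers use a 2 nm bond gap with the
hinge at the bottom edge; recovered bend angles round-trip exactly (to
numerical precision) at zero noise. Synthetic gel lanes place an exact
target-band area fraction on a broad smear and constant baseline. None
of the generators model misfolded particles, imaging noise, mode
correlations or non-Gaussian tails, so passing round trips validate the
estimators, not the experiments.

## Problem sizes and numerical choices

Test ensembles use n = 10³–10⁵ samples (recovery tolerances 10%, 5% and
1% respectively, matching √n sampling error), and sequence sets up to the
tube demand (32 pairs). All stochastic steps take integer seeds and are
byte-reproducible. Angles are kept in degrees at full precision and
rounded to one decimal only at presentation. Ties in accessibility
ranking (equal subunit counts) break on z-score.

## Known limitations

* The length→angle lever model is calibrated, not derived; measured
  dimer means can sit well below the structural target (a (14,3) joint
  averages ~21.6° yet reliably closes 41.8° structures), which is
  exactly why the accessibility window, not the point prediction,
  carries the design conclusion.
* The tube circumferential angle model (360°/m) ignores the helical
  geometry of the triangle lattice.
* Sequence sets are regenerated, not the published ones; anchors are
  placeholders.
* Only achiral (m, 0) tubes, T ∈ {1, 4} shells and n ∈ {5, 6} vertex
  recipes are built; chiral tubes and larger shells are out of scope.
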