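# Methods

This note records the models implemented in `jawscape`, the assumptions
behind them, the defaults and why they were chosen, and what the test
suite does and does not establish.

## Outline representation and ingestion

The atomic object is a closed, counterclockwise polygon of 2D landmarks
(`OutlineLoop`). Binary masks are traced with marching squares at the 0.5
level — single-pixel resolution, no sub-pixel smoothing. Smoothing is
deliberately left to harmonic truncation in the EFA step: the pixel
staircase lives in high harmonics that a 40-harmonic fit discards. A
consequence measured in the tests: the raw traced perimeter of a 1000-px
jaw mask overestimates the true polygon perimeter by ~3–4%, but after the
standard 600-landmark arc-length resample the error falls below 1%.

Ingestion canonicalizes every loop: counterclockwise orientation, landmark
0 at maximum x (the anterior jaw tip under the anterior-right convention).
This fixes the EFA parameter start deterministically; without it the
normalization's half-period phase ambiguity could flip higher-harmonic
signs between otherwise identical shapes.

## Elliptical Fourier analysis

`efa_forward` evaluates the exact Fourier integrals of the piecewise-linear
closed curve parameterized by cumulative arc length (the standard
chain-coded formulation). Normalization removes the centroid offset,
rotates the first-harmonic major axis onto the x-axis, shifts the
parameter origin to the canonical phase, divides by the semi-major axis
length (recorded as `scale_factor`, the size proxy used later by relative
area), and resolves the reflection ambiguity by requiring d₁ > 0.

A subtlety worth stating: EFA's parameter is arc length, so an eccentric
ellipse traversed at constant speed is *not* x = a·cos t, and its
first-harmonic semi-axes deviate from (a, b) — for a 2:1 ellipse they are
(1.8284, 1.0730). The tests therefore validate coefficients against an
independent dense-quadrature oracle of the arc-length Fourier integrals
rather than the constant-angle closed form. Circles are unaffected.

Default harmonic count H = 40: reconstruction error on smooth synthetic
jaws is below 0.5% of outline length, while keeping the PCA space modest.
H is a configuration knob, as is the landmark count (default 600).

## Morphospace and the theoretical grid

PCA is covariance-based (coefficients share units) over the flattened
normalized coefficient vectors (a₁..a_H, b₁..b_H, c₁..c_H, d₁..d_H); the
constant post-normalization entries (a₁ = 1, b₁ = c₁ = 0) carry zero
variance and are retained harmlessly. Axis signs follow a deterministic
convention (largest-magnitude loading positive). All components are kept
so full-score reconstruction is exact.

The theoretical grid is 25 × 20 = 500 cells (PC1 × PC2; PC1 carries more
variance so it gets the longer axis), spanning the empirical score range
padded on both ends of both axes by 20% of the PC1 range. Whether the
original workflow padded PC2 at all is unknowable from the outside; using
the PC1-range pad on both axes is the literal reading and both the
fraction and grid shape are configurable. Each cell's outline is
reconstructed at 600 landmarks from mean + pc1·axis₁ + pc2·axis₂ and
checked for self-intersection (shapely simplicity predicate, validated
against a brute-force all-pairs segment oracle). Self-intersecting cells
are "impossible morphospace": no functional values are computed there and
they are excluded from Pareto ranking rather than assigned a worst rank.

## Meshing

No constrained-Delaunay library is available in the target environment, so
triangulation is built from primitives: the boundary is resampled at 0.6×
the target spacing (preserving any vertex where the outline turns by more
than 20°, so rectangles keep their corners), a hexagonal lattice fills the
interior at clearance 0.55× spacing, scipy's Delaunay triangulates the
point set, and triangles whose centroid falls outside the polygon are
dropped. Lattice spacing is adjusted iteratively until the element count
is within 10% of the target (default 2500). The mesh must reproduce the
polygon area within 0.1% and be a single connected component, or the
spacing is refined and the build retried.

Functional nodes: with anterior to the right, the joint is the leftmost
boundary node whose outward normal is within 30° of vertical and the bite
point the rightmost such node ("near vertical" has no published value; the
tolerance widens in 5° steps to 45° before erroring, and is a config
knob). The muscle insertion sits on the dorsal margin nearest to
one-third of the joint→bite distance — adductor musculature inserts
dorsally; a config flag selects the ventral margin instead. Density and
thickness are unitless 1: every surface is relative, not absolute.

## Finite elements

Standard 3-node constant-strain triangles under plane stress, E = 2 GPa,
ν = 0.3, thickness 1, each shape scaled to unit area so sizes do not
confound shape comparisons. Constraints are eliminated from the assembled
sparse system (not penalized), which keeps the patch test exact: a plate
under uniform tension reproduces element-wise Von Mises stress to 1e-13
relative. Boundary conditions for the jaw lever — joint pinned in x and y,
bite point supported in y, unit muscle force directed along the inward
surface normal — are not published details; they are the standard 2D
lever abstraction and fully exposed in `LoadCase`/`default_jaw_constraints`.

The per-shape statistic is the **median** element Von Mises stress, which
is insensitive to the singular stresses adjacent to point constraints.
The bootstrap (default 1000 iterations) re-draws the muscle node position
uniformly within ±5% of the outline perimeter and the force direction
uniformly within ±45° of the inward normal. The stiffness factorization
depends only on the constraints, so it is computed once per shape and each
iteration is a back-substitution — this is what makes 500 cells × 1000
iterations tractable on one CPU. Iteration i's draws are a pure function
of (seed, i) (and the pipeline keys each cell's seed from the run seed),
so results are independent of evaluation order and bit-reproducible.

## Rotational efficiency and relative area

I = Σ mᵢrᵢ² uses element centroid lumping, as stated for the original
measure; the tests quantify the approximation against the exact
per-triangle polar moment integral (relative error ~1e-3 at 2500
elements, dominated by mesh granularity rather than lumping). Then
v = L·√(2E/I) with E = 1 J and L the joint→bite distance. The published
equation is garbled in the source text ("v = L2I"); the 1 J energy
definition fixes the interpretation used here. v is scale-invariant at
fixed mass (L ∝ s, I ∝ s²), so equal-area scaling makes it a pure shape
measure. Its joint/bite bootstrap jitters both nodes independently along
the boundary arc (±5% of perimeter).

Relative area is the shoelace area of the normalized (unit first-harmonic)
reconstruction, so all grid shapes share a length scale; it is a point
value with no bootstrap.

## Pareto ranking

Objectives: minimize median VMS, maximize rotational efficiency, minimize
relative area, using the bootstrap mean surfaces. Weak dominance (≥ in
all, > in at least one; exact ties co-rank) defines the front; fronts are
peeled iteratively and front j of K receives rank (K − j)/(K − 1), giving
the stated 0 (last front) to 1 (Pareto optimal) scale. The exact
"modification" of the original Goldberg scheme is unpublished; classical
peeling with this linear rescale matches the stated endpoints, and the
implementation is verified for exact equality against a brute-force
peeling oracle up to 500 points in 2 and 3 objectives.

## Synthetic data

The generator emulates the *axes of variation* reported for archosaur
lower jaws — not any taxon's anatomy: relative depth of the anterior
(tooth-bearing) versus posterior region (the robustness/PC1 factor), and
dorsoventral bowing plus vertical joint offset (the PC2 factors). Profiles
are smoothstep-blended depth envelopes pinched at both ends (superellipse
roll-offs; exponent 6 posteriorly for a blunt joint end, tunable 2–4
anteriorly for tip rounding) around a bowed midline. Population defaults:
243 shapes emulating the empirical sample size; depths log-uniform on
[0.05, 0.45] of jaw length (log-uniform keeps gracile and robust forms
equally represented across the plausible anatomical range); curvature
uniform on ±0.10 and joint drop uniform on ±0.08 of length — bands chosen
as the widest that keep essentially all draws simple (non-self-
intersecting); out-of-range draws are rejected deterministically.

What a green synthetic test establishes: the pipeline's mechanics,
determinism and the qualitative structure of the landscapes (gracile
shapes faster and lower-drag, robust shapes stronger). What it does not:
agreement with the empirical variance decomposition (PC1 56.32%, PC2
23.78%, PC3 5.00%), which requires the published 243-outline archive —
the pipeline accepts such a directory via `PipelineConfig(input_dir=...)`,
but real outlines carry preparation details (tooth removal, orientation
choices) the generator does not emulate.

## Numerical choices and limitations

- Self-intersection tolerance is shapely's exact predicate; the brute
  oracle uses 1e-12 collinearity slack.
- Near-tie hazards: at the pinched jaw ends the dorsal and ventral margins
  meet, and joint/bite selection between mirror-image candidates can flip
  under float rounding; all downstream quantities are insensitive to the
  choice (the candidates coincide to within one landmark spacing).
- Bootstrap CIs are percentile (2.5/97.5) across iterations; with jitter
  zero they collapse to the point estimate.
- The FEA is linear-elastic, homogeneous, 2D plane stress: no contact, no
  material anisotropy, no out-of-plane bending. Stresses are meaningful
  only as relative comparisons across equally scaled shapes.
- Default scales (500 cells × 1000 iterations) reproduce the reference
  workflow; tests and the acceptance script run reduced configurations
  (10 × 8 grid, 40–50 iterations, ~1200-element meshes) to fit desk-scale
  budgets — the determinism and sign-structure they check are
  scale-independent.
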